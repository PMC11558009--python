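"""Individual-level retrieved-context memory model.

A drifting unit-norm context vector is bound to items during study through
Hebbian outer-product learning and later cues retrieval.  Recall alternates
sampling an item whose stored context matches the current context with
drifting the context toward the just-retrieved item, until a positionally
increasing stopping hazard fires.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace

import numpy as np

from .semantic import SemanticSpace

__all__ = [
    "CMRParams",
    "AgentState",
    "NoItemsAvailable",
    "init_agent",
    "drift_context",
    "encode_list",
    "retrieval_activations",
    "sample_recall",
    "stop_probability",
    "context_input",
    "recall_item_update",
    "simulate_individual_recall",
]

#: floor on retrieval activations so sampling stays well defined
A_MIN = 1e-7
#: base constant of the stopping hazard
THETA0 = 0.05

_UNIT_RANGE = {"beta_enc", "beta_rec", "gamma_fc", "p_cue"}
_NONNEG = {"gamma_cf", "s_sem", "theta_r", "phi_s", "phi_d"}
_POSITIVE = {"tau", "eps_d"}


@dataclass(frozen=True)
class CMRParams:
    """Model parameters shared by every simulated individual.

    beta_enc / beta_rec : context drift rates at study and at recall/listening
    gamma_fc / gamma_cf : Hebbian learning rates for the two association maps
    s_sem               : scale of pre-experimental semantic associations
    tau                 : choice sensitivity (Luce exponent)
    eps_d               : stopping scale; smaller values stop recall earlier
    theta_r             : growth rate of the stopping hazard over output position
    phi_s, phi_d        : primacy boost magnitude and decay (off by default)
    p_cue               : probability a listener attends to another's novel recall
    """

    beta_enc: float = 0.75
    beta_rec: float = 0.85
    gamma_fc: float = 0.4
    gamma_cf: float = 1.0
    s_sem: float = 3.0
    tau: float = 4.0
    eps_d: float = 0.8
    theta_r: float = 0.15
    phi_s: float = 0.0
    phi_d: float = 1.0
    p_cue: float = 0.2

    def __post_init__(self):
        for f in fields(self):
            v = float(getattr(self, f.name))
            object.__setattr__(self, f.name, v)
            if f.name in _UNIT_RANGE and not 0.0 <= v <= 1.0:
                raise ValueError(f"{f.name} must be in [0, 1], got {v}")
            if f.name in _NONNEG and v < 0.0:
                raise ValueError(f"{f.name} must be nonnegative, got {v}")
            if f.name in _POSITIVE and v <= 0.0:
                raise ValueError(f"{f.name} must be positive, got {v}")

    def replace(self, **kwargs) -> "CMRParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "CMRParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {', '.join(sorted(unknown))}")
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "CMRParams":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


class NoItemsAvailable(RuntimeError):
    """Raised when every item is excluded from the sampling pool."""


@dataclass
class AgentState:
    """One individual: context, association matrices, and recall history.

    The context lives in a (d+1)-dimensional space: the item embedding
    dimensions plus one orthogonal start-of-session dimension, so the first
    studied item has a well-defined association target.
    """

    context: np.ndarray
    m_fc: np.ndarray  # (d+1, n): item feature -> context support
    m_cf: np.ndarray  # (n, d+1): context -> item activations
    item_dirs: np.ndarray  # (n, d+1): semantic direction per item
    recalled_own: list = field(default_factory=list)
    heard: list = field(default_factory=list)
    stopped: bool = False
    context_trajectory: list = field(default_factory=list)
    study_order: np.ndarray | None = None

    @property
    def n_items(self) -> int:
        return self.m_cf.shape[0]


def init_agent(space: SemanticSpace, params: CMRParams, seed: int | None = None) -> AgentState:
    """Create a pre-experimental agent over ``space``.

    The context starts on the orthogonal start-of-session axis.  ``m_fc``
    maps each item feature to its own semantic direction; ``m_cf`` is
    pre-loaded so that context aligned with item i activates item j by
    ``s_sem * cosine(i, j)``.
    """
    if space.n_items < 1:
        raise ValueError("space must contain at least one item")
    n, d = space.n_items, space.dim
    item_dirs = np.zeros((n, d + 1))
    item_dirs[:, :d] = space.vectors
    context = np.zeros(d + 1)
    context[d] = 1.0
    m_fc = item_dirs.T.copy()
    m_cf = params.s_sem * item_dirs.copy()
    return AgentState(context=context, m_fc=m_fc, m_cf=m_cf, item_dirs=item_dirs)


def drift_context(c: np.ndarray, c_in: np.ndarray, beta: float) -> np.ndarray:
    """Drift ``c`` toward unit vector ``c_in`` by rate ``beta``, keeping unit norm.

    Returns ``rho * c + beta * c_in`` with
    ``rho = sqrt(1 + beta^2 ((c.c_in)^2 - 1)) - beta (c.c_in)``, the exact
    normalization that keeps the result on the unit sphere.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"drift rate must be in [0, 1], got {beta}")
    if abs(np.linalg.norm(c_in) - 1.0) > 1e-6:
        raise ValueError("c_in must be a unit vector")
    dot = float(np.dot(c, c_in))
    rho = np.sqrt(max(0.0, 1.0 + beta * beta * (dot * dot - 1.0))) - beta * dot
    new = rho * c + beta * c_in
    norm = np.linalg.norm(new)
    if norm > 0:
        new = new / norm
    return new


def encode_list(agent: AgentState, order, params: CMRParams) -> AgentState:
    """Study the full list in the given order (a permutation of all items).

    For each item: Hebbian updates bind the *pre-drift* context to the item
    in both maps (with the primacy boost ``1 + phi_s exp(-phi_d (pos-1))``
    on the context->feature direction), then the context drifts toward the
    item's semantic direction at rate ``beta_enc``.
    """
    order = np.asarray(order, dtype=int)
    n = agent.n_items
    if sorted(order.tolist()) != list(range(n)):
        raise ValueError("study order must be a permutation of all items")
    c = agent.context
    for pos, item in enumerate(order, start=1):
        phi = 1.0 + params.phi_s * np.exp(-params.phi_d * (pos - 1))
        agent.m_fc[:, item] += params.gamma_fc * c
        agent.m_cf[item] += phi * params.gamma_cf * c
        c = drift_context(c, agent.item_dirs[item], params.beta_enc)
    agent.context = c
    agent.study_order = order.copy()
    agent.context_trajectory = [c.copy()]
    return agent


def retrieval_activations(agent: AgentState) -> np.ndarray:
    """Context-cued activation of every item, floored at ``A_MIN``."""
    return np.maximum(agent.m_cf @ agent.context, A_MIN)


def sample_recall(a: np.ndarray, excluded, tau: float, rng: np.random.Generator) -> int:
    """Sample an item with probability proportional to ``a_i ** tau``.

    Excluded items get zero mass; raises :class:`NoItemsAvailable` when the
    pool is empty.
    """
    a = np.asarray(a, dtype=float)
    mask = np.ones(a.shape[0], dtype=bool)
    for i in excluded:
        mask[i] = False
    avail = np.flatnonzero(mask)
    if avail.size == 0:
        raise NoItemsAvailable("all items excluded from sampling")
    # work in log space so large tau cannot overflow
    logw = tau * np.log(a[avail])
    logw -= logw.max()
    w = np.exp(logw)
    p = w / w.sum()
    return int(rng.choice(avail, p=p))


def stop_probability(output_pos: int, params: CMRParams, theta0: float = THETA0) -> float:
    """Probability of terminating recall before producing output ``output_pos``.

    ``min(1, (theta0 / eps_d) * exp(theta_r * output_pos))`` — strictly
    decreasing in ``eps_d`` (below the cap), nondecreasing in position.
    """
    if output_pos < 0:
        raise ValueError("output_pos must be >= 0")
    if params.eps_d <= 0:
        raise ValueError("eps_d must be positive")
    return float(min(1.0, (theta0 / params.eps_d) * np.exp(params.theta_r * output_pos)))


def context_input(agent: AgentState, item: int) -> np.ndarray:
    """Retrieved-context cue for ``item``: its ``m_fc`` column, normalized.

    Blends the item's semantic direction with its stored study context(s).
    """
    col = agent.m_fc[:, item]
    norm = np.linalg.norm(col)
    if norm == 0:
        return agent.item_dirs[item]
    return col / norm


def recall_item_update(agent: AgentState, item: int, params: CMRParams) -> AgentState:
    """Drift the agent's context toward ``item``'s retrieved-context input.

    Applied identically whether the agent recalled the item itself or
    attended to another member's recall — the shared pathway through which
    group members influence each other.
    """
    if not 0 <= item < agent.n_items:
        raise IndexError("item index out of range")
    agent.context = drift_context(agent.context, context_input(agent, item), params.beta_rec)
    agent.context_trajectory.append(agent.context.copy())
    return agent


def simulate_individual_recall(
    agent: AgentState, params: CMRParams, rng: np.random.Generator
) -> list:
    """Run one free-recall session; returns the ordered recall sequence.

    Loop: stop with ``stop_probability`` at the current output position;
    otherwise sample an item not yet recalled by this agent, record it and
    drift the context toward it.
    """
    recalls: list[int] = []
    excluded: set[int] = set()
    while True:
        if rng.random() < stop_probability(len(recalls), params):
            agent.stopped = True
            break
        a = retrieval_activations(agent)
        try:
            item = sample_recall(a, excluded, params.tau, rng)
        except NoItemsAvailable:
            agent.stopped = True
            break
        recalls.append(item)
        excluded.add(item)
        agent.recalled_own.append(item)
        recall_item_update(agent, item, params)
    return recalls
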