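"""Context-dynamics analyses: between-member similarity, convergence, and
their statistical relationship with recall performance."""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .cmr import CMRParams
from .metrics import proportion_recalled
from .semantic import SemanticSpace
from .simulate import GroupTranscript, simulate_collaborative_group

__all__ = [
    "ContextTrajectorySet",
    "pairwise_context_similarity",
    "context_convergence",
    "within_subject_similarity",
    "own_recall_trajectory",
    "condition_output_anova",
    "convergence_performance_correlation",
    "groupsize_permutation_test",
]


@dataclass
class ContextTrajectorySet:
    """Per-agent context snapshots aligned to a shared output-position axis.

    ``array`` has shape (n_agents, T+1, d); snapshot 0 is the start-of-recall
    context.  Trajectories shorter than the alignment length are padded with
    their final snapshot (a stopped agent's context no longer moves).
    """

    array: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.array, dtype=float)
        if arr.ndim != 3:
            raise ValueError("trajectory set must be (n_agents, T+1, d)")
        self.array = arr

    @property
    def n_agents(self) -> int:
        return self.array.shape[0]

    @property
    def length(self) -> int:
        """Alignment length T+1."""
        return self.array.shape[1]

    @classmethod
    def from_transcript(
        cls, t: GroupTranscript, min_length: int | None = None
    ) -> "ContextTrajectorySet":
        if not t.trajectories:
            raise ValueError("transcript carries no context trajectories")
        length = max(tr.shape[0] for tr in t.trajectories)
        if min_length is not None:
            length = max(length, min_length)
        padded = []
        for tr in t.trajectories:
            tr = np.asarray(tr)
            if tr.shape[0] < length:
                pad = np.repeat(tr[-1:], length - tr.shape[0], axis=0)
                tr = np.vstack([tr, pad])
            padded.append(tr)
        return cls(array=np.stack(padded))


def pairwise_context_similarity(ts: ContextTrajectorySet, output_pos: int) -> float:
    """Mean cosine over all unordered agent pairs at one output position."""
    if ts.n_agents < 2:
        raise ValueError("need at least two agents for pairwise similarity")
    if not 0 <= output_pos < ts.length:
        raise ValueError(f"output_pos {output_pos} outside trajectory range")
    snaps = ts.array[:, output_pos, :]
    sims = [
        float(np.dot(snaps[i], snaps[j]))
        for i, j in itertools.combinations(range(ts.n_agents), 2)
    ]
    return float(np.mean(sims))


def context_convergence(ts: ContextTrajectorySet, early: int = 0, late: int = 10) -> float:
    """Change in mean pairwise context similarity from ``early`` to ``late``."""
    if late >= ts.length:
        raise ValueError(f"late position {late} beyond trajectory length {ts.length}")
    return pairwise_context_similarity(ts, late) - pairwise_context_similarity(ts, early)


def within_subject_similarity(trajectory: np.ndarray, after: int = 10) -> float:
    """Cosine between one agent's start-of-recall context and its context
    ``after`` updates later — higher similarity means less context space
    traversed."""
    trajectory = np.asarray(trajectory)
    if trajectory.shape[0] <= after:
        raise ValueError("trajectory too short for requested position")
    a, b = trajectory[0], trajectory[after]
    return float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))


def own_recall_trajectory(t: GroupTranscript, agent: int, pad_to: int | None = None) -> np.ndarray:
    """Context snapshots at the moments of one agent's own recalls.

    Index k is the agent's context just after its k-th own recall (index 0
    is the start-of-recall context); for collaborative transcripts any
    intervening listening updates are reflected.  Padded with the final
    snapshot when ``pad_to`` exceeds the recall count.
    """
    traj = np.asarray(t.trajectories[agent])
    if t.condition == "nominal":
        snaps = traj
    else:
        idx = [0] + [
            k + 1
            for k, e in enumerate(t.events)
            if e.speaker == agent and e.action == "recall"
        ]
        snaps = traj[idx]
    if pad_to is not None and snaps.shape[0] < pad_to:
        pad = np.repeat(snaps[-1:], pad_to - snaps.shape[0], axis=0)
        snaps = np.vstack([snaps, pad])
    return snaps


def condition_output_anova(df: pd.DataFrame) -> dict:
    """Two-way fixed-effects ANOVA of similarity ~ condition * output position.

    ``df`` needs columns ``similarity``, ``condition``, ``output`` (the last
    typically the early/late labels 0 and 10).  Returns F and p for both main
    effects and, most importantly, the interaction.
    """
    required = {"similarity", "condition", "output"}
    if not required.issubset(df.columns):
        raise ValueError(f"dataframe must have columns {sorted(required)}")
    cells = df.groupby(["condition", "output"]).size()
    if (cells < 2).any() or cells.size < 4:
        raise ValueError("need >= 2 observations in every condition x output cell")
    model = smf.ols("similarity ~ C(condition) * C(output)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    def row(name):
        return {"F": float(table.loc[name, "F"]), "p": float(table.loc[name, "PR(>F)"])}
    return {
        "condition": row("C(condition)"),
        "output": row("C(output)"),
        "interaction": row("C(condition):C(output)"),
    }


def convergence_performance_correlation(
    space: SemanticSpace,
    params: CMRParams,
    group_size: int,
    n_groups: int = 100,
    seed=None,
    late: int = 10,
):
    """Spearman correlation between context convergence and recall performance.

    Simulates ``n_groups`` collaborative groups, each with its own listening
    probability drawn uniformly from [0, 1]; per group measures the change in
    pairwise context similarity from output 0 to ``late`` and the proportion
    of the list recalled.  Returns ``(rho, p, convergences, performances)``.
    """
    if n_groups < 10:
        raise ValueError("n_groups must be >= 10")
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**63 - 1, size=n_groups)
    convergences, performances = [], []
    for k in range(n_groups):
        p_cue = float(rng.uniform())
        t = simulate_collaborative_group(
            space, params.replace(p_cue=p_cue), group_size, seed=int(seeds[k])
        )
        ts = ContextTrajectorySet.from_transcript(t, min_length=late + 1)
        convergences.append(context_convergence(ts, early=0, late=late))
        performances.append(proportion_recalled(t))
    res = stats.spearmanr(convergences, performances)
    return float(res.statistic), float(res.pvalue), np.array(convergences), np.array(performances)


def _spearman_stat(x: np.ndarray, y: np.ndarray) -> float:
    return float(stats.spearmanr(x, y).statistic)


def groupsize_permutation_test(
    inhibition_by_size,
    similarity_by_size,
    n_perm: int = 1000,
    seed=None,
    exhaustive: bool = False,
) -> float:
    """Two-sided permutation p-value for the per-size association between
    collaborative inhibition and within-subject context similarity.

    The statistic is the Spearman correlation between the two per-size
    series; the null shuffles the size labels of one series.  ``exhaustive``
    enumerates all permutations (exact p = fraction at least as extreme);
    otherwise ``n_perm`` random shuffles with add-one smoothing.
    """
    x = np.asarray(inhibition_by_size, dtype=float)
    y = np.asarray(similarity_by_size, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D series")
    if x.size < 3:
        raise ValueError("need at least three group sizes")
    observed = abs(_spearman_stat(x, y))
    tol = 1e-12
    if exhaustive:
        perms = list(itertools.permutations(range(x.size)))
        extreme = sum(
            abs(_spearman_stat(x, y[list(p)])) >= observed - tol for p in perms
        )
        return extreme / len(perms)
    rng = np.random.default_rng(seed)
    extreme = 0
    for _ in range(n_perm):
        extreme += abs(_spearman_stat(x, rng.permutation(y))) >= observed - tol
    return (1 + extreme) / (1 + n_perm)
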