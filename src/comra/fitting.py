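"""Parameter fitting: nRMSE objective, sequential model-based optimization
for the individual-recall parameters, and grid search for the listening
probability."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .cmr import CMRParams
from .metrics import BehavioralSummary, summarize
from .semantic import SemanticSpace
from .simulate import simulate_collaborative_group, simulate_nominal_group

__all__ = ["FitTargets", "FitResult", "nrmse", "fit_nominal", "fit_pcue"]

# per-parameter admissible intervals, mirroring CMRParams invariants
_PARAM_DOMAIN = {
    "beta_enc": (0.0, 1.0),
    "beta_rec": (0.0, 1.0),
    "gamma_fc": (0.0, 1.0),
    "gamma_cf": (0.0, np.inf),
    "s_sem": (0.0, np.inf),
    "tau": (1e-9, np.inf),
    "eps_d": (1e-9, np.inf),
    "theta_r": (0.0, np.inf),
    "phi_s": (0.0, np.inf),
    "phi_d": (0.0, np.inf),
    "p_cue": (0.0, 1.0),
}


@dataclass
class FitTargets:
    """Target behavioral curves and their relative weights.

    Components with a ``None`` target (or zero weight) are skipped.
    """

    spc: np.ndarray | None = None
    pfr: np.ndarray | None = None
    sem_by_lag_own: np.ndarray | None = None
    sem_by_lag_group: np.ndarray | None = None
    weights: dict = field(default_factory=dict)

    _COMPONENTS = ("spc", "pfr", "sem_by_lag_own", "sem_by_lag_group")

    def __post_init__(self):
        active = False
        for name in self._COMPONENTS:
            vec = getattr(self, name)
            if vec is None:
                continue
            vec = np.asarray(vec, dtype=float)
            if not np.all(np.isfinite(vec)):
                raise ValueError(f"target {name} contains non-finite values")
            setattr(self, name, vec)
            if self.weights.get(name, 1.0) > 0:
                active = True
        for name, w in self.weights.items():
            if name not in self._COMPONENTS:
                raise ValueError(f"unknown weight component {name!r}")
            if w < 0:
                raise ValueError("weights must be nonnegative")
        if not active:
            raise ValueError("no active (positively weighted) target component")

    def components(self):
        for name in self._COMPONENTS:
            vec = getattr(self, name)
            w = self.weights.get(name, 1.0)
            if vec is not None and w > 0:
                yield name, vec, w

    @classmethod
    def from_summary(cls, summary: BehavioralSummary, weights: dict | None = None) -> "FitTargets":
        return cls(
            spc=summary.spc,
            pfr=summary.pfr,
            sem_by_lag_own=summary.sem_by_lag_own,
            sem_by_lag_group=summary.sem_by_lag_group,
            weights=weights or {},
        )


@dataclass
class FitResult:
    best_params: CMRParams
    objective_value: float
    evaluation_log: list  # (param dict, objective) pairs
    seed: int | None
    n_sims_per_eval: int

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "best_params": self.best_params.to_dict(),
                    "objective_value": self.objective_value,
                    "evaluation_log": [
                        {"params": p, "objective": v} for p, v in self.evaluation_log
                    ],
                    "seed": self.seed,
                    "n_sims_per_eval": self.n_sims_per_eval,
                },
                fh,
                indent=2,
            )


def nrmse(model: BehavioralSummary, targets: FitTargets) -> float:
    """Range-normalized RMSE, averaged over target components.

    Per component: RMSE between model curve and target divided by the
    target's range; the objective is the weight-normalized mean.  Always
    nonnegative; zero iff every curve matches exactly.
    """
    total, wsum = 0.0, 0.0
    for name, target, w in targets.components():
        curve = getattr(model, name)
        if curve is None:
            raise ValueError(f"model summary lacks component {name}")
        curve = np.asarray(curve, dtype=float)
        if curve.shape != target.shape:
            raise ValueError(f"{name}: model length {curve.shape} != target {target.shape}")
        rng = float(target.max() - target.min())
        if rng == 0:
            raise ValueError(f"target {name} has zero range")
        total += w * float(np.sqrt(np.mean((curve - target) ** 2))) / rng
        wsum += w
    return total / wsum


def _simulate_nominal_summary(space, params, n_sims, eval_seed, max_lag=4):
    ss = np.random.SeedSequence(eval_seed)
    seeds = ss.generate_state(n_sims)
    transcripts = [
        simulate_nominal_group(space, params, 1, seed=int(s)) for s in seeds
    ]
    return summarize(transcripts, space, max_lag=max_lag, group_scope=False)


def _simulate_collab_summary(space, params, n_sims, group_size, eval_seed, max_lag=4):
    ss = np.random.SeedSequence(eval_seed)
    seeds = ss.generate_state(n_sims)
    transcripts = [
        simulate_collaborative_group(space, params, group_size, seed=int(s)) for s in seeds
    ]
    return summarize(transcripts, space, max_lag=max_lag, group_scope=True)


def _validate_bounds(bounds: dict):
    if not bounds:
        raise ValueError("bounds must name at least one parameter to fit")
    for name, (lo, hi) in bounds.items():
        if name not in _PARAM_DOMAIN:
            raise ValueError(f"unknown parameter {name!r}")
        dlo, dhi = _PARAM_DOMAIN[name]
        if not (dlo <= lo < hi <= dhi):
            raise ValueError(f"bounds for {name} must satisfy {dlo} <= lo < hi <= {dhi}")


def fit_nominal(
    targets: FitTargets,
    space: SemanticSpace,
    bounds: dict,
    budget: int = 40,
    n_sims_per_eval: int = 60,
    seed: int | None = None,
    base_params: CMRParams | None = None,
    max_lag: int = 4,
) -> FitResult:
    """Fit individual-recall parameters to nominal behavioral targets.

    Sequential model-based minimization of the nRMSE objective: an initial
    random design followed by Gaussian-process expected-improvement
    proposals.  Every evaluation reuses the same simulation seed (common
    random numbers), so the objective surface is deterministic given
    ``seed``.  ``bounds`` maps parameter names to (low, high) search
    intervals; unlisted parameters stay at ``base_params``.
    """
    if budget < 10:
        raise ValueError("budget must be >= 10")
    _validate_bounds(bounds)
    base = base_params or CMRParams()
    names = sorted(bounds)
    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])
    rng = np.random.default_rng(seed)
    eval_seed = int(rng.integers(0, 2**31 - 1))

    log: list = []
    X, y = [], []

    def evaluate(x: np.ndarray) -> float:
        params = base.replace(**{n: float(v) for n, v in zip(names, x)})
        summary = _simulate_nominal_summary(space, params, n_sims_per_eval, eval_seed, max_lag)
        val = nrmse(summary, targets)
        log.append((params.to_dict(), val))
        X.append((x - lo) / (hi - lo))
        y.append(val)
        return val

    n_init = max(5, budget // 4)
    for _ in range(min(n_init, budget)):
        evaluate(lo + (hi - lo) * rng.uniform(size=len(names)))

    kernel = ConstantKernel(1.0) * Matern(nu=2.5) + WhiteKernel(1e-4, (1e-8, 1e1))
    while len(y) < budget:
        gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True, random_state=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(np.array(X), np.array(y))
        cand = rng.uniform(size=(256, len(names)))
        mu, sigma = gp.predict(cand, return_std=True)
        best = min(y)
        sigma = np.maximum(sigma, 1e-12)
        z = (best - mu) / sigma
        ei = (best - mu) * norm.cdf(z) + sigma * norm.pdf(z)
        evaluate(lo + (hi - lo) * cand[int(np.argmax(ei))])

    i_best = int(np.argmin(y))
    best_params = base.replace(**{n: float(log[i_best][0][n]) for n in names})
    return FitResult(
        best_params=best_params,
        objective_value=float(y[i_best]),
        evaluation_log=log,
        seed=seed,
        n_sims_per_eval=n_sims_per_eval,
    )


def fit_pcue(
    params: CMRParams,
    collab_targets: FitTargets,
    space: SemanticSpace,
    grid_step: float = 0.1,
    n_sims_per_eval: int = 40,
    seed: int | None = None,
    group_size: int = 3,
    max_lag: int = 4,
    grid=None,
) -> FitResult:
    """Grid-search the listening probability with all other parameters fixed.

    Evaluates p_cue over {0, grid_step, ..., 1} (or an explicit ``grid``),
    simulating collaborative groups with common random numbers across grid
    points and scoring nRMSE against the collaborative targets.
    """
    if grid is None:
        grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    eval_seed = int(rng.integers(0, 2**31 - 1))
    log = []
    for p_cue in grid:
        candidate = params.replace(p_cue=float(p_cue))
        summary = _simulate_collab_summary(
            space, candidate, n_sims_per_eval, group_size, eval_seed, max_lag
        )
        log.append((candidate.to_dict(), nrmse(summary, collab_targets)))
    values = [v for _, v in log]
    i_best = int(np.argmin(values))
    return FitResult(
        best_params=params.replace(p_cue=float(grid[i_best])),
        objective_value=float(values[i_best]),
        evaluation_log=log,
        seed=seed,
        n_sims_per_eval=n_sims_per_eval,
    )
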