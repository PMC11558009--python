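"""Experiment orchestration: matched nominal/collaborative simulations at
multiple group sizes and the bundled summary tables."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cmr import CMRParams
from .context import (
    ContextTrajectorySet,
    convergence_performance_correlation,
    groupsize_permutation_test,
    pairwise_context_similarity,
    within_subject_similarity,
)
from .metrics import collaborative_inhibition, summarize
from .semantic import SemanticSpace, generate_synthetic_space
from .simulate import simulate_collaborative_group, simulate_nominal_group

__all__ = ["ExperimentConfig", "generate_experiment", "run_figure_suite"]


@dataclass
class ExperimentConfig:
    """Sizes, counts, parameters and seeds for one simulated experiment.

    The full preset mirrors the reference study design (60-item lists;
    48/32/24/12/12 groups of sizes 2/3/4/8/16); the desk preset trades list
    length and group counts for wall-clock time.
    """

    list_length: int = 60
    group_sizes: list = field(default_factory=lambda: [2, 3, 4, 8, 16])
    groups_per_size: list = field(default_factory=lambda: [48, 32, 24, 12, 12])
    params: CMRParams = field(default_factory=CMRParams)
    dim: int = 16
    n_clusters: int | None = None  # None -> one cluster per item (unstructured)
    cluster_spread: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if len(self.group_sizes) != len(self.groups_per_size):
            raise ValueError("group_sizes and groups_per_size must align")
        if any(s < 1 for s in self.group_sizes) or any(g < 1 for g in self.groups_per_size):
            raise ValueError("sizes and counts must be positive")
        if self.list_length < 2:
            raise ValueError("list_length must be >= 2")

    @classmethod
    def desk(cls, **overrides) -> "ExperimentConfig":
        """Reduced-scale preset for tests and quick runs."""
        defaults = dict(
            list_length=20,
            group_sizes=[2, 3, 4, 8, 16],
            groups_per_size=[20, 20, 20, 20, 20],
            dim=16,
            n_clusters=4,
            cluster_spread=0.1,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def make_space(self) -> SemanticSpace:
        return generate_synthetic_space(
            self.list_length,
            self.dim,
            n_clusters=self.n_clusters,
            cluster_spread=self.cluster_spread,
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        return {
            "list_length": self.list_length,
            "group_sizes": list(self.group_sizes),
            "groups_per_size": list(self.groups_per_size),
            "params": self.params.to_dict(),
            "dim": self.dim,
            "n_clusters": self.n_clusters,
            "cluster_spread": self.cluster_spread,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "params" in d and isinstance(d["params"], dict):
            d["params"] = CMRParams.from_dict(d["params"])
        return cls(**d)


def _group_seeds(config: ExperimentConfig):
    """Paired per-(size, group) seeds: nominal and collaborative share one."""
    ss = np.random.SeedSequence(config.seed)
    out = {}
    children = ss.spawn(len(config.group_sizes))
    for size, n_groups, child in zip(config.group_sizes, config.groups_per_size, children):
        out[size] = child.generate_state(n_groups)
    return out


def generate_experiment(config: ExperimentConfig, space: SemanticSpace | None = None):
    """Simulate matched nominal and collaborative groups for every size.

    Returns ``(nominal, collaborative)`` dicts mapping group size to lists of
    transcripts.  Group k of each size uses the same base seed in both
    conditions (paired design); all randomization is derived from
    ``config.seed``.
    """
    space = space or config.make_space()
    seeds = _group_seeds(config)
    nominal, collaborative = {}, {}
    for size in config.group_sizes:
        nominal[size] = []
        collaborative[size] = []
        for k, s in enumerate(seeds[size]):
            t = simulate_nominal_group(space, config.params, size, seed=int(s))
            t.group_id = k
            nominal[size].append(t)
            if size >= 2:
                t = simulate_collaborative_group(space, config.params, size, seed=int(s))
                t.group_id = k
                collaborative[size].append(t)
    return nominal, collaborative


def _similarity_curve(transcripts, max_pos: int) -> np.ndarray:
    curves = []
    for t in transcripts:
        ts = ContextTrajectorySet.from_transcript(t, min_length=max_pos + 1)
        curves.append(
            [pairwise_context_similarity(ts, p) for p in range(max_pos + 1)]
        )
    return np.mean(curves, axis=0)


def run_figure_suite(
    config: ExperimentConfig,
    out_dir=None,
    p_cue_levels=(0.0, 0.3, 0.6, 1.0),
    eps_d_levels=(0.05, 0.5, 5.0),
    similarity_max_pos: int = 10,
    corr_n_groups: int | None = None,
) -> dict:
    """Compute the full set of summary tables from one configuration.

    Emits behavioral summaries per condition, the inhibition-by-size table,
    pairwise context-similarity curves across listening probabilities, the
    convergence-performance correlation, the within-subject similarity by
    size (with its permutation test), and the stopping-scale sweep.
    Deterministic given ``config.seed``; writes CSV/JSON tables when
    ``out_dir`` is given.
    """
    space = config.make_space()
    nominal, collaborative = generate_experiment(config, space)
    all_nominal = [t for ts in nominal.values() for t in ts]
    all_collab = [t for ts in collaborative.values() for t in ts]

    sizes, diffs, ses = collaborative_inhibition(nominal, collaborative)
    bundle = {
        "config": config.to_dict(),
        "nominal_summary": summarize(all_nominal, space, group_scope=False).to_dict(),
        "collaborative_summary": summarize(all_collab, space, group_scope=True).to_dict(),
        "inhibition_by_size": {
            "size": sizes.tolist(),
            "difference": diffs.tolist(),
            "se": ses.tolist(),
        },
    }

    # context-similarity curves across listening probabilities (one mid size)
    sim_size = config.group_sizes[min(1, len(config.group_sizes) - 1)]
    n_sim_groups = config.groups_per_size[config.group_sizes.index(sim_size)]
    ss = np.random.SeedSequence(config.seed + 1)
    sim_seeds = ss.generate_state(n_sim_groups)
    curves = {}
    nominal_curve = _similarity_curve(
        [simulate_nominal_group(space, config.params, sim_size, seed=int(s)) for s in sim_seeds],
        similarity_max_pos,
    )
    curves["nominal"] = nominal_curve.tolist()
    for p_cue in p_cue_levels:
        ts = [
            simulate_collaborative_group(
                space, config.params.replace(p_cue=p_cue), sim_size, seed=int(s)
            )
            for s in sim_seeds
        ]
        curves[f"p_cue={p_cue:g}"] = _similarity_curve(ts, similarity_max_pos).tolist()
    bundle["context_similarity_curves"] = {"group_size": sim_size, "curves": curves}

    # convergence-performance correlation at the largest size
    big = max(config.group_sizes)
    n_corr = corr_n_groups or max(10, config.groups_per_size[config.group_sizes.index(big)])
    rho, pval, _, _ = convergence_performance_correlation(
        space, config.params, big, n_groups=n_corr, seed=config.seed + 2
    )
    bundle["convergence_performance"] = {"group_size": big, "rho": rho, "p": pval}

    # within-subject similarity by size + permutation test against inhibition;
    # collaborative snapshots are group-event aligned, matching the
    # convergence metric's output-position axis
    wss = []
    for size in sizes:
        vals = []
        for t in collaborative[size]:
            ts = ContextTrajectorySet.from_transcript(t, min_length=similarity_max_pos + 1)
            for g in range(t.group_size):
                vals.append(within_subject_similarity(ts.array[g], after=similarity_max_pos))
        wss.append(float(np.mean(vals)))
    perm_p = (
        groupsize_permutation_test(diffs, wss, exhaustive=len(sizes) <= 6, seed=config.seed)
        if len(sizes) >= 3
        else None
    )
    bundle["within_subject_similarity"] = {
        "size": sizes.tolist(),
        "similarity": wss,
        "permutation_p": perm_p,
    }

    # stopping-scale sweep
    sweep = {}
    for eps_d in eps_d_levels:
        cfg = replace(config, params=config.params.replace(eps_d=eps_d))
        nom_e, col_e = generate_experiment(cfg, space)
        s_e, d_e, se_e = collaborative_inhibition(nom_e, col_e)
        nom_prop = [
            float(np.mean([len({e.item for e in t.recall_events()}) / t.list_length
                           for t in nom_e[size]]))
            for size in s_e
        ]
        sweep[f"eps_d={eps_d:g}"] = {
            "size": s_e.tolist(),
            "inhibition": d_e.tolist(),
            "se": se_e.tolist(),
            "nominal_prop": nom_prop,
        }
    bundle["eps_d_sweep"] = sweep

    if out_dir is not None:
        _write_bundle(bundle, out_dir)
    return bundle


def _write_bundle(bundle: dict, out_dir) -> None:
    import hashlib
    import sys
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "bundle.json", "w", encoding="utf-8") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True)
    cfg = bundle["config"]
    run_log = {
        "seed": cfg["seed"],
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    with open(out / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(run_log, fh, indent=2)
    inh = bundle["inhibition_by_size"]
    pd.DataFrame(inh).to_csv(out / "inhibition_by_size.csv", index=False)
    for cond in ("nominal", "collaborative"):
        s = bundle[f"{cond}_summary"]
        pd.DataFrame(
            {"position": np.arange(1, len(s["spc"]) + 1), "spc": s["spc"], "pfr": s["pfr"]}
        ).to_csv(out / f"{cond}_curves.csv", index=False)
    wss = bundle["within_subject_similarity"]
    pd.DataFrame({"size": wss["size"], "similarity": wss["similarity"]}).to_csv(
        out / "within_subject_similarity.csv", index=False
    )
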