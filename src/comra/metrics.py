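"""Behavioral summary statistics for simulated or empirical transcripts.

Serial position curve, probability of first recall, semantic similarity by
output lag (own- and group-scope), proportion recalled, and the
collaborative-inhibition contrast between conditions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .semantic import SemanticSpace
from .simulate import GroupTranscript, pooled_unique_recall

__all__ = [
    "BehavioralSummary",
    "serial_position_curve",
    "probability_first_recall",
    "semantic_lag_values",
    "semantic_similarity_by_lag",
    "proportion_recalled",
    "collaborative_inhibition",
    "lag1_vs_lag4_test",
    "lag_crp",
    "summarize",
]


@dataclass
class BehavioralSummary:
    """The behavioral surfaces used for fitting and reporting."""

    spc: np.ndarray
    pfr: np.ndarray
    sem_by_lag_own: np.ndarray  # means at lags 1..max_lag
    sem_by_lag_group: np.ndarray | None
    prop_recalled: float

    def to_dict(self) -> dict:
        return {
            "spc": np.asarray(self.spc).tolist(),
            "pfr": np.asarray(self.pfr).tolist(),
            "sem_by_lag_own": np.asarray(self.sem_by_lag_own).tolist(),
            "sem_by_lag_group": (
                None
                if self.sem_by_lag_group is None
                else np.asarray(self.sem_by_lag_group).tolist()
            ),
            "prop_recalled": float(self.prop_recalled),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "BehavioralSummary":
        return cls(
            spc=np.array(d["spc"]),
            pfr=np.array(d["pfr"]),
            sem_by_lag_own=np.array(d["sem_by_lag_own"]),
            sem_by_lag_group=(
                None if d.get("sem_by_lag_group") is None else np.array(d["sem_by_lag_group"])
            ),
            prop_recalled=float(d["prop_recalled"]),
        )

    @classmethod
    def from_json(cls, path) -> "BehavioralSummary":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _require_orders(transcripts):
    for t in transcripts:
        if not t.study_orders or any(o is None for o in t.study_orders):
            raise ValueError("transcripts must carry per-agent study orders")


def serial_position_curve(transcripts) -> np.ndarray:
    """Per-study-position recall probability, pooled over agents.

    Positions index each agent's *own* randomized study order; an item
    counts as recalled for an agent only if that agent itself produced it.
    """
    transcripts = list(transcripts)
    _require_orders(transcripts)
    L = transcripts[0].list_length
    counts = np.zeros(L)
    total = 0
    for t in transcripts:
        for g, order in enumerate(t.study_orders):
            recalled = set(t.own_recalls(g))
            for pos, item in enumerate(np.asarray(order)):
                if item in recalled:
                    counts[pos] += 1
            total += 1
    return counts / total if total else counts


def probability_first_recall(transcripts) -> np.ndarray:
    """Distribution of the study position of each agent's first own recall."""
    transcripts = list(transcripts)
    _require_orders(transcripts)
    L = transcripts[0].list_length
    counts = np.zeros(L)
    for t in transcripts:
        for g, order in enumerate(t.study_orders):
            own = t.own_recalls(g)
            if not own:
                continue
            pos = int(np.flatnonzero(np.asarray(order) == own[0])[0])
            counts[pos] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts


def _sequences(transcripts, scope: str):
    for t in transcripts:
        if scope == "own":
            for g in range(t.group_size):
                yield t.own_recalls(g)
        elif scope == "group":
            yield [e.item for e in t.recall_events()]
        else:
            raise ValueError("scope must be 'own' or 'group'")


def semantic_lag_values(transcripts, space: SemanticSpace, max_lag: int = 4, scope: str = "own"):
    """Raw pairwise cosines per output lag 1..max_lag.

    ``scope='own'`` walks each agent's own recall sequence; ``scope='group'``
    walks the group's pooled chronological output.  Sequences shorter than
    lag+1 contribute nothing at that lag.
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    values = {lag: [] for lag in range(1, max_lag + 1)}
    for seq in _sequences(transcripts, scope):
        for lag in range(1, max_lag + 1):
            for t_out in range(lag, len(seq)):
                values[lag].append(space.similarity[seq[t_out], seq[t_out - lag]])
    return {lag: np.array(v) for lag, v in values.items()}


def semantic_similarity_by_lag(
    transcripts, space: SemanticSpace, max_lag: int = 4, scope: str = "own"
):
    """Mean cosine and standard error (over pairs) at each lag 1..max_lag."""
    values = semantic_lag_values(transcripts, space, max_lag=max_lag, scope=scope)
    means = np.array(
        [values[lag].mean() if values[lag].size else np.nan for lag in sorted(values)]
    )
    sems = np.array(
        [
            values[lag].std(ddof=1) / np.sqrt(values[lag].size) if values[lag].size > 1 else np.nan
            for lag in sorted(values)
        ]
    )
    return means, sems


def proportion_recalled(t: GroupTranscript) -> float:
    """Unique items recalled by the group divided by list length."""
    return len(pooled_unique_recall(t)) / t.list_length


def collaborative_inhibition(nominal: dict, collaborative: dict):
    """Per-group-size mean nominal-minus-collaborative proportion recalled.

    Both inputs map group size -> list of transcripts.  Returns
    ``(sizes, differences, pooled standard errors)``.
    """
    sizes = sorted(nominal)
    if sorted(collaborative) != sizes:
        raise ValueError("group sizes must match across conditions")
    diffs, ses = [], []
    for size in sizes:
        pn = np.array([proportion_recalled(t) for t in nominal[size]])
        pc = np.array([proportion_recalled(t) for t in collaborative[size]])
        diffs.append(pn.mean() - pc.mean())
        se_n = pn.std(ddof=1) / np.sqrt(pn.size) if pn.size > 1 else 0.0
        se_c = pc.std(ddof=1) / np.sqrt(pc.size) if pc.size > 1 else 0.0
        ses.append(float(np.hypot(se_n, se_c)))
    return np.array(sizes), np.array(diffs), np.array(ses)


def lag1_vs_lag4_test(lag1_values, lag4_values):
    """Welch two-sample t test of lag-1 vs lag-4 cosine populations.

    Returns ``(t, df, p)`` with Welch–Satterthwaite degrees of freedom.
    """
    x = np.asarray(lag1_values, dtype=float)
    y = np.asarray(lag4_values, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two values per lag")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        raise ValueError("degenerate variance in both samples")
    res = stats.ttest_ind(x, y, equal_var=False)
    vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
    df = (vx + vy) ** 2 / (vx**2 / (x.size - 1) + vy**2 / (y.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def lag_crp(transcripts, max_lag: int = 5) -> np.ndarray:
    """Conditional response probability by temporal (study-position) lag.

    Auxiliary utility: actual / possible transition counts within each
    agent's own sequence, indexed -max_lag..+max_lag (lag 0 is NaN).
    """
    transcripts = list(transcripts)
    _require_orders(transcripts)
    actual = np.zeros(2 * max_lag + 1)
    possible = np.zeros(2 * max_lag + 1)
    for t in transcripts:
        for g, order in enumerate(t.study_orders):
            pos_of = {int(item): p for p, item in enumerate(np.asarray(order))}
            seq = t.own_recalls(g)
            seen = set()
            for k in range(len(seq) - 1):
                seen.add(seq[k])
                cur = pos_of[seq[k]]
                for cand, pos in pos_of.items():
                    if cand in seen:
                        continue
                    lag = pos - cur
                    if abs(lag) <= max_lag:
                        possible[lag + max_lag] += 1
                nxt = pos_of[seq[k + 1]] - cur
                if abs(nxt) <= max_lag:
                    actual[nxt + max_lag] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        crp = actual / possible
    crp[max_lag] = np.nan
    return crp


def summarize(
    transcripts, space: SemanticSpace, max_lag: int = 4, group_scope: bool | None = None
) -> BehavioralSummary:
    """Bundle the fitting surfaces for a collection of transcripts."""
    transcripts = list(transcripts)
    if group_scope is None:
        group_scope = any(t.condition == "collaborative" for t in transcripts)
    own_means, _ = semantic_similarity_by_lag(transcripts, space, max_lag, scope="own")
    group_means = None
    if group_scope:
        group_means, _ = semantic_similarity_by_lag(transcripts, space, max_lag, scope="group")
    props = np.array([proportion_recalled(t) for t in transcripts])
    return BehavioralSummary(
        spc=serial_position_curve(transcripts),
        pfr=probability_first_recall(transcripts),
        sem_by_lag_own=own_means,
        sem_by_lag_group=group_means,
        prop_recalled=float(props.mean()) if props.size else 0.0,
    )
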