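"""Nominal and collaborative group recall simulation.

Nominal groups are independent individuals whose outputs are pooled after
the fact.  Collaborative groups take turns in rounds: every novel recall is
broadcast, and each other active member independently attends to it with
probability ``p_cue``, drifting its own context toward the recalled item.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cmr import (
    CMRParams,
    NoItemsAvailable,
    encode_list,
    init_agent,
    recall_item_update,
    retrieval_activations,
    sample_recall,
    simulate_individual_recall,
    stop_probability,
)
from .semantic import SemanticSpace

__all__ = [
    "RecallEvent",
    "GroupTranscript",
    "simulate_nominal_group",
    "simulate_collaborative_group",
    "pooled_unique_recall",
    "transcripts_to_frame",
    "write_transcripts_csv",
    "read_transcripts_csv",
    "write_transcripts_json",
    "read_transcripts_json",
]

RECALL, PASS, STOP = "recall", "pass", "stop"


@dataclass(frozen=True)
class RecallEvent:
    """One turn's outcome in a group transcript."""

    round_index: int
    turn_index: int
    speaker: int
    action: str  # recall | pass | stop
    item: int | None = None
    novel: bool = False

    def __post_init__(self):
        if self.action not in (RECALL, PASS, STOP):
            raise ValueError(f"unknown action {self.action!r}")
        if (self.action == RECALL) != (self.item is not None):
            raise ValueError("action == 'recall' iff item is present")


@dataclass
class GroupTranscript:
    """Ordered recall events for one group plus per-agent bookkeeping.

    ``trajectories`` holds one (T+1, d+1) array of context snapshots per
    agent.  For collaborative groups snapshots align to group events (index 0
    is the start-of-recall context); for nominal groups they align to the
    agent's own recall count, padded with the final context to a common
    length.
    """

    condition: str  # nominal | collaborative
    group_size: int
    list_length: int
    events: list = field(default_factory=list)
    study_orders: list = field(default_factory=list)
    trajectories: list = field(default_factory=list)
    group_id: int = 0

    def own_recalls(self, agent: int) -> list:
        return [e.item for e in self.events if e.speaker == agent and e.action == RECALL]

    def recall_events(self) -> list:
        return [e for e in self.events if e.action == RECALL]


def _make_agents(space, params, group_size, rng) -> list:
    agents = []
    for _ in range(group_size):
        agent = init_agent(space, params)
        order = rng.permutation(space.n_items)
        encode_list(agent, order, params)
        agents.append(agent)
    return agents


def simulate_nominal_group(
    space: SemanticSpace, params: CMRParams, group_size: int, seed=None
) -> GroupTranscript:
    """Simulate ``group_size`` independent individuals over the same list.

    Each agent studies its own randomized order and recalls alone; the
    transcript concatenates the individual sequences with agent tags.
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    rng = np.random.default_rng(seed)
    agents = _make_agents(space, params, group_size, rng)
    events = []
    submitted: set[int] = set()
    turn = 0
    for g, agent in enumerate(agents):
        seq = simulate_individual_recall(agent, params, rng)
        for item in seq:
            events.append(
                RecallEvent(0, turn, g, RECALL, item=item, novel=item not in submitted)
            )
            submitted.add(item)
            turn += 1
    max_len = max(len(a.context_trajectory) for a in agents)
    trajectories = [_padded(a.context_trajectory, max_len) for a in agents]
    return GroupTranscript(
        condition="nominal",
        group_size=group_size,
        list_length=space.n_items,
        events=events,
        study_orders=[a.study_order for a in agents],
        trajectories=trajectories,
    )


def simulate_collaborative_group(
    space: SemanticSpace, params: CMRParams, group_size: int, seed=None
) -> GroupTranscript:
    """Simulate one turn-taking collaborative group.

    Recall proceeds in rounds; within each round the still-active agents act
    in a fresh random order.  On its turn an agent either stops for good
    (hazard evaluated on its own output count) or emits one item sampled
    excluding only its *own* prior recalls.  A novel item is broadcast:
    every other active agent independently attends with probability
    ``p_cue`` and drifts its context toward the item.  The session ends when
    all agents have stopped.
    """
    if group_size < 2:
        raise ValueError("collaborative groups need group_size >= 2")
    rng = np.random.default_rng(seed)
    agents = _make_agents(space, params, group_size, rng)
    own_sets = [set() for _ in range(group_size)]
    submitted: set[int] = set()
    events: list[RecallEvent] = []
    snapshots: list[list[np.ndarray]] = [[a.context.copy()] for a in agents]
    round_idx = 0
    while True:
        active = [g for g in range(group_size) if not agents[g].stopped]
        if not active:
            break
        order = [int(g) for g in rng.permutation(active)]
        for turn, g in enumerate(order):
            agent = agents[g]
            if agent.stopped:
                continue
            event = None
            if rng.random() < stop_probability(len(agent.recalled_own), params):
                agent.stopped = True
                event = RecallEvent(round_idx, turn, g, STOP)
            else:
                try:
                    item = sample_recall(
                        retrieval_activations(agent), own_sets[g], params.tau, rng
                    )
                except NoItemsAvailable:
                    agent.stopped = True
                    event = RecallEvent(round_idx, turn, g, STOP)
                else:
                    novel = item not in submitted
                    submitted.add(item)
                    own_sets[g].add(item)
                    agent.recalled_own.append(item)
                    event = RecallEvent(round_idx, turn, g, RECALL, item=item, novel=novel)
                    recall_item_update(agent, item, params)
                    if novel:
                        for h in range(group_size):
                            if h == g or agents[h].stopped:
                                continue
                            if rng.random() < params.p_cue:
                                recall_item_update(agents[h], item, params)
                                agents[h].heard.append(item)
            events.append(event)
            for h in range(group_size):
                snapshots[h].append(agents[h].context.copy())
        round_idx += 1
    trajectories = [np.array(s) for s in snapshots]
    return GroupTranscript(
        condition="collaborative",
        group_size=group_size,
        list_length=space.n_items,
        events=events,
        study_orders=[a.study_order for a in agents],
        trajectories=trajectories,
    )


def _padded(snaps: list, length: int) -> np.ndarray:
    arr = np.array(snaps)
    if arr.shape[0] < length:
        pad = np.repeat(arr[-1:], length - arr.shape[0], axis=0)
        arr = np.vstack([arr, pad])
    return arr


def pooled_unique_recall(t: GroupTranscript) -> set:
    """Distinct items recalled by anyone in the group (duplicates excluded)."""
    return {e.item for e in t.events if e.action == RECALL}


# ---------------------------------------------------------------------------
# transcript I/O

_CSV_COLUMNS = [
    "condition",
    "group_id",
    "group_size",
    "round",
    "turn",
    "agent",
    "action",
    "item",
    "novel",
]


def transcripts_to_frame(transcripts) -> pd.DataFrame:
    rows = []
    for t in transcripts:
        for e in t.events:
            rows.append(
                {
                    "condition": t.condition,
                    "group_id": t.group_id,
                    "group_size": t.group_size,
                    "round": e.round_index,
                    "turn": e.turn_index,
                    "agent": e.speaker,
                    "action": e.action,
                    "item": -1 if e.item is None else e.item,
                    "novel": bool(e.novel),
                }
            )
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def write_transcripts_csv(transcripts, path) -> None:
    transcripts_to_frame(transcripts).to_csv(path, index=False)


def read_transcripts_csv(path, list_length: int) -> list:
    """Read transcripts back from CSV (events only; no trajectories)."""
    df = pd.read_csv(path)
    out = []
    for (cond, gid), grp in df.groupby(["condition", "group_id"], sort=True):
        events = [
            RecallEvent(
                int(r["round"]),
                int(r["turn"]),
                int(r["agent"]),
                str(r["action"]),
                item=None if int(r["item"]) < 0 else int(r["item"]),
                novel=bool(r["novel"]),
            )
            for _, r in grp.iterrows()
        ]
        out.append(
            GroupTranscript(
                condition=str(cond),
                group_size=int(grp["group_size"].iloc[0]),
                list_length=list_length,
                events=events,
                group_id=int(gid),
            )
        )
    return out


def write_transcripts_json(transcripts, path, include_trajectories: bool = False) -> None:
    payload = []
    for t in transcripts:
        entry = {
            "condition": t.condition,
            "group_id": t.group_id,
            "group_size": t.group_size,
            "list_length": t.list_length,
            "study_orders": [np.asarray(o).tolist() for o in t.study_orders],
            "events": [
                {
                    "round": e.round_index,
                    "turn": e.turn_index,
                    "agent": e.speaker,
                    "action": e.action,
                    "item": e.item,
                    "novel": e.novel,
                }
                for e in t.events
            ],
        }
        if include_trajectories:
            entry["trajectories"] = [np.asarray(tr).tolist() for tr in t.trajectories]
        payload.append(entry)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def read_transcripts_json(path) -> list:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    out = []
    for entry in payload:
        events = [
            RecallEvent(
                e["round"], e["turn"], e["agent"], e["action"], item=e["item"], novel=e["novel"]
            )
            for e in entry["events"]
        ]
        out.append(
            GroupTranscript(
                condition=entry["condition"],
                group_size=entry["group_size"],
                list_length=entry["list_length"],
                events=events,
                study_orders=[np.array(o) for o in entry["study_orders"]],
                trajectories=[np.array(tr) for tr in entry.get("trajectories", [])],
                group_id=entry["group_id"],
            )
        )
    return out
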