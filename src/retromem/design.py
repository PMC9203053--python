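"""Stimulus construction, condition counterbalancing, and learning schedules.

The experimental unit is a *quartet* {cue, Δcue, target, Δtarget}: a base
pair (cue–target) plus the related words that replace the cue and/or target
during secondary-pair learning.  Ninety relation pairs of graded semantic
relatedness are split into terciles, crossed into a 3×3 grid of cue- by
target-relatedness cells, and paired within cells into 45 quartets (5 per
cell).  Five within-subject conditions are rotated over quartets every five
subjects so that each quartet is observed in each condition by exactly
n_subjects/5 subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "Quartet",
    "StimulusSet",
    "CounterbalancePlan",
    "LearningSchedule",
    "build_grid",
    "counterbalance",
    "secondary_item",
    "yoke",
]

#: The five within-subject secondary-learning conditions, in rotation order.
CONDITIONS = ("NoDelta", "DeltaTarget", "DeltaCue", "DeltaBoth", "control")

TERCILE_LABELS = ("l", "m", "h")


@dataclass(frozen=True)
class Quartet:
    id: int
    cue: str
    delta_cue: str
    target: str
    delta_target: str
    r_cue: float
    r_target: float
    grid_cell: tuple[str, str]  # (cue tercile, target tercile)
    direction: str = "directed"  # relatedness direction bookkeeping

    def __post_init__(self):
        words = {self.cue, self.delta_cue, self.target, self.delta_target}
        if len(words) != 4:
            raise ValueError(f"quartet {self.id}: four words must be distinct")


@dataclass
class StimulusSet:
    quartets: list[Quartet]
    relatedness_metric: str = "AS"
    relatedness_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        if len(self.quartets) != 45:
            raise ValueError(f"expected 45 quartets, got {len(self.quartets)}")
        cells: dict[tuple[str, str], int] = {}
        for q in self.quartets:
            cells[q.grid_cell] = cells.get(q.grid_cell, 0) + 1
        if sorted(cells.values()) != [5] * 9:
            raise ValueError("expected exactly 5 quartets per grid cell")

    def __len__(self) -> int:
        return len(self.quartets)

    def __iter__(self):
        return iter(self.quartets)

    def by_id(self, qid: int) -> Quartet:
        return next(q for q in self.quartets if q.id == qid)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": q.id,
                "cue": q.cue,
                "delta_cue": q.delta_cue,
                "target": q.target,
                "delta_target": q.delta_target,
                "r_cue": q.r_cue,
                "r_target": q.r_target,
                "cell": "".join(q.grid_cell),
                "direction": q.direction,
            }
            for q in self.quartets
        ]
        return pd.DataFrame(rows)


@dataclass
class CounterbalancePlan:
    """subject index → {quartet id: condition} assignments."""

    assignments: dict[int, dict[int, str]]
    n_subjects: int = field(init=False)

    def __post_init__(self):
        self.n_subjects = len(self.assignments)

    def condition(self, subject: int, quartet_id: int) -> str:
        return self.assignments[subject][quartet_id]

    def subjects_with(self, quartet_id: int, condition: str) -> list[int]:
        return [
            s
            for s, asg in self.assignments.items()
            if asg[quartet_id] == condition
        ]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"subject": s, "quartet_id": q, "condition": c}
            for s, asg in sorted(self.assignments.items())
            for q, c in sorted(asg.items())
        ]
        return pd.DataFrame(rows)


@dataclass
class LearningSchedule:
    """Ordered learning trials for one subject and phase.

    Each trial is (subject, phase, pair id, trial type, round index) with
    trial type ``encode`` (initial presentation), ``retrieve``
    (retrieval-to-criterion attempt), or ``restudy`` (yoked study-only).
    """

    trials: pd.DataFrame  # columns: subject, phase, pair_id, trial_type, round
    complete: bool = True  # all pairs reached criterion (dropped out)

    def __len__(self) -> int:
        return len(self.trials)


# ---------------------------------------------------------------------------
# stimulus grid
# ---------------------------------------------------------------------------

def build_grid(
    relation_pairs: Sequence[tuple[str, str, float]],
    seed: int,
    relatedness_metric: str = "AS",
    direction: str = "directed",
) -> StimulusSet:
    """Assemble 45 quartets from 90 graded relation pairs.

    The 90 pairs are sorted into relatedness terciles (30 each; boundary ties
    broken by a stable sort on (relatedness, words) for determinism).  Each
    tercile is randomly split into 15 cue pairs and 15 target pairs; each
    tercile's cue pairs are randomly dealt 5 apiece to the three target
    levels and vice versa, yielding 9 grid cells with 5 cue and 5 target
    pairs each; within a cell, cue and target pairs are randomly matched
    into 5 quartets.  All randomization draws from one seeded generator in a
    fixed call order, so the result is reproducible from (inputs, seed).

    ``relation_pairs`` entries are ``(base word, new word, relatedness)``:
    the base word serves as cue or target, the new word as Δcue or Δtarget.
    """
    if len(relation_pairs) != 90:
        raise ValueError(f"expected exactly 90 relation pairs, got {len(relation_pairs)}")
    words = [w for a, b, _ in relation_pairs for w in (a, b)]
    if len(set(words)) != len(words):
        raise ValueError("duplicate words across the 90 relation pairs")
    if not all(np.isfinite(r) for _, _, r in relation_pairs):
        raise ValueError("relatedness values must be finite")

    rng = np.random.default_rng(seed)
    ranked = sorted(relation_pairs, key=lambda p: (p[2], p[0], p[1]))
    terciles = [ranked[0:30], ranked[30:60], ranked[60:90]]

    # per tercile: random 15/15 split into cue pairs and target pairs
    cue_pairs: dict[str, list] = {}
    target_pairs: dict[str, list] = {}
    for label, members in zip(TERCILE_LABELS, terciles):
        perm = rng.permutation(30)
        cue_pairs[label] = [members[i] for i in perm[:15]]
        target_pairs[label] = [members[i] for i in perm[15:]]

    # deal each tercile's 15 cue pairs to the three target levels (5 each),
    # and each tercile's 15 target pairs to the three cue levels (5 each)
    cell_cues: dict[tuple[str, str], list] = {}
    cell_targets: dict[tuple[str, str], list] = {}
    for c_label in TERCILE_LABELS:
        perm = rng.permutation(15)
        for j, t_label in enumerate(TERCILE_LABELS):
            cell_cues[(c_label, t_label)] = [
                cue_pairs[c_label][i] for i in perm[5 * j : 5 * j + 5]
            ]
    for t_label in TERCILE_LABELS:
        perm = rng.permutation(15)
        for j, c_label in enumerate(TERCILE_LABELS):
            cell_targets[(c_label, t_label)] = [
                target_pairs[t_label][i] for i in perm[5 * j : 5 * j + 5]
            ]

    quartets: list[Quartet] = []
    qid = 0
    for c_label in TERCILE_LABELS:
        for t_label in TERCILE_LABELS:
            cues = cell_cues[(c_label, t_label)]
            tgts = cell_targets[(c_label, t_label)]
            perm = rng.permutation(5)
            for cue_pair, k in zip(cues, perm):
                tgt_pair = tgts[k]
                quartets.append(
                    Quartet(
                        id=qid,
                        cue=cue_pair[0],
                        delta_cue=cue_pair[1],
                        target=tgt_pair[0],
                        delta_target=tgt_pair[1],
                        r_cue=float(cue_pair[2]),
                        r_target=float(tgt_pair[2]),
                        grid_cell=(c_label, t_label),
                        direction=direction,
                    )
                )
                qid += 1

    values = [r for _, _, r in relation_pairs]
    return StimulusSet(
        quartets=quartets,
        relatedness_metric=relatedness_metric,
        relatedness_range=(float(min(values)), float(max(values))),
    )


# ---------------------------------------------------------------------------
# counterbalancing
# ---------------------------------------------------------------------------

def counterbalance(stimuli: StimulusSet, n_subjects: int) -> CounterbalancePlan:
    """Rotate quartets through the five conditions every five subjects.

    Within each grid cell the five quartets occupy five rotation slots;
    subject ``s`` (counterbalance index ``s mod 5``) sees slot ``j`` in
    condition ``(j + s) mod 5``.  Every subject therefore holds 9 quartets
    per condition (one per cell), and over any block of five consecutive
    counterbalance indices each quartet visits all five conditions once.
    """
    if n_subjects % 5 != 0:
        raise ValueError(f"n_subjects must be a multiple of 5, got {n_subjects}")
    slots: dict[int, int] = {}
    by_cell: dict[tuple[str, str], list[Quartet]] = {}
    for q in stimuli:
        by_cell.setdefault(q.grid_cell, []).append(q)
    for members in by_cell.values():
        for j, q in enumerate(sorted(members, key=lambda q: q.id)):
            slots[q.id] = j
    assignments = {
        s: {qid: CONDITIONS[(slot + s) % 5] for qid, slot in slots.items()}
        for s in range(n_subjects)
    }
    return CounterbalancePlan(assignments=assignments)


def secondary_item(quartet: Quartet, condition: str) -> tuple[str, str] | None:
    """The (cue, target) shown during secondary learning, or None for control."""
    if condition == "NoDelta":
        return (quartet.cue, quartet.target)
    if condition == "DeltaTarget":
        return (quartet.cue, quartet.delta_target)
    if condition == "DeltaCue":
        return (quartet.delta_cue, quartet.target)
    if condition == "DeltaBoth":
        return (quartet.delta_cue, quartet.delta_target)
    if condition == "control":
        return None
    raise ValueError(f"unknown condition {condition!r}")


# ---------------------------------------------------------------------------
# learning schedules
# ---------------------------------------------------------------------------

def build_retrieval_schedule(
    subject: int,
    phase: str,
    pair_ids: Sequence[int],
    trials_to_criterion: dict[int, int],
    rng: np.random.Generator,
) -> LearningSchedule:
    """Retrieval-to-criterion schedule: one encode round, then retrieval
    rounds from which a pair drops out after its first correct retrieval
    (round index = its trials-to-criterion count)."""
    rows = []
    order = list(rng.permutation(list(pair_ids)))
    for pid in order:
        rows.append((subject, phase, int(pid), "encode", 0))
    round_idx = 1
    remaining = [p for p in order if trials_to_criterion[p] >= 1]
    while remaining:
        for pid in rng.permutation(remaining):
            rows.append((subject, phase, int(pid), "retrieve", round_idx))
        remaining = [p for p in remaining if trials_to_criterion[p] > round_idx]
        round_idx += 1
    trials = pd.DataFrame(
        rows, columns=["subject", "phase", "pair_id", "trial_type", "round"]
    )
    return LearningSchedule(trials=trials, complete=True)


def yoke(donor_schedule: LearningSchedule, subject: int | None = None) -> LearningSchedule:
    """Study-only schedule yoked to a retrieval-to-criterion donor.

    Pair order and per-round dropout are copied exactly; every retrieval
    trial becomes a restudy trial.  Raises if the donor is incomplete (a
    pair never reached criterion).
    """
    if not donor_schedule.complete:
        raise ValueError("donor schedule is incomplete (pairs never reached criterion)")
    trials = donor_schedule.trials.copy()
    trials.loc[trials["trial_type"] == "retrieve", "trial_type"] = "restudy"
    if subject is not None:
        trials["subject"] = subject
    return LearningSchedule(trials=trials, complete=True)
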