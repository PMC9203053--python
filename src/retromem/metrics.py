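"""Behavioral measures: exclusions, memorability, dependence, intrusions,
learning efficiency.

Memorability of a pair in a condition is the proportion of the subjects who
held that pair in that condition (n_subjects/5 under the counterbalance) who
recalled it at final test; retroactive effect is memorability minus the same
pair's control-condition memorability.  Dependence of a base/secondary duo
is the across-subject proportion of both-correct-or-both-incorrect outcomes,
equal to one minus the normalized Hamming distance between the two binary
outcome vectors.  Its null reference comes from mismatched duos: the pair's
base vector against every other pair's secondary vector in the same
condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import CONDITIONS, CounterbalancePlan

__all__ = [
    "exclude_subjects",
    "memorability",
    "dependence",
    "dependence_table",
    "dependence_null",
    "exceedance_criterion",
    "intrusion_rate",
    "learning_efficiency",
]


@dataclass
class ExclusionResult:
    data: pd.DataFrame
    excluded: list[int]
    threshold: float


def exclude_subjects(
    data: pd.DataFrame,
    n_sd: float = 4.0,
    drop_zero_base: bool = False,
) -> ExclusionResult:
    """Drop subjects with overall accuracy below mean − n_sd·SD.

    Accuracy pools base and (non-control) secondary test outcomes.  The SD is
    the population SD over subjects; if it is zero (all subjects identical),
    nobody is excluded.  With ``drop_zero_base`` (the study-only rule),
    subjects with no correct base-test responses are excluded even when
    within the SD band.
    """
    if data["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    per_subject = (
        data.melt(
            id_vars="subject",
            value_vars=["base_correct", "secondary_correct"],
            value_name="correct",
        )
        .dropna(subset=["correct"])
        .groupby("subject")["correct"]
        .mean()
    )
    mean, sd = per_subject.mean(), per_subject.std(ddof=0)
    threshold = mean - n_sd * sd
    excluded = set(per_subject.index[per_subject < threshold]) if sd > 0 else set()
    if drop_zero_base:
        base_acc = data.groupby("subject")["base_correct"].sum()
        excluded |= set(base_acc.index[base_acc == 0])
    kept = data[~data["subject"].isin(excluded)].reset_index(drop=True)
    return ExclusionResult(data=kept, excluded=sorted(excluded), threshold=float(threshold))


def memorability(data: pd.DataFrame) -> pd.DataFrame:
    """Per (pair, condition) proportion correct M and retro effect ΔM.

    Returns one row per pair × condition with columns
    ``pair_id, condition, n, M, delta_M`` where ΔM = M − M_control of the
    same pair (NaN for the control rows themselves).  Raises if any
    (pair, condition) cell has no observations.
    """
    cells = (
        data.groupby(["pair_id", "condition"], sort=True)["base_correct"]
        .agg(n="size", M="mean")
        .reset_index()
    )
    full = pd.MultiIndex.from_product(
        [sorted(data["pair_id"].unique()), CONDITIONS],
        names=["pair_id", "condition"],
    )
    missing = full.difference(cells.set_index(["pair_id", "condition"]).index)
    if len(missing):
        raise ValueError(f"empty memorability cell(s): {list(missing[:5])}")
    control = cells[cells["condition"] == "control"].set_index("pair_id")["M"]
    cells["delta_M"] = cells["M"] - cells["pair_id"].map(control)
    cells.loc[cells["condition"] == "control", "delta_M"] = np.nan
    return cells


def dependence(base_row, secondary_row) -> float:
    """Both-or-neither agreement between two aligned binary outcome vectors.

    Equals 1 − Hamming(base, secondary)/n.
    """
    b = np.asarray(base_row, dtype=float)
    s = np.asarray(secondary_row, dtype=float)
    if b.shape != s.shape or b.ndim != 1:
        raise ValueError(f"aligned 1-D vectors required, got {b.shape} vs {s.shape}")
    if b.size == 0:
        raise ValueError("vectors must be non-empty")
    if not (np.isin(b, (0, 1)).all() and np.isin(s, (0, 1)).all()):
        raise ValueError("outcome vectors must be binary")
    return float(np.mean(b == s))


def _condition_vectors(
    data: pd.DataFrame, plan: CounterbalancePlan, condition: str
) -> tuple[dict[int, np.ndarray], dict[int, np.ndarray]]:
    """Base and secondary outcome vectors per pair within one condition.

    Each pair's vectors cover the subjects who held it in that condition,
    in ascending subject order; subjects with a missing outcome for the duo
    are dropped listwise.
    """
    base_vecs: dict[int, np.ndarray] = {}
    sec_vecs: dict[int, np.ndarray] = {}
    sub = data[data["condition"] == condition]
    for pid, grp in sub.groupby("pair_id"):
        grp = grp.sort_values("subject").dropna(
            subset=["base_correct", "secondary_correct"]
        )
        base_vecs[int(pid)] = grp["base_correct"].to_numpy(dtype=int)
        sec_vecs[int(pid)] = grp["secondary_correct"].to_numpy(dtype=int)
    return base_vecs, sec_vecs


def exceedance_criterion(n_pairs: int) -> float:
    """Fraction of mismatched duos the true duo must exceed: (n−2)/(n−1).

    With the 45-pair design this is 43/44 ≈ 0.977 — the true duo's
    dependence must beat all but one of the 44 mismatched values.
    """
    if n_pairs < 3:
        raise ValueError("need at least 3 pairs")
    return (n_pairs - 2) / (n_pairs - 1)


def dependence_null(
    data: pd.DataFrame,
    plan: CounterbalancePlan,
    pair_id: int,
    condition: str = "DeltaTarget",
) -> dict:
    """True-duo dependence, its mismatched-duo null, and the criterion.

    The null pairs the target pair's base outcome vector with every other
    pair's secondary outcome vector in the same condition (vectors aligned
    by within-condition subject order).  The criterion passes when the true
    dependence exceeds all but at most one null value.
    """
    base_vecs, sec_vecs = _condition_vectors(data, plan, condition)
    if len(base_vecs) < 3:
        raise ValueError("need at least 3 pairs for a mismatched null")
    if pair_id not in base_vecs:
        raise KeyError(f"pair {pair_id} absent from condition {condition}")
    b = base_vecs[pair_id]
    true_d = dependence(b, sec_vecs[pair_id])
    null = []
    for other, s in sec_vecs.items():
        if other == pair_id:
            continue
        m = min(len(b), len(s))
        null.append(dependence(b[:m], s[:m]))
    null = np.array(null)
    frac_exceeded = float(np.mean(true_d > null))
    criterion = exceedance_criterion(len(base_vecs))
    # the dependence value the true duo must beat: second-largest null value
    threshold_value = float(np.sort(null)[-2])
    return {
        "pair_id": pair_id,
        "condition": condition,
        "dependence": true_d,
        "null": null,
        "criterion_fraction": criterion,
        "fraction_exceeded": frac_exceeded,
        "passes": frac_exceeded >= criterion,
        "threshold_value": threshold_value,
    }


def dependence_table(
    data: pd.DataFrame, plan: CounterbalancePlan, condition: str = "DeltaTarget"
) -> pd.DataFrame:
    """Per-pair dependence with null thresholds for one condition.

    Columns: pair_id, condition, n, dependence, threshold_value, passes.
    The across-pair mean of ``threshold_value`` is the dotted threshold line
    drawn on dependence-vs-relatedness plots.
    """
    base_vecs, sec_vecs = _condition_vectors(data, plan, condition)
    rows = []
    for pid in sorted(base_vecs):
        res = dependence_null(data, plan, pid, condition)
        rows.append(
            {
                "pair_id": pid,
                "condition": condition,
                "n": len(base_vecs[pid]),
                "dependence": res["dependence"],
                "threshold_value": res["threshold_value"],
                "passes": res["passes"],
            }
        )
    return pd.DataFrame(rows)


def intrusion_rate(
    data: pd.DataFrame,
    stimuli,
    condition: str = "DeltaTarget",
    fuzzy_match: bool = False,
) -> pd.DataFrame:
    """Per-pair proportion of base-test responses equal to the secondary
    target (case-folded, whitespace-stripped exact match).

    ``fuzzy_match`` is accepted for interface symmetry but no typo-tolerant
    matcher is enabled by default.
    """
    if fuzzy_match:
        raise NotImplementedError("fuzzy matching is not implemented")
    delta_target = {q.id: q.delta_target.casefold().strip() for q in stimuli}
    sub = data[data["condition"] == condition]
    rows = []
    for pid, grp in sub.groupby("pair_id"):
        resp = grp["base_response"].fillna("").astype(str).str.casefold().str.strip()
        rows.append(
            {
                "pair_id": int(pid),
                "n": len(grp),
                "intrusion_rate": float((resp == delta_target[int(pid)]).mean()),
            }
        )
    return pd.DataFrame(rows)


def learning_efficiency(data: pd.DataFrame) -> pd.DataFrame:
    """Mean trials to criterion per (pair, condition) during secondary learning.

    Only meaningful for retrieval-to-criterion learning; raises on a
    study-only dataset (no learning measure exists there).
    """
    shown = data[data["condition"] != "control"]
    if shown["trials_to_criterion"].isna().all():
        raise ValueError("study-only dataset has no learning measure")
    out = (
        shown.groupby(["pair_id", "condition"])["trials_to_criterion"]
        .agg(n="size", mean_trials="mean")
        .reset_index()
    )
    return out
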