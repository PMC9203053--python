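"""Generative model of the paired-associate experiments.

The simulator encodes a recursive-reminders account of retroactive memory
effects: while learning a secondary pair, the subject may spontaneously be
reminded of the related base pair.  Reminder probability rises with the
semantic relatedness between old and new material; a reminder both
strengthens the base-pair trace (a logit boost on final recall) and couples
the base and secondary outcomes through a shared latent variable, producing
across-subject dependence between the two memories.

Per shown (subject, pair):

* reminder R ~ Bernoulli(logistic(γ0 + γ1·rel)), where rel is the target
  relatedness (ΔTarget), cue relatedness (ΔCue), their sum (ΔBoth), or 1
  (identical repetition, NoΔ);
* base-test success probability
  logistic(β0 + β_cond + β_rel·rel + δ·R − φ·[48 hr] − κ·[ΔTarget ∧ 5 min]);
  control pairs have no secondary item, so rel = R = 0 for them.  κ is a
  short-delay retrieval-competition penalty, φ a forgetting offset at the
  long delay;
* given R = 1, base and secondary outcomes share a latent Gaussian with
  correlation ρ (a Gaussian copula); given R = 0 they are independent;
* trials to criterion during learning ~ Geometric(logistic(λ0 + λ1·rel)),
  support 1, 2, …, so the mean is the reciprocal success probability;
* on a ΔTarget base-test failure the subject intrudes the secondary-list
  target with probability ι, else leaves a null response.

Association networks and quasi-evenly spaced relatedness pools stand in for
free-association norms and embedding-derived stimulus values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import (
    CONDITIONS,
    CounterbalancePlan,
    StimulusSet,
    build_grid,
    counterbalance,
    secondary_item,
)
from .relatedness import AssociationNetwork

__all__ = [
    "SimulationParams",
    "SubjectDataset",
    "generate_network",
    "generate_pair_pool",
    "simulate_experiment",
]


@dataclass
class SimulationParams:
    """Generative parameters; probabilities arise through a logistic link.

    All β/γ/δ/κ/φ/λ parameters live on the logit scale.
    """

    n_subjects: int = 200
    delay: str = "48hr"  # {"5min", "48hr"}
    learning_mode: str = "retrieval"  # {"retrieval", "study"}
    beta0: float = 0.3
    beta_cond: dict[str, float] = field(
        default_factory=lambda: {
            "NoDelta": 1.0,
            "DeltaTarget": 0.0,
            "DeltaCue": 0.4,
            "DeltaBoth": -0.8,
            "control": 0.0,
        }
    )
    beta_rel: float = 0.5
    gamma0: float = -1.0
    gamma1: float = 2.5
    delta: float = 1.2  # reminder strengthening boost
    rho: float = 0.6  # latent outcome correlation given a reminder
    kappa: float = 0.6  # ΔTarget retrieval competition, short delay only
    phi: float = 0.8  # forgetting offset at 48 hr
    lambda0: float = 0.3
    lambda1: float = 1.2
    iota: float = 0.2  # intrusion probability given ΔTarget base failure
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if self.delay not in ("5min", "48hr"):
            raise ValueError(f"unknown delay {self.delay!r}")
        if self.learning_mode not in ("retrieval", "study"):
            raise ValueError(f"unknown learning mode {self.learning_mode!r}")
        missing = set(CONDITIONS) - set(self.beta_cond)
        if missing:
            raise ValueError(f"beta_cond missing conditions: {sorted(missing)}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SubjectDataset:
    """Simulated behavioral record of one experiment.

    ``data`` is tidy, one row per (subject, pair):
    subject, pair_id, condition, r_cue, r_target, reminder,
    trials_to_criterion (NaN in study mode), base_correct,
    secondary_correct (NaN for control), base_response.
    """

    params: SimulationParams
    stimuli: StimulusSet
    plan: CounterbalancePlan
    data: pd.DataFrame

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# resource generators
# ---------------------------------------------------------------------------

def generate_network(
    n_words: int, mean_out_degree: float = 4.0, seed: int = 0
) -> AssociationNetwork:
    """Sparse random free-association network with planted chains.

    Each node's out-neighbors are sampled at the requested mean out-degree;
    raw strengths are Dirichlet-like draws scaled so each node's outgoing AS
    sums to at most 1.  The first six words form two planted chains
    (w0→w1→w2 and w3→w4→w5) with fixed strengths so that multi-step metrics
    have known hand-computable values.
    """
    if n_words < 10:
        raise ValueError("n_words must be >= 10")
    rng = np.random.default_rng(seed)
    words = [f"w{i}" for i in range(n_words)]
    edges: dict[tuple[str, str], float] = {}
    # planted chains with known strengths
    for (i, j, w) in [(0, 1, 0.5), (1, 2, 0.2), (3, 4, 0.4), (4, 5, 0.3)]:
        edges[(words[i], words[j])] = w
    for i, src in enumerate(words):
        k = rng.poisson(mean_out_degree)
        if k == 0:
            continue
        others = [w for w in words if w != src]
        targets = rng.choice(len(others), size=min(k, len(others)), replace=False)
        raw = rng.gamma(1.0, 1.0, size=len(targets))
        budget = 1.0 - sum(w for (s, _), w in edges.items() if s == src)
        if budget <= 0:
            continue
        scale = budget * rng.uniform(0.5, 0.95) / raw.sum()
        for t_idx, r in zip(targets, raw):
            dst = others[t_idx]
            if (src, dst) not in edges:
                edges[(src, dst)] = max(r * scale, 1e-4)
    return AssociationNetwork([(s, d, w) for (s, d), w in edges.items()])


def generate_pair_pool(
    lo: float = 0.03,
    hi: float = 0.96,
    n_pairs: int = 90,
    seed: int = 0,
    prefix: str = "p",
) -> list[tuple[str, str, float]]:
    """Quasi-evenly spaced relatedness pool over [lo, hi].

    Values sit on an even grid including both endpoints, each jittered by at
    most a quarter of the grid step, so consecutive gaps never exceed twice
    the even spacing.  Words are synthetic tokens.
    """
    if not lo < hi:
        raise ValueError("require lo < hi")
    if n_pairs < 2:
        raise ValueError("n_pairs must be >= 2")
    rng = np.random.default_rng(seed)
    base = np.linspace(lo, hi, n_pairs)
    step = (hi - lo) / (n_pairs - 1)
    jitter = rng.uniform(-0.25, 0.25, size=n_pairs) * step
    jitter[0] = jitter[-1] = 0.0  # pin the endpoints
    values = np.clip(base + jitter, lo, hi)
    return [
        (f"{prefix}{i}a", f"{prefix}{i}b", float(v)) for i, v in enumerate(values)
    ]


# ---------------------------------------------------------------------------
# experiment simulation
# ---------------------------------------------------------------------------

def _condition_relatedness(cond: np.ndarray, r_cue: np.ndarray, r_target: np.ndarray) -> np.ndarray:
    """Relatedness driving reminders: r_target (ΔTarget), r_cue (ΔCue),
    r_cue + r_target (ΔBoth), 1 (NoΔ identity), 0 (control, nothing shown)."""
    rel = np.zeros_like(r_cue, dtype=float)
    rel[cond == "DeltaTarget"] = r_target[cond == "DeltaTarget"]
    rel[cond == "DeltaCue"] = r_cue[cond == "DeltaCue"]
    rel[cond == "DeltaBoth"] = (r_cue + r_target)[cond == "DeltaBoth"]
    rel[cond == "NoDelta"] = 1.0
    return rel


def simulate_experiment(
    params: SimulationParams, stimuli: StimulusSet
) -> SubjectDataset:
    """Simulate one full experiment under the reminder model.

    Deterministic given ``params.seed``; re-running with the same params and
    stimuli reproduces the dataset bitwise.
    """
    rng = np.random.default_rng(params.seed)
    plan = counterbalance(stimuli, params.n_subjects)
    n_s, n_p = params.n_subjects, len(stimuli)

    qids = np.array([q.id for q in stimuli])
    r_cue_v = np.array([q.r_cue for q in stimuli])
    r_tgt_v = np.array([q.r_target for q in stimuli])

    subj = np.repeat(np.arange(n_s), n_p)
    pair = np.tile(qids, n_s)
    r_cue = np.tile(r_cue_v, n_s)
    r_target = np.tile(r_tgt_v, n_s)
    cond = np.array(
        [plan.condition(s, int(p)) for s, p in zip(subj, pair)], dtype=object
    )
    shown = cond != "control"
    rel = _condition_relatedness(cond, r_cue, r_target)

    # reminders only for shown pairs
    p_rem = expit(params.gamma0 + params.gamma1 * rel)
    reminder = (rng.random(n_s * n_p) < p_rem) & shown

    beta_c = np.array([params.beta_cond[c] for c in cond])
    logit_base = (
        params.beta0
        + beta_c
        + params.beta_rel * rel * shown
        + params.delta * reminder
        - params.phi * (params.delay == "48hr")
        - params.kappa * ((cond == "DeltaTarget") & (params.delay == "5min"))
    )
    p_base = expit(logit_base)
    # secondary memory: recently learned, no condition offsets
    p_sec = expit(params.beta0 + params.beta_rel * rel - params.phi * (params.delay == "48hr"))

    # Gaussian copula: latent correlation rho where a reminder occurred
    z_b = rng.standard_normal(n_s * n_p)
    eps = rng.standard_normal(n_s * n_p)
    rho_eff = np.where(reminder, params.rho, 0.0)
    z_s = rho_eff * z_b + np.sqrt(1.0 - rho_eff**2) * eps
    from scipy.stats import norm

    base_correct = (z_b < norm.ppf(p_base)).astype(int)
    secondary_correct = (z_s < norm.ppf(p_sec)).astype(float)
    secondary_correct[~shown] = np.nan

    # learning: geometric trials to criterion (retrieval mode only)
    if params.learning_mode == "retrieval":
        p_learn = expit(params.lambda0 + params.lambda1 * rel)
        trials = rng.geometric(p_learn).astype(float)
        trials[~shown] = np.nan
    else:
        trials = np.full(n_s * n_p, np.nan)

    # intrusions: ΔTarget base failures produce the secondary-list target
    delta_target_words = {q.id: q.delta_target for q in stimuli}
    target_words = {q.id: q.target for q in stimuli}
    responses = np.empty(n_s * n_p, dtype=object)
    intrude = (
        (cond == "DeltaTarget")
        & (base_correct == 0)
        & (rng.random(n_s * n_p) < params.iota)
    )
    for i in range(n_s * n_p):
        if base_correct[i] == 1:
            responses[i] = target_words[int(pair[i])]
        elif intrude[i]:
            responses[i] = delta_target_words[int(pair[i])]
        else:
            responses[i] = ""

    data = pd.DataFrame(
        {
            "subject": subj,
            "pair_id": pair,
            "condition": cond,
            "r_cue": r_cue,
            "r_target": r_target,
            "reminder": reminder.astype(int),
            "trials_to_criterion": trials,
            "base_correct": base_correct,
            "secondary_correct": secondary_correct,
            "base_response": responses,
        }
    )
    return SubjectDataset(params=params, stimuli=stimuli, plan=plan, data=data)


def default_stimulus_set(
    preset: str = "narrow", seed: int = 0
) -> StimulusSet:
    """Convenience stimulus sets mirroring the two study ranges.

    ``narrow``: associative strengths 0.03–0.96 (one-step associates);
    ``wide``: embedding cosines −0.14–0.95 (full relatedness range).
    """
    if preset == "narrow":
        pool = generate_pair_pool(0.03, 0.96, seed=seed, prefix="n")
        return build_grid(pool, seed=seed, relatedness_metric="AS", direction="directed")
    if preset == "wide":
        pool = generate_pair_pool(-0.14, 0.95, seed=seed, prefix="w")
        return build_grid(
            pool, seed=seed, relatedness_metric="GloVe_cos", direction="undirected"
        )
    raise ValueError(f"unknown stimulus preset {preset!r}")
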