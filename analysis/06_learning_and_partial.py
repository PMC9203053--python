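"""Secondary-pair learning efficiency and its relation to relatedness and
memorability: trials-to-criterion per condition, learning-vs-relatedness
correlations, and partial correlations of relatedness with the retroactive
effect controlling for learning efficiency.

Reads results/data/, writes results/learning/.
"""

from pathlib import Path

import pandas as pd

import retromem as rm

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "learning"
OUT.mkdir(parents=True, exist_ok=True)

EXPERIMENT_SET = {
    "narrow_5min": "narrow", "narrow_48hr": "narrow",
    "wide_5min": "wide", "wide_48hr": "wide",
}

rows = []
for name, stim_name in EXPERIMENT_SET.items():
    data = rm.exclude_subjects(pd.read_csv(ROOT / "data" / f"{name}.csv")).data
    stimuli = rm.simulate.default_stimulus_set(stim_name, seed=7)
    rel = stimuli.to_frame().set_index("id")
    learn = rm.learning_efficiency(data).join(
        rel[["r_cue", "r_target"]], on="pair_id"
    )
    learn.to_csv(OUT / f"learning_{name}.csv", index=False)
    memo = rm.memorability(data).join(rel[["r_cue", "r_target"]], on="pair_id")

    for cond, xcol in (("DeltaCue", "r_cue"), ("DeltaTarget", "r_target"),
                       ("DeltaBoth", "sum")):
        sub = learn[learn.condition == cond]
        x = (sub.r_cue + sub.r_target) if xcol == "sum" else sub[xcol]
        fit = rm.item_regression(x.to_numpy(), sub["mean_trials"].to_numpy())
        rows.append({"experiment": name, "condition": cond,
                     "measure": "trials_vs_relatedness",
                     "r": fit.r, "p": fit.slope_p})
        # partial correlation: relatedness vs retro effect | learning speed
        msub = memo[memo.condition == cond].set_index("pair_id")
        lsub = sub.set_index("pair_id").loc[msub.index]
        mx = (msub.r_cue + msub.r_target) if xcol == "sum" else msub[xcol]
        r_part, p_part = rm.partial_correlation(
            mx.to_numpy(), msub["delta_M"].to_numpy(),
            lsub["mean_trials"].to_numpy(),
        )
        rows.append({"experiment": name, "condition": cond,
                     "measure": "relatedness_vs_retro_partial_learning",
                     "r": r_part, "p": p_part})

tab = pd.DataFrame(rows)
tab.to_csv(OUT / "learning_correlations.csv", index=False)
for _, r in tab[tab.measure == "trials_vs_relatedness"].iterrows():
    print(f"{r.experiment} {r.condition}: learning-speed r = {r.r:+.2f} (p={r.p:.3g})")
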