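"""Condition-level effects per experiment: subject exclusions, condition
means, repeated-measures ANOVA (Huynh–Feldt corrected when sphericity is
violated), and FDR-corrected pairwise t-tests.

Reads results/data/, writes results/condition_effects/.
"""

from pathlib import Path

import pandas as pd

import retromem as rm
from retromem.pipeline import _condition_scores

DATA = Path(__file__).resolve().parent.parent / "results" / "data"
OUT = Path(__file__).resolve().parent.parent / "results" / "condition_effects"
OUT.mkdir(parents=True, exist_ok=True)

anova_rows = []
for csv in sorted(DATA.glob("*.csv")):
    name = csv.stem
    data = pd.read_csv(csv)
    excl = rm.exclude_subjects(data, drop_zero_base=(name == "study_only"))
    scores = _condition_scores(excl.data)
    res = rm.rm_anova_hf(scores)
    pairwise = rm.pairwise_t_fdr(scores)
    pairwise.insert(0, "experiment", name)
    pairwise.to_csv(OUT / f"pairwise_{name}.csv", index=False)
    scores.mean().to_frame("mean_accuracy").to_csv(OUT / f"means_{name}.csv")
    anova_rows.append(
        {
            "experiment": name,
            "excluded": len(excl.excluded),
            "F": res.F,
            "df_num": res.df_num,
            "df_den": res.df_den,
            "epsilon": res.epsilon,
            "p": res.p,
        }
    )
    order = scores.mean().sort_values(ascending=False).index.tolist()
    print(
        f"{name}: F({res.df_num:.1f},{res.df_den:.1f})={res.F:.1f}, "
        f"p={res.p:.2g}; ordering {' > '.join(order)}"
    )

pd.DataFrame(anova_rows).to_csv(OUT / "anova.csv", index=False)
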