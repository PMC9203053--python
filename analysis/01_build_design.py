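"""Build the stimulus designs: synthetic association network, relatedness
pair pools for the narrow (associative-strength) and wide (embedding-cosine)
ranges, 45-quartet grids, and the 200-subject counterbalance plan.

Writes results/design/.
"""

from pathlib import Path

import pandas as pd

import retromem as rm

OUT = Path(__file__).resolve().parent.parent / "results" / "design"
OUT.mkdir(parents=True, exist_ok=True)

SEED = 7

network = rm.generate_network(200, mean_out_degree=4.0, seed=SEED)
pd.DataFrame(network.edges, columns=["source", "target", "strength"]).to_csv(
    OUT / "association_network.tsv", sep="\t", index=False
)
print(f"association network: {len(network)} words, {len(network.edges)} edges")

for name, (lo, hi), metric in (
    ("narrow", (0.03, 0.96), "AS"),
    ("wide", (-0.14, 0.95), "GloVe_cos"),
):
    pool = rm.generate_pair_pool(lo, hi, seed=SEED, prefix=name[0])
    stimuli = rm.build_grid(pool, seed=SEED, relatedness_metric=metric)
    stimuli.to_frame().to_csv(OUT / f"stimuli_{name}.csv", index=False)
    plan = rm.counterbalance(stimuli, 200)
    plan.to_frame().to_csv(OUT / f"counterbalance_{name}.csv", index=False)
    df = stimuli.to_frame()
    print(
        f"{name} set: 45 quartets, r_cue span "
        f"[{df.r_cue.min():.2f}, {df.r_cue.max():.2f}], r_target span "
        f"[{df.r_target.min():.2f}, {df.r_target.max():.2f}]; "
        f"counterbalance: 200 subjects, 40 per (quartet, condition)"
    )
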