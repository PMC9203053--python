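# Methods

## Design model

The experimental unit is the quartet {cue, Δcue, target, Δtarget}. Ninety
relation pairs (a base word plus a related new word, each carrying one
relatedness value) are rank-sorted and split into terciles of 30; each
tercile is randomly halved into 15 cue pairs and 15 target pairs; each
tercile's cue pairs are dealt five apiece to the three target levels and
vice versa, crossing cue × target relatedness into a 3×3 grid with exactly
5 cue pairs and 5 target pairs per cell; within a cell the two sets are
randomly matched into 5 quartets. All draws come from one seeded generator
in a fixed call order, so a stimulus set is a pure function of (inputs,
seed). Tercile boundary ties are broken by a stable sort on (relatedness,
words).

Counterbalancing rotates the five quartets of each cell through the five
conditions, advancing one step per subject: subject *s* sees cell slot *j*
in condition (j + s) mod 5. Consequences, asserted by tally in the tests:
every subject holds 9 quartets per condition (36 secondary pairs learned,
45 base pairs tested), and with n subjects (n a multiple of 5) every
(quartet, condition) cell is observed by exactly n/5 subjects — 40 at the
standard n = 200.

Retrieval-to-criterion schedules drop a pair after its first correct
retrieval; study-only schedules are yoked to a donor retrieval schedule,
copying pair order and per-round dropout and replacing retrieval trials
with restudy.

## Relatedness metrics

Association networks are directed graphs whose edge weight is the
free-association probability AS ∈ (0,1]; outgoing weights per node sum to
at most 1; absent edges read as 0 (norms are sparse by construction) while
absent *words* raise an error. Weighted path length minimizes Σ(1−AS) by
Dijkstra (a hop-shortest variant is available by flag) and clamps to a cap,
default 6, when the destination is unreachable; finite lengths beyond the
cap are clamped too (flaggable off). Spreading activation renormalizes each
node's out-weights once (a static transition matrix), propagates mass from
the source for up to 3 steps, and sums the walk-product mass arriving at
the destination; walks may revisit nodes (flaggable). Backward mediator
strength sums AS(new→m)·AS(m→base) over mediators distinct from both
endpoints (max-product available by flag). Embedding vectors come from the
word-per-line text dialect with an auto-detected `n d` header; cosine
similarity rejects zero-norm vectors. A `profile` call bundles all six
metrics, representing missing resources as missing values rather than
zeros.

## Generative model of the experiments

Each shown (subject, pair) may trigger a *reminder* of the base pair with
probability logistic(γ0 + γ1·rel), where rel is the target relatedness in
ΔTarget, the cue relatedness in ΔCue, their sum in ΔBoth, and 1 for the
identical NoΔ repetition. The base pair's final-test success probability is

    logistic(β0 + β_cond + β_rel·rel + δ·R − φ·[48 hr] − κ·[ΔTarget ∧ 5 min])

— a condition offset, a direct relatedness slope, a reminder boost δ, a
forgetting offset φ at the long delay, and a short-delay retrieval
competition penalty κ confined to ΔTarget (interference modeled as a
retrieval-stage impairment rather than trace weakening). Given a reminder,
base and secondary outcomes share a latent Gaussian with correlation ρ
(Gaussian copula), producing across-subject dependence; without one they
are independent. Trials to criterion are geometric with success probability
logistic(λ0 + λ1·rel) (support 1, 2, …, mean 1/p). A ΔTarget base-test
failure emits the secondary-list target as an intrusion with probability ι.

Reminders are modeled per (subject, pair), not per learning trial, because
only final-test outcomes are observed downstream. All parameters sit on the
logit scale. The `stylized` preset (data, not code: a YAML file) is
tuned so the simulated condition ordering matches the qualitative
retrieval-learning pattern NoΔ > ΔCue > ΔTarget > ΔBoth > control at the
narrow range/48-hr settings; the `null` preset zeroes every effect so
condition labels are exchangeable. φ (5 min → 48 hr forgetting) has no
empirically anchored value and defaults to 0.8 logits, chosen to give a
plausible control-condition drop from ~0.55 to ~0.38. The generator
reproduces datasets bitwise from its seed.

What the simulator does **not** emulate: response-time structure, word-level
idiosyncrasies (frequency, concreteness), near-miss spellings, subject
ability heterogeneity beyond binomial noise, or forgetting dynamics between
the two fixed delays. Passing tests therefore demonstrate the pipeline's
statistical behavior under the stated model, not empirical claims about
human data.

## Behavioral measures

Memorability is the per-(pair, condition) proportion correct over the n/5
subjects holding that cell; the retroactive effect subtracts the same
pair's control cell. Dependence is the both-or-neither agreement of the
base and secondary outcome vectors over the subjects who held the duo in
that condition (listwise dropped on missing outcomes); it equals 1 minus
the normalized Hamming distance, is computed against the (n_pairs − 1)
mismatched secondary vectors of the other pairs (aligned by
within-condition subject order) to form a null, and the exceedance
criterion asks the true duo to beat all but one of them —
(n − 2)/(n − 1) = 43/44 ≈ 0.977 at 45 pairs. The per-pair threshold value
(the second-largest mismatched dependence) is averaged across pairs for the
dotted reference line on dependence plots. The tail convention behind the
criterion's nominal α is ambiguous (1/44 ≈ 0.023 one-sided vs 2/44 ≈ 0.045);
the criterion fraction itself is what the code reports. Subject exclusion
removes overall accuracies below mean − 4·SD (population SD; nobody is
excluded when the SD is 0), with an optional study-only rule removing
zero-correct-base subjects. Intrusion scoring is exact string match after
case-folding and trimming; no typo tolerance.

## Surface smoothing

Scattered per-pair values at (target relatedness, cue relatedness)
coordinates are binned to a square grid (default 64×64 with a 2% margin;
cell value = mean, weight = count). The smoother minimizes
‖W^½(z − y)‖² + s‖Δz‖² and is solved in the type-II DCT basis, where the
Laplacian penalty diagonalizes to per-frequency shrinkage
Γ = 1/(1 + s·λ²); non-uniform weights (including zero for empty cells) are
handled by over-relaxed fixed-point iteration, which bridges the inevitable
gaps between stimulus coordinates. Optional robust iterations (default 2)
reweight residuals with the bisquare function at 6·MAD scale. With
robustness off the smoother is linear in the data; it preserves constants
exactly, interpolates as s → 0, and tends to the weighted mean as s → ∞
(all property-tested).

The bandwidth default required a genuine decision. A convention of setting
the smoothing factor to roughly 40% of the input span maps to two extremes
depending on how it is read: as a raw penalty value (s ≈ 0.4) it means a
half-width of roughly one grid cell — near-interpolation — while as a
half-width fraction (0.4 × span) it averages away almost all spatial
structure. Simulation
showed both extremes destroy the cluster test's power to detect a planted
one-cell effect (≤ 15% detection). The default is therefore a half-width of
10% of the axis span (s = (2·n·0.10/π)⁴ grid units), which pools roughly
one 3×3 design cell — the natural effect scale of this design — and gives
> 90% detection at standard sample sizes while leaving the null
false-positive rate at its nominal level. Both the raw penalty `s` and the
fraction `s_frac` are exposed, so either literal reading is one argument
away.

## Cluster-permutation inference

The observed surface smooths ΔM = M_cond − M_control. The permutation null
scrambles condition labels across the pooled 2n memorability values: each
permutation randomly reassigns which 45 values count as "condition" and
which as "control" and re-smooths with identical settings. Per-cell
pointwise thresholds are the α and 1−α quantiles (default α = 0.01 per
tail) over the observed-plus-permuted family of smoothed surfaces —
including the observed surface keeps the family exchangeable; excluding it
measurably inflates the false-positive rate. Suprathreshold clusters
(4-neighbor connectivity by default) are sized, and each observed cluster's
p-value is the fraction of permutations whose own maximum suprathreshold
cluster is at least as large (an optional +1/+1 correction is available).

Two alternatives remain behind flags, with their trade-offs measured by
simulation (see the repository's test suite): a per-pair sign-flip scheme
is exactly calibrated under item heterogeneity but loses most of its power
because a true effect inflates the permutation null precisely at its own
location; and a literal threshold-then-smooth order (quantiles of the raw
binned values, then smoothed) produces thresholds dominated by single-pair
binomial noise, detecting nothing. The label-scramble default is exactly
calibrated when item difficulties are homogeneous and is conservative —
not anticonservative — when they vary, because item heterogeneity widens
the scrambled null.

Operating characteristics are verified at scaled-down sizes in the
acceptance tests: 100 effect-free generated experiments at 200 subjects and
200 permutations on a 32-cell grid keep the any-cluster false-positive rate
inside the 95% binomial band around 0.05, and a +0.3 memorability effect
planted in the high/high design cell is detected (significant above-zero
cluster overlapping the planted cell) in ≥ 90% of 50 runs. These sizes were
chosen to keep the whole suite in the tens of minutes; the analysis scripts
use 1000 permutations.

## Supporting statistics

Repeated-measures ANOVA, Mauchly sphericity, Huynh–Feldt epsilon and
partial correlations delegate to pingouin; OLS with pointwise 95% t-bands
to statsmodels; paired t-tests to scipy; Benjamini–Hochberg adjustment to
statsmodels (one family = the 10 pairwise condition contrasts of one
experiment). The HF correction is applied when the Mauchly test rejects at
0.05 (flag to always correct); epsilon is clamped to ≤ 1, and forcing
ε = 1 reproduces the uncorrected test. Degenerate cases are defined rather
than crashed: identical conditions give F = 0; a zero-variance paired
difference gives p = 1 when the mean difference is 0 and is flagged
degenerate otherwise; a response fully explained by the partial-correlation
covariate returns r = 0.

## Known limitations

The smoother is not a bit-for-bit reimplementation of any particular
published smoothing routine (robust-weight schedules differ across
implementations). The scramble permutation is conservative under strong
item heterogeneity; the sign-flip flag is the exact-but-weaker alternative.
The simulator's ΔBoth reminder drive uses additive r_cue + r_target; other
combinations (min, product) are untested. Empirical effect sizes from real
experiments (F statistics, item correlations, cluster p-values) are outside
the scope of the synthetic pipeline and are not asserted anywhere in the
package.
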