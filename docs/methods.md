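# Methods

## The temporal two-state effect model

For a gene profiled in `n` homozygous strains over `T` time points, a
biallelic variant partitions the panel into allele groups A and B.  The
*observed effects* at time `t` are the cross-allele differences
`D_t = {y_i^t − y_j^t : i ∈ A, j ∈ B}` (all `n_A · n_B` pairs); the
*background* `B_t` collects the within-group differences (`C(n_A,2) +
C(n_B,2)` unordered pairs, sign fixed by ascending strain index).  Working
on differences cancels the stimulus response shared by all strains, so
additive per-time-point shifts leave both samples unchanged.

Each time point carries a hidden state `s_t ∈ {H, L}`; observations at
time `t` are i.i.d. `N(μ_{s_t}, σ_{s_t}²)` with parameters shared across
all time points in the same state, so the parameter count does not grow
with `T`.  State sequences follow a first-order Markov chain with initial
state probability `π = 1/2` for either state and a fixed switching
probability `λ ∈ (0, 0.5]`, the *penalty*.  At `λ = 0.5` every sequence
has prior `2^{-T}` and time order is irrelevant; smaller `λ` geometrically
penalizes each transition.  Means are unrestricted in sign, so the model
represents inversions (an effect that flips direction); after fitting, H
is the state with the larger `|μ|` (ties: larger σ, then the current
label — deterministic and idempotent).

### Fitting

`fit_two_state` maximizes the joint objective `log P(S) + log P(D | S,
θ)` over sequences and parameters.  Baum–Welch (EM with the transition
matrix held fixed at the penalty) finds the basin; a segmental polish
then alternates Viterbi decoding with closed-form per-state Gaussian
MLEs, which is monotone in the joint objective and terminates at a fixed
point, so the reported likelihood is exact at the decoded sequence rather
than an EM approximation.  The deterministic initialization is
low-effect-like: both states start at the pooled σ with means offset by
± half the pooled σ around the pooled mean.  Defaults: EM tolerance 1e-8,
500 iterations max, σ floored at 1e-6.  `restarts=N` adds random starts
(`μ ~ m + σ·U(−2,2)`, `σ' ~ σ·U(0.5,1.5)`) as a robustness check.
`enumerate_ml_oracle` evaluates all `2^T` sequences with per-sequence
closed-form MLEs (refused above T=12) and is used in tests as an
independent check that the fit attains the global optimum.

All likelihood computations run on per-time-point sufficient statistics
`(n_t, Σx, Σx²)`, so a genome scan never materializes the quadratic
number of strain pairs; a batched implementation fits tens of thousands
of (gene, variant, permutation) problems at once.

### Variance stabilization

The model assumes the noise scale of the effects does not change over
time, so within every (time point, allele group) cell the values are
rescaled around their mean, `x → m + (x − m)·(v/s)`.  The target
variance `v²` defaults to the gene's average within-group variance over
all cells: the spread is *equalized* across time without changing the
gene's overall noise scale.  An absolute target (e.g. 1.0) is supported
but distorts the effect-to-noise ratio whenever the data's intrinsic
variance differs from it, since group means — the effects — are
preserved while the noise is rescaled.  Zero-variance cells pass through
unchanged with a warning.  Stabilization is conditional on the tested
variant's allele split and is recomputed under every permutation.

## Association score and significance

The test conditions on the variant's fitted temporal two-state model:
with the sequence `S` fixed (fitted on D), observations pool within each
state and each hypothesis term re-maximizes only the Gaussian
parameters, in closed form:

    log Λ = Σ_s [ ll(D_s) + ll(B_s) − ll(D_s ∪ B_s) ]

Under the null the variant has no effect, D and B are exchangeable and a
single per-state model represents the pooled sample, so `log Λ` is
exactly 0 when D and B coincide and grows with any distributional
difference the state partition exposes.  Significance is empirical:
strain genotype labels are permuted (once per gene per permutation,
reused across variants), D, B and the stabilization are recomputed, and
`p = (1 + #{permuted ≥ observed}) / (1 + n_perm)` (add-one smoothing
keeps p positive).  Per gene, p-values are Bonferroni-corrected by the
number of testable (polymorphic, ≥2 strains per allele) variants; the
best variant is the minimal corrected p with ties broken by the larger
observed score.  Across genes, Benjamini–Hochberg controls the FDR
(default 6%).  The *dynamic association score* is a Welch t-test between
D pooled over H and over L time points (undefined for single-state
patterns); BH at 15% among predicted associations flags *predicted
dynamic associations*.

Time points where either allele group has no observation are dropped
(never imputed), so panels with per-time-point missingness are handled
natively; complete-data genes take the fast batched path and masked
genes a per-pair reference path.

An optional exact pruning (`prune_max_exceed=c`) stops accumulating
permutations for variants whose exceedance count already exceeds `c`.
When the reporting threshold implies "beat all permutations" (e.g.
corrected p < 0.001 with 999 permutations and 100 variants), `c = 0`
reproduces the full scan's significance calls and best variants exactly
while skipping most of the work; it is off by default.

## Synthetic data

The generator emulates a segregant panel: i.i.d. fair-coin biallelic
genotypes (default 50 strains × 100 variants on synthetic chromosome
positions), and per-gene effect curves `μ(t)`:

- **sustained** `h·sigmoid(q(t − vT))`, `q = v = 0.5`: half height at the
  midpoint, a single state transition;
- **impulse** product of rising and falling sigmoids, sharp transitions
  (steepness 10) around a flat high-effect plateau of length `l`
  (default `T/3`), peak normalized to `h` — exactly `l` grid points
  exceed `h/2`;
- **complex** two impulses, one per half of the course;
- **linear** a ramp `0 → h`.

The ground-truth pattern calls H where `μ(t) > h/2`.  Strains carrying A
express `N(μ(t), σ²/2)` per time point, B strains `N(0, σ²/2)`, so the
*observed effect* (pair difference) is marginally `N(μ(t), σ²)` — σ
(default 1) parameterizes the effect-level noise, and effect sizes `h ∈
{0.125, …, 1}` are in units of that noise.  A collection is 500 genes
with 300 associated (each to one uniformly drawn variant); the full
benchmark grid is 8 effect sizes × 9 time-course lengths (3…27).  A
second family samples the H/L path itself from the Markov sequence prior
(for pattern-error evaluation), and `apply_missingness` drops k% of
strains independently at every time point.  Simulating at strain level
(rather than drawing pair differences directly) exercises the whole
pipeline — stabilization, background pairs, permutations — end to end.

What the generator does *not* emulate: linkage disequilibrium between
markers, strain relatedness structure, heteroskedastic or heavy-tailed
expression noise, and shared stimulus response curves (these cancel in
the differences anyway).  Passing benchmarks therefore demonstrates
correctness of the machinery and calibration under exchangeability, not
robustness to confounding in real panels.

## Evaluation

Classification is variant-aware: a significant call is a true positive
only if the predicted variant is the causal one; a significant wrong
variant — even on an associated gene — is a false positive.  Sensitivity
is TP over associated genes, specificity TN over non-associated ones;
*accuracy* is the trapezoidal area under sensitivity vs (1−specificity)
across 200 log-spaced thresholds in [1e-6, 1] (≈0 for random, 1 for
perfect).  The *two-state pattern error rate* is the fraction of wrong
fitted patterns among significant correct-variant calls: stringent =
exact string match, flexible = equal after run-length collapsing (state
order right, timing free).

Baselines: **naive** per-time-point two-group ANOVA, minimum p over
times; **pca** one-way ANOVA on PC1 scores of the strains × time matrix
(strains with missing time points excluded); **dynamics** F-test of
per-genotype intercept+slope against a shared line (N.B. this joint test
nests a mean-shift detector and is a deliberately strong formulation);
**random** a uniform variant and p.  All are Bonferroni-corrected over
variants.

## Problem sizes and reproducibility

The packaged experiments run at desk scale, chosen to finish in minutes
on one CPU while keeping the estimates' sampling error below the
tolerances used in the tests: pattern-error runs use 150 Markov-path
genes (50 strains, 100 variants, T=9, effect 0.75, 999 permutations),
impulse sensitivity 100 associated genes (T=27, effect 0.625, lengths 5
and 15), initialization robustness 200 fits vs 100 restarts, null
calibration 500 genes with 199 permutations, and ordering comparisons
five replicate collections (40 genes, 15 variants, T=18, effect 0.5 —
short courses make the sustained sigmoid effectively linear, which is
the regime where the linear-trend baseline is expected to win).  Every
experiment derives all randomness from a single integer seed via
`numpy`'s `SeedSequence`.

## Known limitations

- The two-state emission model treats the `n_A·n_B` pair differences at
  a time point as independent although they share strains; the fit is
  therefore over-confident per time point and isolated state-call errors
  occur even for clear effects.  The permutation test calibrates the
  *score* against this, but fitted patterns retain timing noise, and a
  penalty `λ < 0.5` reduces transitions only mildly at large panel
  sizes.
- With `n_perm` permutations the smallest attainable p is
  `1/(n_perm+1)`; thresholds near that floor (e.g. Bonferroni 0.1 over
  100 variants with 999 permutations) require beating every permutation,
  which discards borderline-significant genes that a finer permutation
  resolution would admit.
- Only homozygous biallelic markers are supported; no kinship or
  covariate adjustment; two states only, first-order Markov, fixed λ.
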