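# Methods

This note records the models, conventions and numerical choices behind
`exomedium`, and what the synthetic-data validations do and do not show.

## Medium formulation

A medium is a list of components (name, molecular formula, tier, µM), a
salt profile (mM per ion, with flags for entries contributing inorganic N),
supplement pass-through lines, and a pH range. Tiers (`sugars`,
`organic_acids`, `amino_acids`, `other`) are *concentration* tiers, not
strict chemical classes: every member of a tier is dosed equimolar, which is
what makes the inverse problem (pick a base concentration to hit a carbon
budget) a one-line linear solve.

Elemental masses use a bundled table of standard atomic weights
(conventional single values, ≤ 4 decimals; version string
`IUPAC-2021-conventional-4dp` is embedded in report headers) so every number
is reproducible bit-for-bit. Per-component element mass is
`count × weight × µM × 10⁻³` mg/L. Internal values keep full precision; the
display variant of the stoichiometry table rounds half-away-from-zero to
integers, and the totals row is rounded from the full-precision total rather
than summed from rounded rows — the two can differ by 1 in the last digit
(the packaged medium prints tier carbons of 578 + 195 + 225 + 43 = 1041
against a rounded total of 1042; this is the rounding convention, not an
inconsistency).

The formula grammar supports nested parentheses with multipliers and
hydrate dot notation — broader than the packaged medium needs, because the
generality is cheap.

### The packaged NLDM definition

The packaged 64-metabolite NLDM fixture reproduces the published per-tier
budgets exactly: sugars (875 µM × 7) 578 / 12 mg/L C / N, organic acids
(525 µM × 7) 195 / 22, amino acids (175 µM × 20) 225 / 71, other
(17.5 µM × 30) 43 / 18, totals 1042 / 123. Two published carbon totals
circulate for this medium — 1,042 mg/L (the tabulated budget this package
reproduces) and 1,146 mg/L (quoted in prose comparisons); the fixture and
all tests follow the tabulated value.

Tier membership is only partly public. Where the published description is
explicit a row is flagged `main_text`. Two placements are forced by the
elemental budgets rather than stated directly (`tier_inferred`): the
organic-acid tier's 22 mg/L N at 525 µM requires exactly three N atoms, which
uniquely places citrulline (C6H13N3O3) there; and the sugar tier's 12 mg/L N
at 875 µM admits exactly one single-N compound (N-acetylglucosamine) and 55
carbon atoms in total, which excludes N-acetylmuramic acid from that tier
(it sits in `other`) and implies a seventh C6H12O6 sugar, included as
fructose. The remaining `other`-tier members not named in the public
description (flagged `inferred`) are plausible soil/R2A metabolites chosen
once, under the constraint that the tier's rounded C and N budgets are
reproduced; they are a synthetic reconstruction, not a transcription, and
anyone with the authoritative supplementary recipe should regenerate the
fixture from it.

### C:N conventions

`cn_ratio` supports molar or mass basis, with or without inorganic N. For
the packaged medium the molar ratio is 9.87 organic-only and 8.86 with the
1 mM ammonium included; the published "9:1" design target corresponds to
the molar-including-ammonium reading, so that is what the docs quote, but
both are always computed. `solve_cn_scale` exploits that the organic C:N is
invariant under uniform scaling while the ammonium anchor is fixed, giving a
closed-form scale factor for a target ratio (infeasible at or above the
organic-only ratio, which is the supremum).

## Growth curves

Growth is called on blank-corrected OD600 series by the threshold rule
`max(OD) − OD[0] ≥ 0.05` (inclusive). Because the published procedure does
not specify rate/lag estimators, the package uses the standard log-linear
sliding window: µ_max is the steepest degree-1 fit of log OD over a window
(default 5 points ≈ 1 h at 15-min reads), and lag is where that tangent
re-crosses the starting log-OD level. ODs are clipped to 1e-4 only for the
log transform, never for ΔOD. Windows dipping below a noise guard
(default OD 0.005) are excluded when any clean window exists, so reader
noise near zero cannot masquerade as exponential growth. On noiseless
logistic curves (OD0 = 0.02, K = 0.6) the estimator recovers µ within ~6 %
across 0.1–1.0 h⁻¹ (the small negative bias is the logistic's
`(1 − OD/K)` correction over the window). Note that fitting *blank-corrected*
curves estimates the rate of the baseline-shifted signal, which exceeds the
generative µ of the raw curve — a property of the procedure itself, shared
with any analysis that subtracts the uninoculated control before log-fitting.

Media comparison is per isolate: Welch's t (the variance assumption is
unstated upstream, so the unequal-variance default is the safer choice) on
replicate maximum ODs, Benjamini–Hochberg adjustment across isolates, and
the log2 ratio of mean maxima. Isolates missing a medium or with < 2
replicates are excluded with a warning, never silently.

## Exometabolite profiling

Pipeline order: extraction-blank subtraction (per-metabolite blank mean,
negatives clipped to 0) → optional blank-ratio filter (a feature is dropped
when its maximum non-blank signal is below `ratio ×` its maximum blank
signal; boundary inclusive, default ratio 10) → normalization (each
metabolite scaled so its *maximum* over uninoculated-control samples is
exactly 100; metabolites with a zero control maximum are masked, not
divided) → fold changes → significance calls. Whether blank subtraction
precedes or follows normalization is not specified upstream; subtracting
first is the package's choice and is scale-invariant either way.

Fold change is log2(mean isolate / mean control) on the normalized scale,
with an abundance floor (default: half the smallest nonzero normalized
value) applied to both means so fully depleted metabolites stay finite;
cells with equal means are forced to exactly 0. Masked metabolites are
reported, never silently dropped.

### The rank-sum approximation, deliberately

Calls use the two-sided Wilcoxon rank-sum with the large-sample normal
approximation, midranks for ties, and *no* continuity or tie correction —
the classical z form, identical to `scipy.stats.ranksums` (pinned by test).
This is reproducibility-critical at triplicate scale: with n = 3 vs 3 and
complete separation the approximation gives z = 4.5/√5.25 ≈ 1.964,
two-sided p ≈ 0.0495 < 0.05, while exhaustive enumeration of all 20 rank
arrangements bounds the exact p at 0.10. Triplicate significance calls
therefore exist *only* under the approximation; an exact-test reimplementation
would silently call nothing. No multiple-testing correction is applied by
default (calls are raw p < α, matching the upstream convention); a
Benjamini–Hochberg option exists but is off.

Direction comes from the sign of the mean difference, so every `depleted`
call has negative fold change and every `produced` call positive (asserted
as an invariant).

### Clustering

Bray–Curtis dissimilarity is undefined for negative values, so clustering
operates on per-isolate *mean normalized abundances* (0–100, non-negative)
while the log2 matrix is what gets displayed; both are emitted, and passing
a matrix with negatives raises with a pointer to the right input. Linkage is
average (UPGMA) by default, configurable; leaf order is scipy's
deterministic tie-break. The dendrogram is exported as Newick with branch
lengths from merge-height differences.

## Niche conservatism

Patristic distances are computed by a single postorder pass (merge
per-clade leaf lists, cross pairs at each internal node); missing branch
lengths are an error, the root's absent subtending edge excepted. The
implementation is checked against brute-force path sums on random trees of
every size up to 6 leaves, and satisfies the triangle inequality on random
trees.

Profile distances are Euclidean on log2 fold-change columns (a
pairwise-complete option rescales by the shared-metabolite fraction). The
association between the two matrices is reported as an OLS fit plus
Spearman's rho over the n(n−1)/2 upper-triangle pairs — but those pairs are
not independent, so the attached significance is a Mantel-style permutation
test: one matrix's labels are permuted `n_perm` times with an explicit
seed, and `p = (#{perm ρ ≥ ρ_obs} + 1)/(n_perm + 1)` (one-sided). A plain
regression p over pairs would be anticonservative; the permutation p is the
defensible number. The cophenetic-distance alternative (distances from the
Bray–Curtis dendrogram instead of raw Euclidean profile distances) is
provided as an option; Euclidean is the default.

Pairwise profile correlations are Spearman with midranks, Bonferroni-capped
(`min(1, p × n_pairs)`); constant profiles have undefined rho and are
masked. The group-level test compares within-group vs between-group
pairwise correlations with a one-sided rank-sum (within > between).

Every stochastic routine takes an explicit seed and uses a local
`numpy.random.Generator`; there is no global random state anywhere.

## Synthetic data: what it emulates, and what it does not

The generator mirrors a 30-isolate × 64-metabolite triplicate screen with
18 uninoculated-control samples and 3 extraction blanks:

- **Tree**: pure-birth (Yule) with Exp(k·λ) waiting times (default λ = 1),
  tips extended by one extra waiting time so all pendant branches are
  positive.
- **Profiles**: per metabolite a latent trait evolves by Brownian motion
  along the tree (increment variance σ²_phylo × branch length; default
  σ_phylo = 1.5), leaves get independent N(0, σ²_noise) jitter (default
  0.15), and the logistic map turns traits into depletion fractions in
  (0, 1). The module's core statistical contract,
  E[(trait_i − trait_j)²] = σ²_phylo·d_ij + 2σ²_noise, is verified by Monte
  Carlo (8000 metabolites, within 5 %). Cells can instead be flagged
  *produced* with a multiplier in (1.5, 4); production and depletion are
  mutually exclusive per cell.
- **Peak tables**: control abundance log-uniform over 1e4–1e7 (typical
  targeted peak-height range), replicates multiplied by log-normal noise
  with CV 0.2 (routine LC-MS replicate variability), blanks at 5 % of the
  control signal.
- **Growth**: logistic with explicit lag and additive Gaussian OD noise.
- **Families** for the group test come from cutting the tree at a fixed
  depth (default 25 % of maximum leaf depth) — ground-truth-consistent by
  construction.

Defaults were chosen once as realistic study conditions; the closed-loop
validations run at σ_phylo/σ_noise = 10 (the "strong signal" regime), where
the Mantel test rejects in ≥ 90 % of 200 seeded replicates and ≥ 95 % of
strongly depleted cells (true fraction ≥ 0.8) are recovered at n = 3,
α = 0.05. Under zero signal the significant-call rate lands in [0.03, 0.07]
(the discrete rank-sum null at n = 3 vs 18 gives 0.047 exactly) and the
Mantel p is uniform.

What passing these validations does **not** show about real data: the
generator has no retention-time drift, batch effects, missingness from
detection limits, correlated noise across metabolites, or non-Brownian
trait evolution (selection, saltation); real screens can violate any of
these. The validations certify the *pipeline's* correctness and
calibration, not the biology of any particular dataset.

## Problem sizes and tolerances

The test suite and acceptance script run the synthetic validations at the
sizes quoted above (200 replicate screens for power/recall, 2048 null
tests, 500 Mantel-null runs at 99 permutations, 8000-metabolite Brownian
check, exhaustive ≤ 6-leaf patristic comparison) — sizes chosen so the
closed-loop checks are statistically meaningful while the whole suite stays
fast on a single CPU. Numerical tolerances: additivity and solver
round-trips at 1e-9 relative; rank-sum equivalence with scipy at 1e-12;
Brownian contract at 5 %; growth-rate recovery at 10 %.

## Known limitations

- The medium fixture's `inferred` rows are reconstructions (see above).
- Lag estimation on blank-corrected curves whose early signal is near zero
  is unreliable (the tangent intercept is clipped at 0); ΔOD and the growth
  call are unaffected.
- `depletion_test` assumes exchangeable replicates; plate or batch effects
  are not modelled.
- The Mantel permutation test conditions on the observed distance
  structure; it does not correct for non-independence *within* the profile
  matrix beyond label exchange.
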