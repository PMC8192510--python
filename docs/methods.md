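# Methods

This note documents the statistical machinery implemented in `immunosig`:
the synthetic-cohort model, the profiling and association procedures, the
discriminant classifier, the genetic-algorithm signature search, and the
numerical choices made where the design was genuinely open.

## Synthetic cohorts

The generator (`immunosig.synthetic`) emulates a cross-sectional cohort of
150 late-middle-aged volunteers carrying five immune-activation (IA)
profiles with fixed sizes 43/22/39/41/5. Its defaults are calibrated to
the published cohort characteristics: per-profile metabolic means/SDs
(insulinemia, glycemia, lipids, waist/hip, blood pressure, γGT, alcohol),
per-profile therapy prevalences (counts 4/3/1/1/0 antidiabetic,
6/8/10/6/0 antihyperlipidemic, 8/7/10/8/0 antihypertensive over the
profile sizes), Profile-2 marker elevations expressed in rest-group SD
units (e.g. effector-memory CD4 +2.5, sCD163 +1.3, IgA +1.2), and four
cohort-level Spearman targets among the soluble markers
(sCD163–sTNFRI 0.291, tPA–sTNFRI 0.230, sCD163–CRP 0.295, tPA–CRP 0.344).

**Sampling model.** Markers are drawn as a latent multivariate normal
`Z ~ N(0, R)`, shifted additively per profile by the effect matrix (units:
latent SD on the transform scale), and back-transformed marginally:

- *identity* for the generic panel members;
- *moment-matched log-normal* for soluble concentrations and for γGT,
  alcohol, triglycerides and insulinemia, whose printed SDs are comparable
  to their means (right skew, positivity). Moment matching means the
  log-normal's mean and SD equal the configured values exactly, so
  marginal calibration survives the transform;
- *delta-scaled logistic* for percentage markers (slope chosen so the
  native-scale SD matches near the baseline), clipped to [0.1, 99.9] %.

**Correlation calibration.** The Spearman targets are cohort-level
quantities, and the cohort is a five-component mixture: profile shifts
shared by a marker pair contribute a between-profile correlation
component on top of the latent one. The generator therefore solves, per
target pair, for the latent correlation `r` such that the *mixture*
population Spearman equals the target, using the identity
ρ_S = 12·P(X₁<X₂, Y₁<Y₃) − 3 (each mixture term a bivariate-normal orthant
probability with correlation r/2) and Brent root-finding. With no shifts
this reduces exactly to the normal-copula closed form
`r = 2·sin(π·ρ_S/6)`. The implied latent matrix must be positive definite
or generation fails with "infeasible correlation targets". Because every
marginal transform is strictly increasing, Spearman correlations are
preserved by back-transformation.

**Panel structure.** Sixteen named markers (T-cell subsets as
percentages; sTNFRI, sCD163, tPA, IgA, CRP as concentrations) plus 27
generic `aux_*` members complete the 43-marker panel. Since the five
profiles were originally *defined* by clustering the full panel, each
profile also carries a block of ±1.5-SD shifts on disjoint aux markers
(`PROFILE_EFFECT_PATTERNS`); without panel-wide structure, profiles
signed by a single headline marker would be undetectable by any distance-
based clustering in 43 dimensions. Baselines for markers without printed
group summaries (CD57⁺CD4, activated NK, monocytes, CRP) are free
parameters set to values typical of this age group and flagged as such in
the config.

**Outcome coupling.** Metabolic outcomes are conditional on profile only,
plus an optional shared "activation" factor: a standardized average of the
*pre-shift* latent scores of the soluble activation markers enters the
insulinemia draw with loading 0.3 (config-exposed). Using pre-shift
latents keeps every per-profile outcome mean exactly calibrated; the
loading produces a continuous marker–insulin correlation (~0.2 at the
default) without distorting group contrasts. Therapy flags are Bernoulli
with per-profile rates.

**Determinism.** One master seed feeds a `SeedSequence`; the label,
marker, outcome and therapy streams are spawned in a fixed order, so
identical (config, seed) gives bit-identical cohorts and adding an
outcome never perturbs the marker stream. Profile counts are apportioned
exactly (largest remainder) by default; `draw_counts="multinomial"`
enables sampling variation.

**What the generator does not model:** assay noise and detection limits,
batch effects, missing data, age/sex structure, and any marker→outcome
causal pathway beyond shared profile membership plus the single activation
factor. Passing tests on these cohorts demonstrate correctness of the
*procedures* under the calibrated conditions, not performance on real
data.

## Profiling

Markers are z-scored per column (sample SD; a robust median/MAD variant
is available; constant columns are rejected by name). Subjects are
clustered by Ward linkage on Euclidean distances and the tree is cut at
k = 5; markers are clustered by average linkage on correlation distances
for heatmap ordering. These defaults are explicit package choices
(config-exposed), not claims about the original study's settings, which
are not public. Agglomeration is delegated to scipy's deterministic
nearest-neighbor-chain implementation, so runs are reproducible; a
silhouette score is reported as the only choice-of-k diagnostic.

Recovered clusters are named by a 5×5 linear assignment maximizing the
mean signed z-score of each profile's signature markers
(naive-T-high → Profile 1, CD4-senescent/inflammatory → Profile 2,
CD8-senescent → Profile 3, NK-activated → Profile 4, monocyte-high →
Profile 5). An exact tie between optimal assignments (within 1e-9)
raises; a small optimal-vs-runner-up margin (< 0.25 by default) flags the
naming as low-confidence, which is the expected outcome on effect-free
cohorts.

## Association battery

- **Group contrasts** (profile vs rest): pooled-variance Student t when
  both groups pass Shapiro–Wilk at α = 0.05, else Mann–Whitney. The
  pooled (not Welch) form is the default because it reproduces the
  published insulinemia contrast p-value from the printed group summaries.
  Mann–Whitney uses exact enumeration when both groups have ≤ 20
  observations without ties, otherwise the tie-corrected normal
  approximation. All tests are two-sided.
- **Correlations**: Spearman with midrank ties; p by exact permutation
  enumeration for n ≤ 10 (chunked; ~3.6 M permutations at n = 10),
  Student-t approximation above.
- **2×2 tests**: Pearson χ² without continuity correction when all
  expected counts are ≥ 5, else Fisher's exact (two-sided by the
  point-probability rule). Of note, the published antihyperlipidemic
  contrast (8/22 vs 22/128, p = 0.038) corresponds to the uncorrected χ²
  even though its minimum expected count (4.4) makes the default rule
  choose Fisher; the rule is overridable per contrast.
- **HOMA-IR** = glycemia (mM) × insulinemia (µU/mL) / 22.5 (the standard
  HOMA1-IR form), computed per subject; the waist/hip ratio is likewise a
  per-subject ratio summarized afterwards.
- No multiplicity correction is applied by default (matching the original
  analysis); a Benjamini–Hochberg column is available.

The battery's statistics are delegated to scipy.stats except the exact
tie-aware Spearman permutation p, which scipy does not provide.

## Linear discriminant analysis

`PooledLDA` is a two-class Gaussian equal-covariance classifier: pooled
within-class covariance Σ = Σₖ(nₖ−1)Sₖ/(n−2), discriminant score
δₖ(x) = xᵀΣ⁻¹μₖ − ½μₖᵀΣ⁻¹μₖ + log πₖ, posteriors by softmax over the two
scores, ties broken to the first class. Priors are empirical by default —
under 22:128 imbalance this is what yields the characteristic
specificity ≫ sensitivity operating point — with uniform or explicit
priors available. When Σ's condition number exceeds 1e8 a deterministic
ridge ε·trace(Σ)/p (ε = 1e-6) is added, so the collinear subsets a feature
search inevitably proposes degrade gracefully. Tests verify exact
agreement (≤ 1e-10) with an explicit Gaussian-density Bayes oracle and
cross-check against scikit-learn's implementation, which is never used
internally.

## Genetic-algorithm signature selection

Solutions are duplicate-free ordered subsets of 1–10 marker names.

- **Initialization**: subset sizes uniform on 1..10, features sampled
  without replacement; population 100.
- **Selection**: tournament of size 2; elitism carries the best 2 intact.
- **Cross-over** (rate 0.7): shared features kept, each symmetric-
  difference feature included with probability ½, empty child falls back
  to one random parent feature, oversized child randomly truncated to 10.
- **Mutation** (rate 0.3): exactly one edit, uniform over the feasible
  subset of {add, remove, substitute}.
- **Duplicate avoidance**: a child identical (as a set) to a member
  already placed in the next generation is re-mutated (up to 10 tries).
  Without this, tournament selection drives the population to copies of a
  single elite within ~20 generations and the final generations lose the
  candidate diversity the final re-evaluation is meant to exploit.
- **Fitness**: mean held-out LDA accuracy over 5 repeats of stratified
  2-fold CV minus λ·|S| with λ = 0.02. Each restart draws its own fixed
  set of CV splits from its seed stream, making within-run fitness a pure
  function of the subset — this enables exact caching, makes the elitism
  guarantee (best fitness non-decreasing per generation) hold exactly,
  and renders the whole search bit-reproducible from the master seed.
  λ = 0.02 means one extra feature must buy two CV-accuracy percentage
  points to pay for itself.
- **Restarts**: 4 independent runs; the union of their final generations
  is re-evaluated with 30 independent stratified 2-fold LDA
  cross-validations (common splits across candidates, so comparisons are
  paired) and ranked by mean correct classification rate; ties go to the
  smaller subset, then lexicographic marker order. Sensitivity and
  specificity are pooled over all held-out predictions with the target
  profile as the positive class, and every evaluation records the
  majority-class accuracy floor (128/150 ≈ 0.853) that a useful signature
  must beat.

**Known caveats.** The 30×2-fold estimate evaluates candidates that were
themselves selected on the same cohort, so it retains an optimistic bias
relative to nested cross-validation, which is deliberately out of scope.
Two statistical limits of the calibrated study conditions are worth
stating because they bound what any search can deliver. First, with a
3-marker signature planted at 1.5 latent-SD per marker and 22 positives
out of 150, the triple's true accuracy margin over its best 2-marker
subset is under half a percentage point in roughly half of cohort draws,
while the 30-run evaluation's resolution is of the same order — so the
top-ranked solution recovers the full triple in only ~50–65 % of draws,
with the remainder topped by a high-performing sub-signature or a
near-tied variant. Second, the calibrated Profile-2 insulinemia elevation
(13.3 ± 9.2 vs 9.7 ± 5.6 µU/mL at n = 22 vs 128) yields ~50 % power at
α = 0.05 for the profile-vs-rest contrast, which the acceptance script
reports as the measured rejection rate; a single cross-sectional cohort of
this size sits near the detection boundary for that effect.

## Problem sizes used in the test and acceptance runs

Marginal and copula fidelity are checked on one n = 10,000 draw (3-SE
band for means, ±0.05 for Spearman targets). Cluster recovery uses 20
cohorts per effect size (0.5/1.5/3.0 SD). GA guarantees are exercised on
reduced searches (populations 16–30, 8–12 generations) over a
3-point hyperparameter grid; signature recovery runs the full default
search (100×50×4) on 20 planted cohorts. The acceptance script averages
signature metrics over 5 planted cohorts and estimates the insulinemia
rejection rate over 40 cohorts. These sizes are the package's choices,
balancing Monte-Carlo error against runtime.
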