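# immunosig

Immune-activation profiling and parsimonious biomarker signature selection
for insulin-resistance studies.

## The problem

Chronic immune activation (IA) promotes insulin resistance (IR):
inflammatory signalling (TNFα and its soluble receptor sTNFRI, monocyte
activation read out by sCD163, endothelial activation read out by tPA,
B-cell overactivity read out by IgA) interferes with insulin signalling.
In a cohort of 150 middle-aged volunteers profiled on a panel of 43
immune, endothelial and coagulation markers, five distinct IA profiles can
be distinguished by two-way hierarchical clustering, and one of them —
"Profile 2", marked by CD4⁺ T-cell senescence, inflammation, and
monocyte/B-cell/endothelial activation — carries elevated insulinemia,
HOMA-IR, triglyceridemia and γGT. A signature of only three markers
suffices to recognise this at-risk profile with a low error rate, opening
the door to routine screening.

`immunosig` reimplements that complete analysis as a tested Python
pipeline and, because no individual-level data are deposited with such
studies, pairs it with a calibrated synthetic-cohort generator so every
stage is verifiable end to end:

- **`immunosig.synthetic`** — cohorts with five planted IA profiles
  (sizes 43/22/39/41/5), profile-specific marker elevations, target
  inter-marker Spearman correlations via an exactly calibrated Gaussian
  copula, per-profile metabolic outcome distributions, and therapy
  prevalences.
- **`immunosig.profiling`** — marker standardization and two-way
  hierarchical clustering (`ProfileClusterer`), plus signature-based
  cluster naming.
- **`immunosig.association`** — the profile-vs-rest battery: Student-t /
  Mann–Whitney contrasts with a Shapiro–Wilk gate, Spearman rank
  correlations (exact permutation p for small n), χ²/Fisher 2×2 tests,
  and HOMA-IR = glycemia (mM) × insulinemia (µU/mL) / 22.5.
- **`immunosig.lda`** — a self-contained two-class pooled-covariance
  linear discriminant classifier (`PooledLDA`) with empirical priors and
  deterministic ridge regularization.
- **`immunosig.ga`** — genetic-algorithm wrapper feature selection
  (`GASignatureSelector`): subsets of ≤ 10 markers evolved by mutation
  (add/remove/substitute), cross-over and tournament selection with
  elitism, scored by

  *fitness(S) = mean 2-fold CV LDA accuracy − λ·|S|* (λ = 0.02),

  run from four independent restarts; every member of the final
  generations is then re-evaluated with 30 independent stratified 2-fold
  LDA cross-validations and ranked by mean correct classification rate.

The profiling, LDA and GA components are scikit-learn-style estimators
(`fit` / `predict` / `transform`, `get_params`) and compose with sklearn
pipelines and model selection.

## Worked example

```python
import immunosig as im

# 1. simulate a 150-subject cohort with the five calibrated profiles
cohort = im.generate_cohort(im.default_config(), seed=7)

# 2. recover profiles by two-way hierarchical clustering and name them
clusterer = im.ProfileClusterer(k_profiles=5).fit(cohort)
naming = im.name_profiles(clusterer.labels_, cohort)
labels = naming.relabel(clusterer.labels_)

# 3. Profile-2-vs-rest contrasts
for var in ("insulinemia", "homa"):
    gc = im.compare_profile_vs_rest(cohort, labels, var)
    print(f"{var}: {gc.mean_a:.1f} vs {gc.mean_b:.1f} "
          f"({gc.method}, p = {gc.p_value:.3f})")

# 4. GA signature selection for Profile 2 (reduced search for the example)
sel = im.GASignatureSelector(population_size=40, n_generations=20,
                             n_restarts=2, seed=7).fit(cohort.markers, labels == 2)
best = sel.best_evaluation_
print("best subset:", "+".join(sorted(best.subset)))
print(f"error {best.error_rate:.1%}, sensitivity {best.sensitivity:.1%}, "
      f"specificity {best.specificity:.1%}")
```

prints

```
insulinemia: 13.6 vs 9.5 (mann_whitney, p = 0.005)
homa: 3.8 vs 2.3 (mann_whitney, p = 0.001)
best subset: iga+pct_cd57_cd4+pct_em_cd4+pct_naive_cd4
error 1.2%, sensitivity 97.0%, specificity 99.1%
```

The recovered Profile-2 group shows the expected hyperinsulinemia and
elevated HOMA-IR, and the selected signature is a small subset of the
planted Profile-2 markers. Sensitivity below specificity is the expected
operating point under 22:128 class imbalance with empirical priors.

A command-line interface mirrors the library
(`immunosig simulate|profile|associate|signature|report`); `report` runs
the whole pipeline and writes a manifest with checksums of every output.

### Cohort file schema

`simulate`/`read_cohort` exchange three UTF-8 CSV tables keyed by
`subject_id`: `markers.csv` (43 numeric marker columns), `metabolic.csv`
(insulinemia µU/mL, glycemia mM, triglycerides/HDL/LDL/cholesterol mM,
waist/hip cm, systolic/diastolic mmHg, gamma_gt UI/L, alcohol g/day), and
`therapy.csv` (boolean antidiabetic / antihyperlipidemic /
antihypertensive, optional integer `profile`).

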