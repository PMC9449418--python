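# Methods

This note records the statistical model the package implements, the
conventions and defaults chosen where several were defensible, and what
the synthetic-data tests do and do not establish.

## Cohort model

One baseline visit per subject before 6 months: a 14-nutrient milk panel
(TSFA, TMUFA, TPUFA, n-6/n-3, ARA, DHA, ARA/DHA, PC, PE, PI, SPH, free
choline, PCho, GPC), four confounders (age in months, sex, site,
household income < 75k indicator), MSEL subscale T-scores and/or 14 IBQ-R
subscale means, and follow-up assessments binned at (6, 9], (9, 12] and
(12, 18] months. Composite outcomes are the early learning composite
(ELC = VR + FM + RL + EL, gross motor excluded) and the three IBQ-R
factors (surgency, negative affectivity, orienting/regulation) as
weighted averages of the subscales under a user-supplied loading matrix.
The loadings shipped in `data/ibq_loadings_placeholder.csv` are a
synthetic placeholder (each subscale loading on one factor with unit
weight) so that the pipeline runs end-to-end; real analyses must supply
published factor loadings. Factors are normalized weighted averages
(divide by the weight sum); a switch yields raw weighted sums.

## Preprocessing conventions

- Nutrients are z-scored (sample SD, ddof = 1) **within each instrument's
  analysis subset**, because the MSEL and IBQ-R models are fit on
  different subject sets; originals are kept under a `raw_` prefix.
- Confounders stay on their raw scale. "Standardized coefficient" for
  both the marginal and joint models means: outcome and nutrients
  z-scored, confounders raw, nutrient OLS coefficients reported. This
  convention reproduces the t-based CI arithmetic of the marginal model
  at n − 6 residual df.
- Missing income indicators are single-mean-imputed from the observed
  values (fractional imputed values are intentional); no multiple
  imputation.
- Cohort description utilities: per-nutrient age trends by simple linear
  regression on age, and Welch's two-sided t-test (not pooled-variance,
  which the equal-variance assumption would not support at these sizes)
  comparing nutrient means between the two instrument subsets, which may
  overlap.

## Marginal scan and FDR families

Each nutrient × outcome pair is fit separately; BH step-up adjustment is
applied within a configurable family. The default family is all pairs of
one instrument (84 for MSEL with 6 outcomes, 42 for IBQ-R with 3); a
`family_size` override supports families only partially represented in a
given scan, which is why the adjustment is implemented directly (~6
lines) rather than delegated — statsmodels' `fdr_bh` is used as a test
oracle and agrees to 1e-12 when the family equals the input.

## Clustering

Distance is d = 1 − r on **signed** correlations: thresholds are applied
to raw correlation coefficients and all block structure of interest is
positive; a flag offers 1 − |r|. Three equivalent constructions of the
threshold partition (graph components of {r > T_c}, merge-tree cut,
MST-edge cut) are implemented and cross-checked on random instances.
Thresholds compare strictly (r > T_c); stability intervals are reported
as (low, high] where the upper endpoint is the merge correlation that
dissolves the partition. With continuous data the boundary convention is
immaterial; at an exact tie the strict rule applies.

Dunn index: minimum single-linkage inter-cluster distance divided by the
maximum intra-cluster diameter, singletons contributing diameter zero. It
is undefined (a distinct error, not a value) for fewer than two clusters
or when every cluster is a singleton. Including singletons at diameter
zero is a choice; the alternative (excluding them from the diameter
maximum) changes no ordering on the shipped defaults but is flagged here.
Equal Dunn values break toward fewer clusters, then the lower threshold
interval (parsimony, determinism). The sample correlation matrix is
symmetrized exactly before clustering; `np.corrcoef` carries ~1e-17
asymmetry that would otherwise split tied edges.

## Joint selection

Candidates are all nutrient subsets with at most one member per cluster,
empty set included (count = product of cluster sizes + 1 each; 1200 for
the reference 7-cluster panel). Confounders are always included and never
count toward the constraint. The objective is adjusted R² with
`n_regressors` = selected nutrients + number of confounders (excluding
the intercept); this convention reproduces the published (R², adjusted
R²) bookkeeping exactly at both cohort sizes. Ties break toward smaller
subsets, then lexicographic names. Rank-deficient candidate designs are
skipped with a log message, never a crash. The search runs on numpy
least squares; the selected model is refit with statsmodels for
coefficient inference and AIC (reported, not optimized).

Significance is the nested ANOVA F against the confounder-only model,
with BH across the instrument's outcomes. This p-value is computed on the
data used for selection and is anti-conservative; results carry that
label (`note` field) rather than any selective-inference correction,
matching the procedure being reproduced.

## Cross-validation and follow-up

CV fixes the selected nutrient set and refits coefficients per training
fold (uniform random folds, no stratification); per repetition, the
pooled out-of-fold predictions give one Pearson correlation and one mean
squared error. The significance threshold r\* solves
r√((n−2)/(1−r²)) = t_{0.975, n−2}. A repetition counts as significant
when its correlation **exceeds +r\***: under a null model out-of-fold
predictions are negatively biased (fold means anti-correlate with
held-out values), so a two-sided count would flag anti-predictive noise
fits as successes; with the one-sided count the null rate is ≈ 5%
(measured ≈ 0.055, bimodal across datasets — usually 0, occasionally
large — so calibration statements average many independent datasets).

Follow-up prediction applies the frozen baseline coefficients to each
follow-up subject's baseline standardized nutrients and baseline
confounders; the baseline age is the default age covariate (the
coefficients were trained on baseline ages), with a flag to substitute
the follow-up age. Bins require at least 3 unique subjects.

## Synthetic cohort generator

The generator emulates the study conditions, not milk biology:

- Nutrients: multivariate normal on the standardized scale, affinely
  mapped to the published panel means/SDs, truncated at zero. The default
  correlation target is block-structured (within-cluster 0.8, between
  0.1) over the reference 7 clusters, plus two documented cross-links:
  PCho–choline 0.50 and TSFA–PC 0.28. Non-PSD user targets are repaired
  by eigenvalue clipping; repairs beyond Frobenius distance 0.05 are an
  error.
- Truncation: the guard is the **analytic** clip probability
  Φ(−mean/sd) per nutrient (limit 10%), so small samples cannot trip it
  by chance; realized fractions are logged and returned. Under the
  published moments, DHA clips ≈ 5.2% and free choline ≈ 6.2% of draws —
  a consequence of normal marginals with means < 2 SD above zero — which
  raises their realized means slightly; nutrients well away from zero
  (e.g. TSFA) match their published moments to Monte-Carlo error.
- Outcomes: linear in z-scored predictors plus Gaussian noise. With
  `target_r2` set, the noise SD is scaled to the realized linear-predictor
  variance so the generating model's R² equals the target conditional on
  the sampled design. Default models use the five reported outcome
  equations (their standardized coefficients and R² values); unmodelled
  outcomes are confounder-free noise. Constant predictors in a small
  stratum (e.g. a one-sex follow-up bin) carry no signal and are skipped.
- Design: exact stratified draws reproduce the configured counts
  (54/38/42/26 subjects, 19 male, 2 incomes missing completely at
  random); follow-up subjects are drawn from the instrument's baseline
  pool with ages clipped into their bins. Follow-up scores default to the
  same frozen generating model with fresh noise (`followup_signal_decay`
  = 1); the decay of association with age is the analysis question, so it
  is a parameter, not an assumption.

What passing tests show: the pipeline's machinery is correct (oracle
agreement, calibration, recovery of planted effects at n = 200) and its
small-sample behaviour is faithful to the design. What they do not show:
anything about real milk composition — the generator has no lactation
kinetics, no assay error structure, no skewed marginals beyond zero
truncation, and placeholder factor loadings.

## Problem sizes and determinism

Calibration checks use 2 000 null simulations in the test suite (20 000
in the acceptance script, where the tighter Monte-Carlo SE matters);
planted-model recovery uses 100 seeds at n = 200; oracle equivalence uses
200 random instances at p ≤ 10 and exhaustive best-subset checks at ≤ 6
clusters. All randomness flows through `numpy.random.Generator` seeded
from a single integer; identical config + seed reproduces every output
file byte-for-byte.

## Known limitations

- Exact member identification inside a highly correlated cluster is
  information-limited: with a weak effect (standardized 0.19) and
  three siblings at r = 0.8, no selector reliably names the true member
  at n = 200 (measured ≈ 60%); the pipeline's guarantee is cluster-level
  representation (≈ 98–99%), with coefficients unbiased once the set is
  fixed.
- The post-selection F-test is anti-conservative by construction and only
  labelled as such.
- Single mean imputation understates income uncertainty; acceptable at 2
  missing of 54.
- The marginal-scan FDR family is configurable because reported adjusted
  p-values in this design cannot be uniquely reverse-engineered from the
  printed values; the per-instrument default is one defensible choice.
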