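# milkcog

Joint association analysis of human-milk nutrients with infant cognition
and temperament.

Studies of breast-milk composition and neurodevelopment usually test one
nutrient at a time, but milk nutrients are strongly collinear (fatty acids,
phospholipids and choline metabolites travel in correlated blocks), so
marginal scans both miss joint effects and double-count shared signal.
`milkcog` implements a pipeline for small observational cohorts in which a
14-nutrient milk panel is measured once per mother and infant cognition
(Mullen Scales of Early Learning, MSEL) and temperament (Infant Behavior
Questionnaire–Revised, IBQ-R) are assessed at a baseline visit under 6
months with follow-ups to 18 months. It is aimed at biostatisticians and
nutrition researchers working with collinear predictor panels and small n.

## The method

1. **Marginal scan (model M0).** For each nutrient X and outcome Y,

   `Y_z ~ 1 + age + sex + site + income + X_z`

   with Y and X z-scored and confounders raw; the nutrient's OLS
   coefficient is the standardized coefficient r, with t-based 95% CI and
   p-value on n − 6 df, Benjamini–Hochberg adjusted within the
   instrument's nutrient × outcome family.

2. **Nutrient clustering.** Pearson correlations among the 14 nutrients;
   single-linkage clustering under distance d = 1 − r. Cutting the merge
   tree at threshold T_c equals taking connected components of the graph
   {r_ij > T_c} and equals cutting the minimum spanning tree — three
   constructions of the same partition, all exposed. The partition
   maximizing the Dunn index (minimum inter-cluster single-linkage
   separation over maximum intra-cluster diameter) is selected, reported
   with its stability interval of thresholds.

3. **Cluster-constrained best subset (model M1 vs M2).** All nutrient
   subsets with at most one member per cluster are fit by OLS (confounders
   always included); the subset maximizing adjusted R² is selected. Model
   significance is the nested ANOVA F-test against the confounder-only
   model M2, BH-adjusted across the instrument's outcomes, and labelled as
   post-selection (anti-conservative).

4. **Validation.** 100 repetitions of 5-fold cross-validation with the
   selected set fixed and coefficients refit per fold; pooled out-of-fold
   Pearson correlation and squared error per repetition, compared against
   the significance threshold r\* solving the t-quantile equation at the
   cohort size. Follow-up scores in age bins (6–9], (9–12], (12–18] months
   are predicted from frozen baseline coefficients and compared with
   Pearson's t-test.

Because real cohort data of this kind are not public, the package ships a
**synthetic cohort generator**: nutrients are multivariate normal on the
standardized scale with a block correlation target (truncated at zero and
mapped to published panel means/SDs), outcomes are linear in standardized
predictors with noise calibrated to a target R², and availability patterns
(38 MSEL / 42 IBQ-R of 54 subjects, 2 missing incomes, binned follow-ups)
are reproduced exactly.

## Worked example

```sh
milkcog cluster --seed 1 --out out/
# selected k=7 clusters (Dunn 1.70, Tc in 0.48 < Tc <= 0.73)
```

The full pipeline from Python:

```python
from milkcog.pipeline import PipelineConfig, run_pipeline

res = run_pipeline(PipelineConfig(seed=1, output_dir="out", cv_reps=100))
sel = res.partition_scan.selected
print(sel.k, sel.interval_label, round(sel.dunn, 2))
# 7 "0.48 < Tc <= 0.73" 1.7
```

With seed 1 the simulated 54-subject cohort recovers the generator's
7-cluster structure (bulk fatty acids + ARA; n-6/n-3; DHA with ARA/DHA;
the four phospholipids; the three choline metabolites apart), stable for
thresholds 0.48 < T_c ≤ 0.73 with Dunn index 1.70. The surgency model's
cross-validation summary for the same run:

```python
cv = res.cv["ibq_sur"]
print(round(cv.mean_correlation, 3), cv.interval, cv.fraction_significant)
# 0.264 (0.106, 0.414) 0.26
```

i.e. a mean out-of-fold prediction correlation of 0.26 with 95% of
repetitions between 0.11 and 0.41, clearing the n = 42 significance
threshold in 26% of repetitions — at n = 42 with realistic noise the
selected model predicts, but not in every random split. Follow-up
prediction for surgency at 12–18 months on the same run gives r = 0.61
(p = 0.0008, n = 27): the planted baseline association persists because
the generator's follow-up scores come from the same frozen model.

Every stage writes a CSV (`marginal_*`, `correlations`, `partitions`,
`mst_edges`, `selection_*`, `cv_summary`, `followup_summary`) plus a run
log; identical config and seed reproduce every file byte-for-byte.

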