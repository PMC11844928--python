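# Methods

## Overview

`pegskit` implements poly-epigenetic scores (PEGS, also called methylation
risk scores) for eight cardiometabolic risk factors — systolic and diastolic
blood pressure (SBP/DBP), body mass index (BMI), C-reactive protein (CRP),
HDL and LDL cholesterol, triglycerides (TG) and fasting glucose — together
with the regression machinery used to validate them: covariate-adjusted
association models, incremental variance attribution, race-stratified and
sample-weighted variants, and moderation analysis with simple slopes,
BH-FDR and Johnson–Neyman regions of significance.

A PEGS for individual *i* is the weighted sum over *k* trait-associated CpGs

    PEGS_i = w_1 m_i1 + … + w_k m_ik

where *m_ik* are (pre-adjusted) methylation beta values in [0,1] and *w_k*
are external weights taken from a published epigenome-wide association
study (EWAS).

## Weight orientation transformation

EWAS report either the regression of the trait on methylation
(`meth_independent`) or of methylation on the trait (`meth_dependent`).
Scores require the former orientation, so methylation-as-outcome
coefficients are converted via

    R² = Z² / (Z² + N − 1)
    β* = β (1 − R²) / ((N − 1) SE²)

with Z, β, SE, N the reported association statistics. Algebraically, for a
simple regression of y on x, β (1−R²)/((N−1) SE²) equals the slope of x on y
times (N−2)/(N−1); at EWAS sample sizes (all N > 10,000 here) the factor is
negligible, and the reverse-regression experiment in
`pegskit.validation.reverse_regression_experiment` measures the median
relative error of the transformation against directly fitted reverse slopes
(simulated bivariate data, n = 5,000, 200 replicates).

CpG selection keeps records that are Bonferroni-significant in the source
EWAS *and* measured on the target array; an empty selection is an error
because the score would be undefined. CpGs failing array QC are excluded
silently with a logged count. Absent Z-scores are filled by the Wald
identity Z = β/SE. Duplicate CpG ids in one catalog are a hard error
rather than being averaged, since weight provenance must be unambiguous.

## Methylation preprocessing

Operating on a post-QC beta matrix (array normalization, detection-p
filtering and sample QC are upstream concerns):

1. **Mean imputation.** Missing beta values are replaced by the CpG's mean
   over observed samples; this preserves each CpG's mean exactly. A CpG
   with no observed values raises.
2. **Batch/cell residualization.** Each CpG is regressed on plate,
   plate-row and plate-column indicators (unordered categoricals,
   first-level reference coding) plus the five reference-based white-cell
   proportions (NK, B, CD4, CD8, monocyte) entered untransformed. The
   adjusted value is the OLS residual plus the CpG's grand mean, keeping
   values on an interpretable beta-like scale; the constant is immaterial
   after standardization. All CpGs are fit at once with a single
   least-squares solve; rank-deficient designs (aliased batch levels,
   compositional collinearity) fall back to the minimum-norm solution,
   equivalent to dropping aliased columns, with a warning.

Order of operations is impute → residualize → score, so the adjustment
design stays balanced. Residuals are orthogonal to every design column
(checked to 1e−8) and the adjustment is idempotent.

## Score standardization and winsorization

Raw scores are standardized over the full analysis sample (sample SD,
ddof = 1) and then clipped at ±5 SD without re-standardizing — clipping
first would move the 5-SD fence. The same full-sample standardization is
reused in stratified analyses (one score per trait, not per stratum).

## Phenotypes and covariates

* **Blood pressure**: per-reading censoring — SBP readings above 250 mmHg
  and DBP readings below 40 mmHg are removed (strict inequalities; each
  channel independently) and the surviving readings averaged; a channel
  with no survivors is missing.
* **BMI** = weight (kg) / height (m)².
* **LDL-C** by Friedewald: TC − HDL-C − TG/5 (mg/dL), defined only for
  TG < 400 mg/dL (strict bound).
* **Log transforms**: CRP, HDL-C, TG and glucose are modeled as natural
  logs. Glucose is restricted to self-reported fasting samples.
* **Winsorization**: every trait is clipped at mean ± 5 SD on its analysis
  scale, with the fence computed from the pre-winsorization moments in a
  single pass.
* **Drinking (NIAAA)**: drinks/day = weekly units / 7; heavy is > 2/day for
  men aged ≤ 65 and > 1/day for women ≤ 65 and everyone older than 65;
  zero is a nondrinker, the remainder moderate.
* **Dichotomies** for moderation: current vs non-current smoker, ever vs
  never smoker, heavy vs non-heavy drinker, ≥ high school vs less.

## Association models

Model 1 covariates: age, sex, race/ethnicity (4 levels), education
(3 levels) and relevant medication use — antihypertensives for SBP/DBP,
lipid-lowering for HDL/LDL/TG, diabetes medication for glucose, none for
BMI and CRP. Model 2 adds smoking (3 levels), drinking (3 levels) and
physical activity. LDL-C and TG models additionally adjust for fasting
status. Fits are complete-case OLS (or WLS with sample weights);
p-values use the t distribution with residual df. Incremental R² is
R²(covariates + PEGS) − R²(covariates only) on the identical sample, which
is nonnegative for nested OLS. The sample-weighted variant reports WLS
point estimates with HC1 sandwich standard errors — an approximation to a
full design-based (strata/PSU) variance, which is out of scope.

Ln-scale coefficients are converted to raw units for a person at the sample
mean via `mean × (exp(β) − 1)`.

## Moderation analysis

Seven modifiers per trait: centered age, sex (reference male), the
education, current-smoking, ever-smoking and heavy-drinking dichotomies,
and physical activity. A modifier that re-codes a Model 2 covariate
replaces its 3-level parent in the design (avoiding aliasing), and a
modifier already in Model 2 enters once. Age is centered at the
complete-case mean; Johnson–Neyman boundaries are reported on the original
age scale.

The conditional slope at modifier value x is b₁ + b₃x with variance
V₁₁ + 2x V₁₃ + x² V₃₃ from the coefficient covariance. The JN region
solves (b₁ + b₃x)² = t²_crit (V₁₁ + 2x V₁₃ + x² V₃₃) — a quadratic with
0–2 real roots — using two-sided t critical values with residual df, and
classifies sub-intervals of the observed range by the midpoint p-value.
Degenerate cases (b₃ = V₃₃ = 0) collapse to the marginal test. The
interaction p-values are BH-adjusted within each trait's 7-modifier family.

Predicted-value tables fix remaining continuous covariates at their means
and categorical ones at their reference level, with pointwise CIs from the
full covariance.

## Synthetic-study generator

The generator emulates the structure of a population methylation study of
older US adults so every stage can be validated without restricted data.

* **Covariates**: age ~ truncated Normal(69.5, 9.6²) on [55, 100] (the
  `age_mean` field is the location parameter; left truncation lifts the
  realized mean by ~1.2 y), 58.7% female, race 66.5/16.3/14.1/3.1%,
  smoking 44.5/44.1/11.4%, education 16.7/59.2/24.1%, 47.2% physically
  active, 60.8% nondrinkers with lognormal weekly units among drinkers,
  medication flags with age-increasing logits, 66% fasting, lognormal
  sample weights normalized to mean 1.
* **Methylation**: per-CpG latent normals with additive plate/row/column
  shifts (SD 0.05 on the logit scale), linear cell-proportion loadings
  (cell proportions from a Dirichlet over six blood components, five
  reported), idiosyncratic SD 0.4, mapped through the inverse logit so all
  values lie strictly in (0,1); missingness completely at random (default
  1%, a realistic post-QC rate).
* **Catalogs**: per-CpG (β, SE, Z, N) internally consistent (Z = β/SE)
  under a configurable orientation mix; methylation-as-outcome rows are
  constructed so the orientation transformation reproduces the generating
  weight exactly. Extra non-significant and off-array rows exercise CpG
  selection.
* **Phenotypes**: trait = intercept + β_true·(true score) + covariate
  effects + interaction terms + Normal noise on the analysis scale;
  ln-scale traits are exponentiated into the raw columns; BP is emitted as
  reading pairs with rare (0.5%) artifact readings so censoring is
  exercised; BMI is back-constructed through height and weight; LDL-C
  through TC/HDL/TG so the Friedewald rule is exercised.
* **Truth definition**: the "true standardized score" is the weighted sum
  of clean (batch-free) beta values with the generator's known batch/cell
  design projected out — the technical-artifact-free methylation signal,
  which is precisely the estimand of the preprocessing step. This keeps
  the recovery experiments estimand-aligned; residual attenuation from
  mean imputation and the mild non-linearity of the logistic link is below
  1% of the effect size at the default settings.
* **Effect sizes** default to values giving comfortable power at
  n ≈ 2,000–4,000 (e.g. BMI slope 2.4 kg/m² per SD against noise SD 6,
  an incremental R² of ~0.14); they are not calibrated to any external
  dataset beyond that.

What the generator does **not** emulate: genome-scale CpG counts,
co-methylation (LD-like) blocks, informative missingness, survey design
strata/PSU, or non-linear score–trait relationships. Passing recovery
tests therefore demonstrate correctness of the estimation machinery under
the stated generating model, not performance on real cohort data.

## Validation experiment sizes

Chosen to give stable Monte-Carlo estimates at interactive run times:
reverse-regression oracle n = 5,000 × 200 replicates; JN-vs-grid check 50
fits at n = 500 against a 10,000-point grid; CI coverage 1,000 replicates
of two-trait studies at n = 2,000 (Monte-Carlo SE ≈ 0.7% on the coverage
rate) with a true −0.06 kg/m²·SD⁻¹·year⁻¹ age interaction on BMI; null FDR
calibration 250 replicates × 2 trait-families at n = 400 (the null
calibration of BH is sample-size-free). The full-scale marginals above are
used unchanged in all experiments.

## Known limitations

* Survey-design variance is approximated by HC1 sandwich SEs on WLS.
* Complete-case analysis throughout; no phenotype imputation.
* The orientation transformation assumes the source EWAS coefficient comes
  from (approximately) a simple association; heavy covariate adjustment in
  the source EWAS changes the recoverable reverse slope.
* One score per trait: no per-stratum re-derivation or re-standardization.
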