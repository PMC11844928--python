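# pegskit

Poly-epigenetic scores (PEGS, also called methylation risk scores) summarize
an individual's DNA methylation at trait-associated CpG sites into a single
epigenetic surrogate for a clinical trait. `pegskit` builds such scores for
eight cardiometabolic risk factors — systolic/diastolic blood pressure, BMI,
C-reactive protein, HDL-C, LDL-C, triglycerides and fasting glucose — from
published EWAS summary statistics, and provides the analysis layer used to
validate them in a cohort: covariate-adjusted association models,
incremental variance attribution, race-stratified and sample-weighted fits,
and moderation analysis (simple slopes, BH-FDR, Johnson–Neyman regions).
It is aimed at epigenetic epidemiologists working with array-based
methylation (e.g. Illumina EPIC) and phenotype-rich cohort data.

## The method

For individual *i*, the score over *k* selected CpGs with external weights
*w* is the weighted sum of (pre-adjusted) beta values *m* ∈ [0,1]:

    PEGS_i = w_1 m_i1 + … + w_k m_ik

Selected CpGs are those Bonferroni-significant in the source EWAS and
present on the target array. When the source EWAS modeled methylation as
the *dependent* variable, its coefficient is re-oriented before use:

    R² = Z² / (Z² + N − 1),    β* = β (1 − R²) / ((N − 1) SE²)

which recovers the slope of the reverse (trait-on-methylation) regression.
Before scoring, each CpG is mean-imputed and residualized on batch factors
(plate, plate row, plate column) and estimated white-cell proportions;
scores are standardized and winsorized at ±5 SD. Associations are fit as

    trait ~ PEGS + age + sex + race/ethnicity + education [+ medication]
            [+ smoking + alcohol + physical activity] [+ fasting]

and moderation models add `modifier + PEGS × modifier`, with conditional
slopes b₁ + b₃x and Johnson–Neyman boundaries solved from the coefficient
covariance. See `docs/methods.md` for the full model description.

Because the motivating cohort data are access-restricted, the package ships
a seed-reproducible synthetic-study generator (`pegskit.simulate`) that
emulates the data structure — beta-valued methylation with batch and
cell-composition structure, realistic covariate marginals, phenotypes with
known score and interaction effects — so every stage is testable end to end.

## Worked example

```python
import pegskit as pk

cfg = pk.GeneratorConfig(seed=7, n_samples=3000, traits=("bmi", "tg"))
study = pk.simulate_study(cfg)          # known truth: bmi 2.4, tg 0.17
res = pk.run_pipeline(study)            # impute -> residualize -> score

fit = pk.fit_association(pk.ModelSpec("tg"), res.pegs["tg"], res.table)
print(fit.summary_row())
```

prints (seed 7):

```
{'trait': 'tg', 'model': 'model2', 'stratum': 'all', 'n': 3000,
 'beta': 0.17041..., 'se': 0.00897..., 'r2_incremental': 0.10568...,
 'p': 5.88...e-76}
```

The score-trait slope 0.170 (truth 0.17) is the change in ln(TG) per 1-SD
higher TG score; the score explains ~10.6% of ln(TG) variance beyond the
covariates. Converting to raw units at the sample mean:

```python
import numpy as np
tg_mean = float(np.exp(res.table["ln_tg"]).mean())   # 140.1 mg/dL
pk.back_transform_effect(fit.beta, tg_mean)          # +26.0 mg/dL per SD
```

The `examples/` directory contains one short narrative script per
capability: weight orientation (`01`), preprocessing and scoring (`02`),
phenotype rules (`03`), association models (`04`), moderation analysis
(`05`) and the file-driven pipeline (`06`).

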