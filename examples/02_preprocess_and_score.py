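"""Impute, batch-adjust and score a synthetic methylation matrix.

Simulates a small study, runs the preprocessing chain (mean imputation, then
per-CpG residualization on plate/row/column and cell proportions) and
computes the standardized, 5-SD-winsorized score for BMI.
"""

import numpy as np

import pegskit as pk

cfg = pk.GeneratorConfig(seed=42, n_samples=500, n_cpgs_per_trait=10,
                         traits=("bmi",), missing_rate=0.03)
study = pk.simulate_study(cfg)

m = study.methylation
print(f"beta matrix: {len(m.sample_ids)} samples x {len(m.cpg_ids)} CpGs, "
      f"{m.values.isna().to_numpy().mean():.1%} missing")

imputed = pk.impute_missing(m)
adjusted = pk.residualize_cpgs(imputed)
print(f"design used: {len(adjusted.adjustment_meta['design_columns'])} columns "
      f"(rank {adjusted.adjustment_meta['design_rank']})")

weights = pk.finalize_weights(
    pk.select_cpgs(study.catalogs["bmi"], set(m.cpg_ids)))
score = pk.standardize_winsorize(pk.compute_pegs(adjusted, weights, "bmi"))

print(f"\nBMI score over {score.n_cpgs_used} CpGs: "
      f"mean={score.z.mean():+.3f}, SD={score.z.std(ddof=1):.3f}, "
      f"range=[{score.z.min():.2f}, {score.z.max():.2f}]")
corr = np.corrcoef(score.z, study.truth.true_scores["bmi"])[0, 1]
print(f"correlation with the generating score: {corr:.3f}")
# ~0.98 at this small n: batch adjustment and imputation recover the signal
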