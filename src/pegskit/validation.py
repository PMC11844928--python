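"""Validation experiments: worked examples and simulation-based checks.

These routines back the package's reproducibility claims.  The worked
examples evaluate the effect back-transformation and the interaction simple
slope on published summary inputs; the simulation experiments measure, under
the synthetic-study generator, (a) the accuracy of the EWAS orientation
transformation against directly fitted reverse regressions, (b) agreement of
the analytic Johnson–Neyman boundaries with a dense grid search, (c)
confidence-interval coverage of the generating effects, and (d) the
per-family false-positive rate of the BH-FDR interaction screen under the
null.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .association import ModelSpec, back_transform_effect, fit_association
from .interaction import InteractionFit, fit_interaction, interaction_scan, johnson_neyman, simple_slope
from .pipeline import run_pipeline
from .simulate import GeneratorConfig, simulate_study
from .weights import EWASWeightRecord, transform_weight

#: published Model 2 ln-scale coefficients and sample means of the log-scale
#: traits (mg/dL for TG/HDL/glucose, mg/L for CRP)
LN_SCALE_EXAMPLES = {
    "tg": (0.17, 147.4),
    "crp": (0.32, 4.9),
    "hdl": (0.08, 56.9),
    "glucose": (0.03, 111.3),
}

#: CRP × education interaction worked example: PEGS slope at the reference
#: (< high school), interaction coefficient, and the sample-mean CRP (mg/L)
CRP_EDUCATION_EXAMPLE = {"beta_pegs": 0.22, "beta_int": 0.13, "crp_mean": 4.9}


def worked_example_effects() -> dict[str, float]:
    """Raw-scale effects per 1-SD score from ln-scale coefficients."""
    return {
        trait: back_transform_effect(beta, mean)
        for trait, (beta, mean) in LN_SCALE_EXAMPLES.items()
    }


def education_simple_slope_example() -> dict[str, float]:
    """Raw-scale CRP effect per 1-SD score in the two education subgroups.

    Builds the conditional slopes at the two levels of a 0/1 modifier from
    the published coefficients and converts each to mg/L at the sample-mean
    CRP.  The covariance block only affects SEs, not the slopes themselves.
    """
    ex = CRP_EDUCATION_EXAMPLE
    fit = InteractionFit(
        trait="crp", modifier="education2", n=0,
        beta_pegs=ex["beta_pegs"], beta_mod=0.0, beta_int=ex["beta_int"],
        cov=np.eye(3) * 1e-4, df_resid=1000.0,
    )
    slope_lo, _, _ = simple_slope(fit, 0.0)   # < high school (reference)
    slope_hi, _, _ = simple_slope(fit, 1.0)   # high school degree or above
    return {
        "slope_hs_or_more": slope_hi,
        "effect_hs_or_more": back_transform_effect(slope_hi, ex["crp_mean"]),
        "effect_lt_hs": back_transform_effect(slope_lo, ex["crp_mean"]),
    }


def reverse_regression_experiment(
    seed: int, n: int = 5000, reps: int = 200
) -> dict[str, float]:
    """Orientation transformation vs directly fitted reverse regressions.

    Simulates paired (trait, methylation) data with a known
    methylation-on-trait slope, fits the forward regression to obtain
    (β, SE, Z, N), transforms, and compares with the directly fitted
    trait-on-methylation slope.  Returns the median relative error.
    """
    rng = np.random.default_rng(seed)
    rel_errors = np.empty(reps)
    for i in range(reps):
        trait = rng.normal(0.0, 1.0, n)
        slope = rng.uniform(0.02, 0.10) * rng.choice([-1.0, 1.0])
        meth = slope * trait + rng.normal(0.0, 0.12, n)
        X = np.column_stack([np.ones(n), trait])
        coef, *_ = np.linalg.lstsq(X, meth, rcond=None)
        resid = meth - X @ coef
        se = np.sqrt(
            resid @ resid / (n - 2) / ((trait - trait.mean()) ** 2).sum()
        )
        rec = EWASWeightRecord(
            "cg", float(coef[1]), float(se), n, "meth_dependent",
            z=float(coef[1] / se),
        )
        w = transform_weight(rec).w
        Xr = np.column_stack([np.ones(n), meth])
        rev = np.linalg.lstsq(Xr, trait, rcond=None)[0][1]
        rel_errors[i] = abs(w - rev) / abs(rev)
    return {"median_rel_error": float(np.median(rel_errors)), "n": n,
            "reps": reps}


def jn_grid_experiment(
    seed: int, n_fits: int = 50, n: int = 500, grid_points: int = 10_000
) -> dict[str, float]:
    """Analytic Johnson–Neyman boundaries vs a dense grid search.

    Fits moderation models on simulated studies with varying age-interaction
    strength, computes the analytic region, and classifies a dense grid of
    simple-slope p-values.  Returns the worst boundary discrepancy in grid
    steps and the worst misclassified grid fraction.
    """
    rng = np.random.default_rng(seed)
    worst_steps = 0.0
    worst_frac = 0.0
    for i in range(n_fits):
        coef = float(rng.uniform(-0.12, 0.02))
        cfg = GeneratorConfig(
            seed=int(rng.integers(2**31 - 1)), n_samples=n,
            n_cpgs_per_trait=5, traits=("bmi",),
            interactions={("bmi", "age_centered"): coef},
        )
        res = run_pipeline(simulate_study(cfg))
        fit = fit_interaction("bmi", "age_centered", res.pegs["bmi"], res.table)
        lo, hi = float(res.table["age"].min()), float(res.table["age"].max())
        region = johnson_neyman(fit, (lo, hi))
        grid = np.linspace(lo, hi, grid_points)
        x = grid - fit.modifier_center
        slope = fit.beta_pegs + fit.beta_int * x
        var = fit.cov[0, 0] + 2 * x * fit.cov[0, 2] + x**2 * fit.cov[2, 2]
        p = 2 * stats.t.sf(np.abs(slope / np.sqrt(var)), fit.df_resid)
        sig = p < region.alpha
        step = grid[1] - grid[0]
        in_any = np.zeros_like(sig)
        for a, b in region.significant_intervals:
            in_any |= (grid >= a) & (grid <= b)
        mism = sig ^ in_any
        worst_frac = max(worst_frac, float(mism.mean()))
        interior = [b for b in region.boundaries if lo < b < hi]
        for b in interior:
            # sign of (p - alpha) must flip within one grid step of b
            j = int(np.clip(np.searchsorted(grid, b), 1, grid_points - 2))
            flip = sig[j - 1] != sig[j + 1]
            if not flip:
                worst_steps = max(worst_steps, np.inf)
        # mismatches may only occur within one step of a boundary
        if mism.any():
            d = np.min(
                np.abs(grid[mism][:, None] - np.array(interior)[None, :]),
                axis=1,
            ) if interior else np.full(mism.sum(), np.inf)
            worst_steps = max(worst_steps, float(d.max() / step))
    return {
        "max_boundary_error_grid_steps": worst_steps,
        "max_misclassified_fraction": worst_frac,
        "n_fits": n_fits,
        "grid_points": grid_points,
    }


def recovery_experiment(
    seed: int, reps: int = 100, n: int = 2000
) -> dict[str, float]:
    """95% CI coverage of generating effects across generator replicates.

    Two-trait studies (BMI, ln TG) with a true BMI × age interaction; counts
    replicates whose t-based 95% CI covers the generating main-effect and
    interaction coefficients.
    """
    rng = np.random.default_rng(seed)
    int_coef = -0.06
    covered = {"bmi": 0, "tg": 0, "bmi_x_age": 0}
    for _ in range(reps):
        cfg = GeneratorConfig(
            seed=int(rng.integers(2**31 - 1)), n_samples=n,
            traits=("bmi", "tg"),
            interactions={("bmi", "age_centered"): int_coef},
        )
        study = simulate_study(cfg)
        res = run_pipeline(study)
        for trait in ("bmi", "tg"):
            fit = fit_association(ModelSpec(trait), res.pegs[trait], res.table)
            tcrit = stats.t.ppf(0.975, fit.df_resid)
            truth = study.truth.beta_true[trait]
            if abs(fit.beta - truth) <= tcrit * fit.se:
                covered[trait] += 1
        ifit = fit_interaction("bmi", "age_centered", res.pegs["bmi"], res.table)
        se_int = np.sqrt(ifit.cov[2, 2])
        tcrit = stats.t.ppf(0.975, ifit.df_resid)
        if abs(ifit.beta_int - int_coef) <= tcrit * se_int:
            covered["bmi_x_age"] += 1
    return {
        "coverage_bmi": covered["bmi"],
        "coverage_tg": covered["tg"],
        "coverage_bmi_x_age": covered["bmi_x_age"],
        "reps": reps,
        "n": n,
    }


def null_fdr_experiment(
    seed: int, reps: int = 250, n: int = 400
) -> dict[str, float]:
    """Per-family false-positive rate of the interaction screen under the null.

    Studies with no true interactions; each (replicate, trait) family runs
    all 7 modifier tests with BH-FDR.  Returns the fraction of families with
    any q < 0.05.
    """
    rng = np.random.default_rng(seed)
    families = 0
    positives = 0
    for _ in range(reps):
        cfg = GeneratorConfig(
            seed=int(rng.integers(2**31 - 1)), n_samples=n,
            n_cpgs_per_trait=8, traits=("bmi", "tg"),
        )
        res = run_pipeline(simulate_study(cfg))
        for trait in ("bmi", "tg"):
            fits = interaction_scan(trait, res.pegs[trait], res.table)
            families += 1
            if any(f.q_int < 0.05 for f in fits):
                positives += 1
    return {
        "family_positive_rate": positives / families,
        "families": families,
        "reps": reps,
        "n": n,
    }
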