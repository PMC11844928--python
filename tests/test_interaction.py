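"""Moderation analysis: interaction fits, FDR, simple slopes, Johnson–Neyman."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import pegskit as pk
from pegskit.interaction import MODIFIERS


@pytest.fixture(scope="module")
def moderated():
    """Study with a true age interaction on BMI (−0.06 kg/m² per SD per year)."""
    cfg = pk.GeneratorConfig(
        seed=55, n_samples=3000, n_cpgs_per_trait=10, traits=("bmi",),
        interactions={("bmi", "age_centered"): -0.06},
    )
    study = pk.simulate_study(cfg)
    res = pk.run_pipeline(study)
    fit = pk.fit_interaction("bmi", "age_centered", res.pegs["bmi"], res.table)
    return study, res, fit


class TestFitInteraction:
    def test_age_interaction_recovery(self, moderated):
        study, _, fit = moderated
        se_int = np.sqrt(fit.cov[2, 2])
        assert abs(fit.beta_int - (-0.06)) < 3 * se_int
        assert fit.p_int < 0.01

    def test_all_modifiers_fit(self, moderated):
        _, res, _ = moderated
        fits = pk.interaction_scan("bmi", res.pegs["bmi"], res.table)
        assert [f.modifier for f in fits] == list(MODIFIERS)
        assert all(np.isfinite(f.q_int) for f in fits)
        assert all(f.q_int >= f.p_int - 1e-12 for f in fits)
        tab = pk.interaction_table(fits)
        assert len(tab) == 7

    def test_modifier_enters_once(self, moderated):
        """A modifier that is a Model 2 covariate appears once in the design."""
        _, res, _ = moderated
        fit = pk.fit_interaction("bmi", "current_smoker", res.pegs["bmi"],
                                 res.table)
        names = list(fit.result.params.index)
        assert sum("smoking" in n for n in names) == 0  # replaced by dichotomy
        assert names.count("mod") == 1

    def test_constant_modifier_errors(self, moderated):
        _, res, _ = moderated
        table = res.table.copy()
        table["smoking3"] = "never"
        table["current_smoker"] = False
        with pytest.raises(ValueError, match="constant"):
            pk.fit_interaction("bmi", "current_smoker", res.pegs["bmi"], table)

    def test_dichotomous_subgroup_equivalence(self):
        """With no shared covariates, subgroup slopes equal beta_pegs and
        beta_pegs + beta_int from the pooled interaction model."""
        rng = np.random.default_rng(17)
        n = 1200
        z = rng.normal(size=n)
        grp = rng.random(n) < 0.5
        y = 1.0 + 2.0 * z + 0.5 * grp + 0.8 * z * grp + rng.normal(0, 1, n)
        df = pd.DataFrame({"y": y, "pegs": z, "mod": grp.astype(float)})
        import statsmodels.formula.api as smf

        pooled = smf.ols("y ~ pegs * mod", data=df).fit()
        lo = smf.ols("y ~ pegs", data=df[~grp]).fit()
        hi = smf.ols("y ~ pegs", data=df[grp]).fit()
        assert pooled.params["pegs"] == pytest.approx(lo.params["pegs"], abs=1e-10)
        assert pooled.params["pegs"] + pooled.params["pegs:mod"] == pytest.approx(
            hi.params["pegs"], abs=1e-10)


class TestFDR:
    def test_single_p_identity(self):
        assert pk.fdr_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_bh_with_monotonicity(self):
        """p=(.01,.02,.03,.04), m=4: q_i = min over j>=i of p_j·m/j = 0.04."""
        q = pk.fdr_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(pk.fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_hand_step_up(self):
        """Cross-check against an explicit BH step-up implementation."""
        rng = np.random.default_rng(4)
        p = rng.uniform(1e-6, 1, 7)
        order = np.argsort(p)
        m = len(p)
        q_sorted = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(q_sorted, 1.0)
        np.testing.assert_allclose(pk.fdr_adjust(p), expected, rtol=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            pk.fdr_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            pk.fdr_adjust([0.5, 1.2])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=10))
    @settings(max_examples=100, deadline=None)
    def test_order_invariant(self, pvals):
        p = np.asarray(pvals)
        perm = np.random.default_rng(0).permutation(len(p))
        q = pk.fdr_adjust(p)
        q_perm = pk.fdr_adjust(p[perm])
        np.testing.assert_allclose(q[perm], q_perm, rtol=1e-12)


class TestSimpleSlope:
    def test_level_zero_is_reference(self, moderated):
        _, _, fit = moderated
        slope, se, _ = pk.simple_slope(fit, 0.0)
        assert slope == pytest.approx(fit.beta_pegs)
        assert se == pytest.approx(np.sqrt(fit.cov[0, 0]))

    def test_linear_combination(self, moderated):
        _, _, fit = moderated
        slope, _, _ = pk.simple_slope(fit, 10.0)
        assert slope == pytest.approx(fit.beta_pegs + 10 * fit.beta_int)

    def test_recentering_oracle(self, moderated):
        """Slope and SE at level L equal the PEGS coefficient of the same
        model with the modifier re-centered at L."""
        import statsmodels.formula.api as smf

        _, res, fit = moderated
        level = 8.0  # 8 years above the age center
        df = fit.data.copy()
        df["mod"] = df["mod"] - level
        rhs = fit.result.model.formula.split("~", 1)[1]
        refit = smf.ols(f"bmi ~ {rhs}", data=df).fit()
        slope, se, p = pk.simple_slope(fit, level)
        assert slope == pytest.approx(refit.params["pegs"], abs=1e-10)
        assert se == pytest.approx(refit.bse["pegs"], abs=1e-10)

    def test_slope_at_mean_matches_centered_model(self, moderated):
        _, _, fit = moderated
        # age modifier is centered at its mean, so level 0 is the sample mean
        slope, _, _ = pk.simple_slope(fit, 0.0)
        assert slope == pytest.approx(fit.result.params["pegs"], abs=1e-12)


class TestJohnsonNeyman:
    def test_boundaries_match_grid_oracle(self, moderated):
        _, res, fit = moderated
        lo, hi = res.table["age"].min(), res.table["age"].max()
        region = pk.johnson_neyman(fit, (lo, hi))
        # vectorized grid search over simple-slope p-values
        grid = np.linspace(lo, hi, 10_000)
        x = grid - fit.modifier_center
        slope = fit.beta_pegs + fit.beta_int * x
        var = fit.cov[0, 0] + 2 * x * fit.cov[0, 2] + x**2 * fit.cov[2, 2]
        pgrid = 2 * stats.t.sf(np.abs(slope / np.sqrt(var)), fit.df_resid)
        sig = pgrid < 0.05
        step = grid[1] - grid[0]
        for b in region.boundaries:
            if lo < b < hi:
                j = np.searchsorted(grid, b)
                assert sig[max(j - 2, 0)] != sig[min(j + 2, len(grid) - 1)]
        in_any = np.zeros_like(sig)
        for a, bnd in region.significant_intervals:
            in_any |= (grid >= a - step) & (grid <= bnd + step)
        # analytic region and grid classification agree up to grid resolution
        assert np.mean(sig ^ in_any) < 1e-3

    def test_no_moderation_significant_main(self, moderated):
        _, _, fit0 = moderated
        fit = pk.InteractionFit(
            trait="bmi", modifier="age_centered", n=fit0.n,
            beta_pegs=2.0, beta_mod=0.0, beta_int=0.0,
            cov=np.diag([0.01, 1.0, 0.0]), df_resid=1000.0,
            modifier_center=fit0.modifier_center,
        )
        region = pk.johnson_neyman(fit, (55.0, 95.0))
        assert region.significant_intervals == [(55.0, 95.0)]
        assert region.significant_side == "the entire observed range"

    def test_no_moderation_null_main(self, moderated):
        _, _, fit0 = moderated
        fit = pk.InteractionFit(
            trait="bmi", modifier="age_centered", n=fit0.n,
            beta_pegs=0.01, beta_mod=0.0, beta_int=0.0,
            cov=np.diag([1.0, 1.0, 0.0]), df_resid=1000.0,
            modifier_center=fit0.modifier_center,
        )
        region = pk.johnson_neyman(fit, (55.0, 95.0))
        assert region.significant_intervals == []

    def test_boundaries_move_outward_as_alpha_decreases(self, moderated):
        _, res, fit = moderated
        lo, hi = res.table["age"].min(), res.table["age"].max()
        r05 = pk.johnson_neyman(fit, (lo, hi), alpha=0.05)
        r01 = pk.johnson_neyman(fit, (lo, hi), alpha=0.01)
        len05 = sum(b - a for a, b in r05.significant_intervals)
        len01 = sum(b - a for a, b in r01.significant_intervals)
        assert len01 <= len05 + 1e-9


class TestPredictedValues:
    def test_slope_consistency_and_leverage(self, moderated):
        _, _, fit = moderated
        grid = np.linspace(-3, 3, 13)
        out = pk.predicted_values(fit, grid, [0.0])
        # difference of predictions at pegs 1 vs 0 equals the simple slope
        p0 = out.loc[np.isclose(out["pegs"], 0.0), "predicted"].iloc[0]
        p1 = out.loc[np.isclose(out["pegs"], 0.5), "predicted"].iloc[0]
        slope, _, _ = pk.simple_slope(fit, 0.0)
        assert (p1 - p0) / 0.5 == pytest.approx(slope, abs=1e-8)
        # CI width grows away from the data centroid
        width = out["upper"] - out["lower"]
        mid = len(grid) // 2
        assert width.iloc[0] > width.iloc[mid]
        assert width.iloc[-1] > width.iloc[mid]

    def test_two_levels_shapes(self, moderated):
        _, _, fit = moderated
        out = pk.predicted_values(fit, [-2, 0, 2], [-8.0, 8.0])
        assert len(out) == 6
        assert (out["lower"] <= out["predicted"]).all()
        assert (out["predicted"] <= out["upper"]).all()


class TestNullCalibration:
    def test_pvalues_uniform_under_null(self):
        """With no true interaction, p_int is U(0,1) across replicates."""
        pvals = []
        for seed in range(60):
            cfg = pk.GeneratorConfig(
                seed=1000 + seed, n_samples=250, n_cpgs_per_trait=4,
                traits=("bmi",), missing_rate=0.0,
            )
            study = pk.simulate_study(cfg)
            res = pk.run_pipeline(study)
            fit = pk.fit_interaction("bmi", "age_centered", res.pegs["bmi"],
                                     res.table)
            pvals.append(fit.p_int)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
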