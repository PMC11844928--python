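"""Synthetic-study generator: reproducibility, marginals, self-consistency."""

import numpy as np
import pandas as pd
import pytest

import pegskit as pk
from pegskit.simulate import generate_covariates, generate_ewas_catalog


class TestCovariates:
    def test_seed_reproducible(self):
        cfg = pk.GeneratorConfig(seed=3, n_samples=200)
        rng1, rng2 = np.random.default_rng(3), np.random.default_rng(3)
        a = generate_covariates(cfg, rng1)
        b = generate_covariates(cfg, rng2)
        pd.testing.assert_frame_equal(a, b)

    def test_marginals_near_configured(self):
        cfg = pk.GeneratorConfig(seed=5, n_samples=10_000)
        cov = generate_covariates(cfg, np.random.default_rng(5))
        assert (cov["sex"] == "female").mean() == pytest.approx(0.587, abs=0.02)
        # left truncation at 55 pulls the realized mean ~1.2 y above the location
        assert 69.5 < cov["age"].mean() < 71.5
        assert cov["age"].between(*cfg.age_range).all()
        assert (cov["race"] == "nh_white").mean() == pytest.approx(0.665, abs=0.02)
        assert (cov["drinks_per_week"] == 0).mean() == pytest.approx(0.608, abs=0.02)

    def test_point_mass_category(self):
        cfg = pk.GeneratorConfig(
            seed=1, n_samples=50,
            smoking_probs={"never": 1.0, "former": 0.0, "current": 0.0},
        )
        cov = generate_covariates(cfg, np.random.default_rng(1))
        assert (cov["smoking3"] == "never").all()

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            pk.GeneratorConfig(race_probs={"nh_white": 0.5, "nh_black": 0.4,
                                           "hispanic": 0.2, "other": 0.1})


class TestMethylation:
    def test_values_strictly_in_unit_interval(self, small_study):
        vals = small_study.methylation.values.to_numpy()
        finite = vals[~np.isnan(vals)]
        assert finite.min() > 0 and finite.max() < 1

    def test_missing_rate_zero_boundary(self):
        cfg = pk.GeneratorConfig(seed=2, n_samples=100, n_cpgs_per_trait=5,
                                 traits=("bmi",), missing_rate=0.0)
        study = pk.simulate_study(cfg)
        assert not study.methylation.values.isna().any().any()

    def test_missingness_near_rate(self, small_study):
        rate = small_study.methylation.values.isna().to_numpy().mean()
        assert rate == pytest.approx(small_study.config.missing_rate, abs=0.005)

    def test_no_batch_effect_roundtrip(self):
        """With zero batch/cell effects, residualization barely moves values."""
        cfg = pk.GeneratorConfig(seed=4, n_samples=2000, n_cpgs_per_trait=5,
                                 traits=("bmi",), missing_rate=0.0,
                                 batch_sd=0.0, cell_loading_sd=0.0)
        study = pk.simulate_study(cfg)
        adj = pk.residualize_cpgs(pk.impute_missing(study.methylation))
        # only the incidental finite-sample projection of noise onto the
        # design is removed: adjusted values track the originals tightly
        for cpg in study.methylation.cpg_ids:
            r = np.corrcoef(adj.values[cpg], study.methylation.values[cpg])[0, 1]
            assert r > 0.99


class TestCatalogs:
    def test_meth_independent_pass_through(self):
        cfg = pk.GeneratorConfig(seed=6, orientation_mix=0.0, traits=("bmi",))
        recs, true_w = generate_ewas_catalog(cfg, "bmi", np.random.default_rng(6))
        sig = [r for r in recs if r.bonferroni_significant and r.cpg_id in true_w]
        final = pk.finalize_weights(sig)
        for tw in final:
            assert tw.w == pytest.approx(true_w[tw.cpg_id])

    def test_meth_dependent_transformation_self_consistent(self):
        """Transforming the emitted statistics reproduces the generating weight."""
        cfg = pk.GeneratorConfig(seed=7, orientation_mix=1.0, traits=("bmi",))
        recs, true_w = generate_ewas_catalog(cfg, "bmi", np.random.default_rng(7))
        sig = [r for r in recs if r.bonferroni_significant and r.cpg_id in true_w]
        assert all(r.orientation == "meth_dependent" for r in sig)
        final = pk.finalize_weights(sig)
        rel = [abs(tw.w - true_w[tw.cpg_id]) / abs(true_w[tw.cpg_id])
               for tw in final]
        assert np.median(rel) < 0.02

    def test_catalog_files_byte_identical_across_runs(self, tmp_path):
        cfg = pk.GeneratorConfig(seed=8, n_samples=50, n_cpgs_per_trait=4,
                                 traits=("bmi",))
        p1 = pk.write_dataset(pk.simulate_study(cfg), tmp_path / "a")
        p2 = pk.write_dataset(pk.simulate_study(cfg), tmp_path / "b")
        assert p1["catalog_bmi"].read_bytes() == p2["catalog_bmi"].read_bytes()

    def test_selection_drops_off_array_and_nonsignificant(self, small_study):
        recs = small_study.catalogs["bmi"]
        available = set(small_study.methylation.cpg_ids)
        kept = pk.select_cpgs(recs, available)
        assert len(kept) == small_study.config.n_cpgs_per_trait
        assert all(r.bonferroni_significant for r in kept)


class TestPhenotypes:
    def test_noiseless_limit_exact_recovery(self):
        """With zero noise the generated trait is an exact function of the
        recorded truth: fitting against the true score recovers the slope
        to 4 decimals."""
        cfg = pk.GeneratorConfig(
            seed=9, n_samples=600, n_cpgs_per_trait=5, traits=("bmi",),
            noise_sd={"bmi": 0.0}, bp_reading_sd=0.0,
        )
        study = pk.simulate_study(cfg)
        table = pk.build_analysis_table(study.samples)
        z = study.truth.true_scores["bmi"].to_numpy()
        pegs = pk.PEGSVector("bmi", list(table.index), z, 5, z=z)
        fit = pk.fit_association(pk.ModelSpec("bmi"), pegs, table)
        assert fit.beta == pytest.approx(2.4, abs=1e-4)

    def test_missing_catalog_trait_errors(self):
        cfg = pk.GeneratorConfig(seed=10, n_samples=50, traits=("bmi",))
        study = pk.simulate_study(cfg)
        from pegskit.simulate import generate_phenotypes
        with pytest.raises(ValueError, match="catalog"):
            generate_phenotypes(cfg, study.covariates, study.clean_betas,
                                study.methylation, {}, np.random.default_rng(0))

    def test_bp_artifacts_exercised_and_censored(self):
        cfg = pk.GeneratorConfig(seed=15, n_samples=2000, n_cpgs_per_trait=4,
                                 traits=("sbp", "dbp"))
        raw = pk.simulate_study(cfg).samples
        assert (raw[["sbp1", "sbp2"]] > 250).to_numpy().any()
        table = pk.build_analysis_table(raw)
        assert table["sbp"].max() <= 250
        assert table["dbp"].min() >= 40

    def test_friedewald_exercised(self):
        cfg = pk.GeneratorConfig(seed=16, n_samples=2000, n_cpgs_per_trait=4,
                                 traits=("hdl", "ldl", "tg"))
        raw = pk.simulate_study(cfg).samples
        table = pk.build_analysis_table(raw)
        manual = raw["tc"] - raw["hdl"] - raw["tg"] / 5
        high_tg = raw["tg"] >= 400
        assert high_tg.any()  # the TG<400 rule is actually exercised
        assert table.loc[high_tg, "ldl"].isna().all()
        ok = ~high_tg & manual.notna()
        # winsorization may clip the extreme tail; check the bulk matches
        matches = np.isclose(table.loc[ok, "ldl"], manual[ok])
        assert matches.mean() > 0.99


class TestEndToEnd:
    def test_full_run_recovers_all_truth_within_3_se(self):
        cfg = pk.GeneratorConfig(
            seed=12, n_samples=2500, n_cpgs_per_trait=8,
            traits=("bmi", "crp", "tg"),
            interactions={("tg", "age_centered"): -0.005},
        )
        study = pk.simulate_study(cfg)
        res = pk.run_pipeline(study)
        for trait in cfg.traits:
            fit = pk.fit_association(pk.ModelSpec(trait), res.pegs[trait],
                                     res.table)
            assert abs(fit.beta - study.truth.beta_true[trait]) < 3 * fit.se
        ifit = pk.fit_interaction("tg", "age_centered", res.pegs["tg"],
                                  res.table)
        assert abs(ifit.beta_int - (-0.005)) < 3 * np.sqrt(ifit.cov[2, 2])

    def test_study_is_pure_function_of_config(self):
        cfg = pk.GeneratorConfig(seed=13, n_samples=120, n_cpgs_per_trait=4,
                                 traits=("hdl",))
        a, b = pk.simulate_study(cfg), pk.simulate_study(cfg)
        pd.testing.assert_frame_equal(a.samples, b.samples)
        pd.testing.assert_frame_equal(a.methylation.values, b.methylation.values)
        pd.testing.assert_frame_equal(a.truth.true_scores, b.truth.true_scores)

    def test_written_dataset_round_trips_through_manifest(self, tmp_path):
        cfg = pk.GeneratorConfig(seed=14, n_samples=150, n_cpgs_per_trait=5,
                                 traits=("bmi",))
        study = pk.simulate_study(cfg)
        paths = pk.write_dataset(study, tmp_path)
        loaded = pk.read_methylation(paths["beta_matrix"], paths["sample_meta"])
        pd.testing.assert_frame_equal(
            loaded.values, study.methylation.values, rtol=1e-12)
        pd.testing.assert_frame_equal(loaded.batch, study.methylation.batch)
        entries = pk.read_manifest(paths["manifest"])
        weights = pk.load_trait_weights(
            entries["bmi"], set(study.methylation.cpg_ids))
        assert len(weights) == 5
        final_direct = pk.finalize_weights(
            pk.select_cpgs(study.catalogs["bmi"],
                           set(study.methylation.cpg_ids)))
        for a, b in zip(weights, final_direct):
            assert a.w == pytest.approx(b.w, rel=1e-10)
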