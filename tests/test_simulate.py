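"""Synthetic-cohort generator: determinism, marginals, and truth ledger."""

import warnings

import numpy as np
import pandas as pd
import pytest

from mitoage import io
from mitoage.heteroplasmy import score_study
from mitoage.simulate import (
    ConfigError,
    SimConfig,
    generate_cohort,
    generate_mr_dataset,
    generate_mtdna,
    generate_traits,
    simulate_study,
    threshold_traits,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [("female_prop", 1.2), ("n_per_cohort", (0, 10, 10, 10)),
         ("wbc_concentration", (1.0, -2.0, 1.0, 1.0, 1.0)),
         ("mlc_missing", -0.1), ("n_batches", 0)],
    )
    def test_invalid_field_named_in_error(self, field, value):
        with pytest.raises(ConfigError, match=field.split("_")[0]):
            SimConfig(**{field: value})

    def test_unknown_field_rejected(self):
        with pytest.raises(ConfigError, match="bogus"):
            SimConfig.from_dict({"bogus": 1})

    def test_round_trip_dict(self):
        cfg = SimConfig(n_per_cohort=(50, 50, 50, 50))
        assert SimConfig.from_dict(cfg.to_dict()) == cfg


class TestDeterminism:
    def test_cohort_tables_identical(self):
        cfg = SimConfig(n_per_cohort=(100,) * 4)
        t1, _ = generate_cohort(cfg, seed=5)
        t2, _ = generate_cohort(cfg, seed=5)
        pd.testing.assert_frame_equal(t1, t2)

    def test_full_study_identical(self):
        cfg = SimConfig(n_per_cohort=(60,) * 4, seed=5)
        s1, s2 = simulate_study(cfg), simulate_study(cfg)
        pd.testing.assert_frame_equal(s1.mtdna.calls, s2.mtdna.calls)
        pd.testing.assert_frame_equal(s1.betas, s2.betas)
        pd.testing.assert_frame_equal(s1.traits, s2.traits)
        pd.testing.assert_frame_equal(s1.mr_exposure, s2.mr_exposure)

    def test_different_seeds_differ(self):
        cfg = SimConfig(n_per_cohort=(100,) * 4)
        t1, _ = generate_cohort(cfg, seed=5)
        t2, _ = generate_cohort(cfg, seed=6)
        assert not t1["age"].equals(t2["age"])


class TestCohortMarginals:
    def test_age_distribution_matches_config(self):
        cfg = SimConfig(n_cohorts=1, n_per_cohort=(2289,),
                        age_mean=(45.6,), age_sd=(6.3,))
        table, _ = generate_cohort(cfg, seed=2)
        se = 6.3 / np.sqrt(2289)
        assert abs(table["age"].mean() - 45.6) < 3 * se

    def test_female_proportion_in_binomial_interval(self):
        cfg = SimConfig(n_per_cohort=(1500,) * 4, female_prop=0.58)
        table, _ = generate_cohort(cfg, seed=2)
        n = len(table)
        obs = table["female"].mean()
        half_width = 2.576 * np.sqrt(0.58 * 0.42 / n)
        assert abs(obs - 0.58) < half_width

    def test_wbc_proportions_sum_to_one(self, small_study):
        wbc = small_study.cohort[[c for c in small_study.cohort if c.startswith("wbc_")]]
        np.testing.assert_allclose(wbc.sum(axis=1), 1.0, atol=1e-12)


class TestMtdnaGeneration:
    def test_rare_burden_rises_after_55(self):
        cfg = SimConfig(n_cohorts=1, n_per_cohort=(5000,),
                        age_mean=(60.0,), age_sd=(13.0,))
        cohort, ledger = generate_cohort(cfg, seed=3)
        generate_mtdna(cohort, cfg, seed=3, ledger=ledger)
        t = ledger.samples
        older = t.loc[t["age"] >= 60, "true_MHcount"].mean()
        younger = t.loc[t["age"] < 60, "true_MHcount"].mean()
        assert older > younger

    def test_cn_declines_from_peak(self):
        cfg = SimConfig(n_cohorts=1, n_per_cohort=(6000,),
                        age_mean=(55.0,), age_sd=(15.0,))
        cohort, ledger = generate_cohort(cfg, seed=3)
        generate_mtdna(cohort, cfg, seed=3, ledger=ledger)
        t = ledger.samples
        near_peak = t.loc[(t["age"] - cfg.cn_peak_age).abs() < 3, "true_mtDNA_CN"].mean()
        at_60 = t.loc[(t["age"] - 62.5).abs() < 3, "true_mtDNA_CN"].mean()
        assert at_60 < near_peak

    def test_vafs_within_unit_interval(self, small_study):
        vaf = small_study.mtdna.calls["vaf"]
        assert ((vaf > 0) & (vaf < 1)).all()

    def test_vcf_round_trip_reproduces_call_set(self, small_study, tmp_path):
        path = tmp_path / "calls.vcf"
        ids = small_study.cohort["sample_id"].tolist()
        io.write_vcf(small_study.mtdna.calls, path, sample_ids=ids)
        back = io.read_vcf(path)
        a = (small_study.mtdna.calls.sort_values(["sample_id", "position", "alt"])
             .reset_index(drop=True))
        b = back.sort_values(["sample_id", "position", "alt"]).reset_index(drop=True)
        assert len(a) == len(b)
        np.testing.assert_allclose(a["vaf"], b["vaf"], atol=1e-6)
        assert (a["depth"].to_numpy() == b["depth"].to_numpy()).all()
        assert (a["position"].to_numpy() == b["position"].to_numpy()).all()

    def test_scoring_pipeline_recovers_truth_exactly(self, small_study):
        ids = small_study.cohort["sample_id"].tolist()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = score_study(
                small_study.mtdna.calls, ids, mlc=small_study.mtdna.mlc,
                panel=small_study.mtdna.panel,
                site_coverage=small_study.mtdna.site_coverage,
            )
        sc = res.scores.set_index("sample_id")
        truth = small_study.ledger.samples
        assert (sc["MHcount"] == truth["true_MHcount"]).all()
        np.testing.assert_allclose(sc["MSS"], truth["true_MSS"], atol=1e-12)
        assert (sc["MH_com_count"] == truth["true_MH_com_count"]).all()


class TestClocksAndLedger:
    def test_emitted_year_clock_recovers_latent_age(self, small_study):
        from mitoage.clocks import compute_clock_value

        year = next(c for c in small_study.clocks if c.scale == "years")
        values = compute_clock_value(small_study.betas, year)
        ba = small_study.ledger.samples.loc[values.index, "true_BA"]
        assert np.corrcoef(values, ba)[0, 1] > 0.9

    def test_pace_clock_centered_at_one(self, small_study):
        from mitoage.clocks import compute_clock_value

        pace = next(c for c in small_study.clocks if c.scale == "pace")
        values = compute_clock_value(small_study.betas, pace)
        assert values.mean() == pytest.approx(1.0, abs=0.02)

    def test_betas_bounded(self, small_study):
        b = small_study.betas.to_numpy()
        assert (b >= 0).all() and (b <= 1).all()

    def test_ledger_covers_every_emitted_sample(self, small_study):
        ledger_ids = set(small_study.ledger.samples.index)
        for frame in (small_study.cohort, small_study.traits):
            assert set(frame["sample_id"]) <= ledger_ids
        assert set(small_study.mtdna.calls["sample_id"]) <= ledger_ids
        assert set(small_study.betas.index) <= ledger_ids

    def test_ledger_json_round_trip(self, small_study, tmp_path):
        p = tmp_path / "truth.json"
        small_study.ledger.to_json(p)
        from mitoage.simulate import TruthLedger

        back = TruthLedger.from_json(p)
        assert back.coefficients == small_study.ledger.coefficients
        assert len(back.samples) == len(small_study.ledger.samples)

    def test_null_config_yields_null_association(self):
        from mitoage.experiments import pooled_metric_association

        cfg = SimConfig(n_per_cohort=(300,) * 4, gamma_mss=0.0,
                        gamma_cn=0.0, theta_cn=0.0,
                        n_cpgs_year=40, n_cpgs_pace=10)
        meta = pooled_metric_association(cfg, seed=4)
        assert abs(meta.beta) < 3 * meta.se


class TestTraits:
    def test_threshold_rules(self):
        base = dict(glucose=100.0, diabetes_treatment=0, sbp=120.0, dbp=80.0,
                    bp_treatment=0, cholesterol=180.0, triglycerides=100.0,
                    lipid_treatment=0)
        df = pd.DataFrame([
            {**base, "bmi": 30.0},                       # inclusive obesity bound
            {**base, "bmi": 29.9},
            {**base, "bmi": 25.0, "glucose": 125.9},     # below T2DM bound
            {**base, "bmi": 25.0, "glucose": 126.0},
            {**base, "bmi": 25.0, "diabetes_treatment": 1},
        ])
        out = threshold_traits(df)
        assert out["obesity"].tolist() == [1, 0, 0, 0, 0]
        assert out["t2dm"].tolist() == [0, 0, 0, 1, 1]

    def test_stronger_theta_cn_strengthens_obesity_cn_association(self):
        def assoc(theta):
            cfg = SimConfig(n_cohorts=1, n_per_cohort=(6000,),
                            age_mean=(60.0,), age_sd=(10.0,), theta_cn=theta,
                            n_cpgs_year=10, n_cpgs_pace=10)
            cohort, ledger = generate_cohort(cfg, seed=8)
            generate_mtdna(cohort, cfg, seed=8, ledger=ledger)
            from mitoage.simulate import generate_methylation_clocks

            generate_methylation_clocks(cohort, ledger, cfg, seed=8)
            traits = generate_traits(cohort, ledger, cfg, seed=8)
            merged = traits.set_index("sample_id").join(ledger.samples)
            return np.corrcoef(merged["obesity"], merged["true_CN_std"])[0, 1]

        assert abs(assoc(-0.1)) > abs(assoc(-0.005))


class TestMRGeneration:
    def test_noiseless_wald_ratios_equal_theta(self):
        cfg = SimConfig(mr_theta=0.5, mr_noise_sd=0.0)
        exp, out, truth = generate_mr_dataset(cfg, seed=3)
        np.testing.assert_allclose(out["beta"] / exp["beta"], 0.5, atol=1e-12)
        assert truth["theta"] == 0.5

    def test_reproducible_given_seed(self):
        cfg = SimConfig()
        e1, o1, _ = generate_mr_dataset(cfg, seed=3)
        e2, o2, _ = generate_mr_dataset(cfg, seed=3)
        pd.testing.assert_frame_equal(e1, e2)
        pd.testing.assert_frame_equal(o1, o2)

    def test_snp_count_floor(self):
        with pytest.raises(ConfigError, match="mr_n_snps"):
            SimConfig(mr_n_snps=1)
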