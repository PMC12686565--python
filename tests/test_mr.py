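"""Two-sample MR: harmonization, IVW, Egger, weighted median, LOO."""

import numpy as np
import pandas as pd
import pytest

from mitoage.mr import (
    harmonize,
    leave_one_out,
    mr_egger,
    mr_ivw,
    mr_weighted_median,
    weighted_median_point,
)


def _side(snps, ea, oa, eaf, beta, se=0.01):
    k = len(snps)
    return pd.DataFrame({
        "snp": snps, "ea": ea, "oa": oa, "eaf": eaf,
        "beta": beta, "se": [se] * k, "p": [1e-9] * k,
    })


def _harmonized(beta_exp, beta_out, se_out=0.01, se_exp=0.005):
    k = len(beta_exp)
    return pd.DataFrame({
        "snp": [f"rs{i}" for i in range(k)],
        "beta_exp": beta_exp, "se_exp": [se_exp] * k,
        "beta_out": beta_out, "se_out": [se_out] * k,
    })


class TestHarmonize:
    def test_identical_orientation_unchanged(self):
        exp = _side(["rs1"], ["A"], ["G"], [0.3], [0.1])
        out = _side(["rs1"], ["A"], ["G"], [0.3], [0.05])
        h, audit = harmonize(exp, out)
        assert h.loc[0, "beta_out"] == pytest.approx(0.05)
        assert audit.empty

    def test_swapped_alleles_flip_sign(self):
        exp = _side(["rs1"], ["A"], ["G"], [0.3], [0.1])
        out = _side(["rs1"], ["G"], ["A"], [0.7], [0.05])
        h, _ = harmonize(exp, out)
        assert h.loc[0, "beta_out"] == pytest.approx(-0.05)
        assert h.loc[0, "eaf_out"] == pytest.approx(0.3)

    def test_palindromic_near_half_dropped(self):
        exp = _side(["rs1"], ["A"], ["T"], [0.50], [0.1])
        out = _side(["rs1"], ["A"], ["T"], [0.50], [0.05])
        h, audit = harmonize(exp, out)
        assert h.empty
        assert audit.loc[0, "reason"] == "palindromic_ambiguous"

    def test_palindromic_outside_window_kept(self):
        exp = _side(["rs1"], ["A"], ["T"], [0.20], [0.1])
        out = _side(["rs1"], ["A"], ["T"], [0.20], [0.05])
        h, _ = harmonize(exp, out)
        assert len(h) == 1

    def test_allele_mismatch_dropped(self):
        exp = _side(["rs1"], ["A"], ["G"], [0.3], [0.1])
        out = _side(["rs1"], ["A"], ["C"], [0.3], [0.05])
        h, audit = harmonize(exp, out)
        assert h.empty and audit.loc[0, "reason"] == "allele_mismatch"

    def test_no_overlap_raises(self):
        exp = _side(["rs1"], ["A"], ["G"], [0.3], [0.1])
        out = _side(["rs2"], ["A"], ["G"], [0.3], [0.05])
        with pytest.raises(ValueError, match="overlap"):
            harmonize(exp, out)


class TestIVW:
    def test_noiseless_consistency(self, rng):
        bx = rng.uniform(0.02, 0.1, 10)
        h = _harmonized(bx, 0.5 * bx)
        est = mr_ivw(h)
        assert est.theta == pytest.approx(0.5, abs=1e-12)
        np.testing.assert_allclose(est.wald_ratios, 0.5, atol=1e-12)

    def test_single_snp_is_wald_ratio(self):
        h = _harmonized([0.04], [0.02])
        assert mr_ivw(h).theta == pytest.approx(0.5)

    def test_zero_exposure_beta_excluded_with_warning(self):
        h = _harmonized([0.04, 0.0], [0.02, 0.5])
        with pytest.warns(UserWarning, match="zero exposure"):
            est = mr_ivw(h)
        assert est.n_snps == 1

    def test_invariance_to_order_and_joint_sign_flip(self, rng):
        bx = rng.uniform(0.02, 0.1, 8)
        by = 0.3 * bx + rng.normal(0, 0.01, 8)
        h = _harmonized(bx, by)
        t0 = mr_ivw(h).theta
        shuffled = h.sample(frac=1, random_state=3).reset_index(drop=True)
        assert mr_ivw(shuffled).theta == pytest.approx(t0, abs=1e-12)
        flipped = h.copy()
        flipped.loc[0, ["beta_exp", "beta_out"]] *= -1
        assert mr_ivw(flipped).theta == pytest.approx(t0, abs=1e-12)

    def test_multiplicative_se_never_below_fixed(self, rng):
        bx = rng.uniform(0.02, 0.1, 15)
        by = 0.3 * bx + rng.normal(0, 0.05, 15)
        h = _harmonized(bx, by)
        assert mr_ivw(h, "multiplicative").se >= mr_ivw(h, "fixed").se - 1e-15


class TestEgger:
    def test_noiseless_line_recovered(self, rng):
        bx = rng.uniform(0.02, 0.1, 10)
        est = mr_egger(_harmonized(bx, 0.4 * bx))
        assert est.intercept == pytest.approx(0.0, abs=1e-12)
        assert est.theta == pytest.approx(0.4, abs=1e-12)

    def test_constant_offset_appears_in_intercept(self, rng):
        bx = rng.uniform(0.02, 0.1, 60)
        est = mr_egger(_harmonized(bx, 0.4 * bx + 0.05))
        assert est.intercept == pytest.approx(0.05, abs=1e-10)
        assert est.theta == pytest.approx(0.4, abs=1e-8)

    def test_too_few_snps(self):
        with pytest.raises(ValueError, match="3"):
            mr_egger(_harmonized([0.02, 0.03], [0.01, 0.02]))

    def test_three_snps_warns_on_unstable_df(self, rng):
        bx = [0.02, 0.05, 0.08]
        by = [0.011, 0.024, 0.041]
        with pytest.warns(UserWarning, match="residual df"):
            mr_egger(_harmonized(bx, by))


class TestWeightedMedian:
    def test_equal_weight_simple_median(self):
        assert weighted_median_point(np.array([0.4, 0.5, 0.6]),
                                     np.ones(3)) == pytest.approx(0.5)

    def test_equal_weights_match_sample_median(self, rng):
        ratios = rng.normal(0.3, 0.1, 21)
        wm = weighted_median_point(ratios, np.ones(21))
        assert wm == pytest.approx(np.median(ratios), abs=1e-9)

    def test_concentrated_weight_converges_to_that_ratio(self):
        ratios = np.array([0.1, 0.9, 0.5])
        w = np.array([1e-9, 1e-9, 1e6])
        assert weighted_median_point(ratios, w) == pytest.approx(0.5, abs=1e-3)

    def test_estimator_and_seeded_bootstrap(self, rng):
        bx = rng.uniform(0.02, 0.1, 20)
        by = 0.3 * bx + rng.normal(0, 0.005, 20)
        h = _harmonized(bx, by)
        e1 = mr_weighted_median(h, bootstrap_reps=200, seed=5)
        e2 = mr_weighted_median(h, bootstrap_reps=200, seed=5)
        assert e1.theta == pytest.approx(0.3, abs=0.05)
        assert e1.se == e2.se  # seeded bootstrap is reproducible

    def test_too_few_snps(self):
        with pytest.raises(ValueError, match="3"):
            mr_weighted_median(_harmonized([0.02, 0.03], [0.01, 0.02]))


class TestLeaveOneOut:
    def test_cardinality(self, rng):
        bx = rng.uniform(0.02, 0.1, 7)
        h = _harmonized(bx, 0.3 * bx + rng.normal(0, 0.005, 7))
        assert len(leave_one_out(h)) == 7

    def test_two_snps_each_estimate_is_other_ratio(self):
        h = _harmonized([0.04, 0.05], [0.02, 0.03])
        loo = leave_one_out(h).set_index("snp")
        assert loo.loc["rs0", "theta"] == pytest.approx(0.03 / 0.05, abs=1e-12)
        assert loo.loc["rs1", "theta"] == pytest.approx(0.02 / 0.04, abs=1e-12)

    def test_homogeneous_instruments_not_influential(self, rng):
        bx = rng.uniform(0.02, 0.1, 30)
        h = _harmonized(bx, 0.3 * bx + rng.normal(0, 0.003, 30))
        full = mr_ivw(h)
        loo = leave_one_out(h)
        assert (np.abs(loo["theta"] - full.theta) <= full.se + 1e-12).all()

    def test_single_snp_rejected(self):
        with pytest.raises(ValueError, match="2"):
            leave_one_out(_harmonized([0.04], [0.02]))
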