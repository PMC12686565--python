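"""Burden scoring: site mask, VAF window, rarity, and score assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoage.heteroplasmy import (
    DEFAULT_VAF_WINDOW,
    MT_GENOME_LENGTH,
    MaskError,
    SiteMask,
    build_site_mask,
    classify_heteroplasmic,
    classify_rarity,
    compute_burden_scores,
)

from conftest import make_calls


class TestSiteMask:
    def test_default_blacklist_counts(self):
        mask = build_site_mask()
        assert mask.n_excluded == 550
        assert mask.n_retained == 16_019

    @pytest.mark.parametrize("pos", [1, 61, 301, 302, 310, 316, 499, 567, 3107, 16088, 16569])
    def test_listed_positions_excluded(self, pos):
        assert not build_site_mask().is_retained(pos)

    @pytest.mark.parametrize("pos", [62, 300, 303, 3106, 3108, 16087])
    def test_neighbours_retained(self, pos):
        assert build_site_mask().is_retained(pos)

    def test_empty_blacklist_is_identity(self):
        mask = build_site_mask(blacklist_ranges=[])
        assert mask.n_retained == MT_GENOME_LENGTH

    def test_out_of_range_rejected(self):
        with pytest.raises(MaskError):
            build_site_mask(blacklist_ranges=[(16560, 16570)])
        with pytest.raises(MaskError):
            build_site_mask(blacklist_ranges=[(0, 5)])


class TestVafWindow:
    @pytest.mark.parametrize(
        "vaf,expected",
        [(0.50, True), (0.04, False), (0.95, True), (0.05, True),
         (0.049, False), (0.951, False), (0.0, False), (1.0, False)],
    )
    def test_inclusive_window(self, vaf, expected):
        assert classify_heteroplasmic(vaf) is expected

    def test_vectorized(self):
        out = classify_heteroplasmic(np.array([0.5, 0.96, 0.05]))
        assert out.tolist() == [True, False, True]


class TestRarity:
    def _calls_with_carriers(self, n_carriers, pos=100, alt="T"):
        rows = [(f"s{i}", pos, "A", alt, 0.2, 500) for i in range(n_carriers)]
        return make_calls(rows)

    @pytest.mark.parametrize(
        "carriers,total,expected_rare",
        [(5, 1000, True),     # 0.5% < 1%
         (30, 1000, False),   # 3%
         (10, 1000, False)],  # exactly 1%: strictly-below rule
    )
    def test_threshold(self, carriers, total, expected_rare):
        rarity = classify_rarity(self._calls_with_carriers(carriers), total)
        assert rarity.loc[(100, "T"), "rare"] == expected_rare

    def test_carrier_counting_ignores_out_of_window(self):
        calls = pd.concat([
            self._calls_with_carriers(5),
            make_calls([("hom", 100, "A", "T", 0.99, 500)]),  # homoplasmic-like
        ])
        rarity = classify_rarity(calls, 1000)
        assert rarity.loc[(100, "T"), "carriers"] == 5

    def test_zero_participants_error(self):
        with pytest.raises(ValueError):
            classify_rarity(self._calls_with_carriers(1), 0)


def brute_force_scores(calls, excluded, min_cov, rarity, mlc, panel, site_cov, samples):
    """Independent triple-loop oracle over (sample, site, allele)."""
    out = {}
    seen = set()
    for s in samples:
        mh, mss, com = 0, 0.0, 0
        for row in calls.itertuples(index=False):
            if row.sample_id != s:
                continue
            key = (row.sample_id, row.position, row.ref, row.alt, row.vaf, row.depth)
            if key in seen:
                continue
            if not (0.05 <= row.vaf <= 0.95):
                continue
            if row.position in excluded:
                continue
            if site_cov.get((row.sample_id, row.position), min_cov) < min_cov:
                continue
            if (row.position, row.ref, row.alt) in panel:
                com += 1
            if rarity.get((row.position, row.alt), True):
                mh += 1
                mss += mlc.get((row.position, row.alt), 0.0)
        out[s] = (mh, mss, com)
    # mark duplicates after full pass (dedup is global, not per sample)
    return out


class TestBurdenScores:
    def test_direct_summation(self):
        mask = build_site_mask()
        calls = make_calls([("s1", 1000, "A", "G", 0.3, 500),
                            ("s1", 2000, "C", "T", 0.6, 500)])
        mlc = pd.DataFrame({"position": [1000, 2000], "alt": ["G", "T"], "mlc": [0.9, 0.3]})
        rarity = classify_rarity(calls, 1000)
        scores, audit = compute_burden_scores(calls, mask, rarity, mlc=mlc, sample_ids=["s1"])
        row = scores.set_index("sample_id").loc["s1"]
        assert row["MHcount"] == 2
        assert row["MSS"] == pytest.approx(1.2)
        assert audit.empty

    def test_no_calls_gives_zero_scores(self):
        mask = build_site_mask()
        scores, _ = compute_burden_scores(
            make_calls([]), mask, pd.DataFrame(columns=["rare"]), sample_ids=["s1", "s2"]
        )
        assert (scores[["MHcount", "MSS", "MH_com_count"]].to_numpy() == 0).all()

    def test_masked_site_and_missing_mlc(self):
        mask = build_site_mask()
        calls = make_calls([("s1", 301, "A", "G", 0.3, 500),   # masked homopolymer site
                            ("s1", 5000, "C", "T", 0.6, 500)])  # retained, no MLC entry
        rarity = classify_rarity(calls, 1000)
        with pytest.warns(UserWarning, match="MLC"):
            scores, audit = compute_burden_scores(
                calls, mask, rarity, mlc=pd.DataFrame(columns=["position", "alt", "mlc"]),
                sample_ids=["s1"],
            )
        row = scores.set_index("sample_id").loc["s1"]
        assert row["MHcount"] == 1
        assert row["MSS"] == 0.0
        assert audit["reason"].tolist() == ["masked_site"]

    def test_unknown_sample_raises(self):
        calls = make_calls([("ghost", 1000, "A", "G", 0.3, 500)])
        with pytest.raises(KeyError, match="ghost"):
            compute_burden_scores(calls, build_site_mask(),
                                  pd.DataFrame(columns=["rare"]), sample_ids=["s1"])

    def test_matches_brute_force_oracle(self, rng):
        samples = [f"s{i}" for i in range(20)]
        n_calls = 50
        positions = rng.integers(1, MT_GENOME_LENGTH + 1, n_calls)
        calls = make_calls([
            (samples[rng.integers(20)], int(p), "A", rng.choice(["C", "G", "T"]),
             float(rng.uniform(0, 1)), int(rng.integers(100, 3000)))
            for p in positions
        ])
        mask = build_site_mask()
        rarity = classify_rarity(calls, len(samples))
        mlc = pd.DataFrame({
            "position": positions[:30], "alt": calls["alt"][:30],
            "mlc": rng.uniform(0, 1, 30),
        }).drop_duplicates(["position", "alt"])
        panel = calls[["position", "ref", "alt"]].iloc[40:45].drop_duplicates()
        site_cov = pd.DataFrame({
            "sample_id": calls["sample_id"][:10],
            "position": calls["position"][:10],
            "coverage": rng.uniform(100, 400, 10),
        }).drop_duplicates(["sample_id", "position"])

        scores, _ = compute_burden_scores(
            calls, mask, rarity, mlc=mlc, panel=panel,
            site_coverage=site_cov, sample_ids=samples,
        )
        oracle = brute_force_scores(
            calls.drop_duplicates(), set(mask.excluded), mask.min_coverage,
            rarity["rare"].to_dict(),
            mlc.set_index(["position", "alt"])["mlc"].to_dict(),
            set(map(tuple, panel.to_numpy())),
            {(r.sample_id, r.position): r.coverage for r in site_cov.itertuples()},
            samples,
        )
        for s in samples:
            row = scores.set_index("sample_id").loc[s]
            mh, mss, com = oracle[s]
            assert row["MHcount"] == mh
            assert row["MSS"] == pytest.approx(mss, abs=1e-12)
            assert row["MH_com_count"] == com


class TestScoreInvariants:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.randoms(use_true_random=False))
    def test_order_and_duplication_invariance(self, rnd):
        base = make_calls([
            ("s1", 1000, "A", "G", 0.3, 500),
            ("s2", 2000, "C", "T", 0.6, 500),
            ("s1", 3000, "G", "A", 0.5, 500),
        ])
        rarity = classify_rarity(base, 10)
        mask = build_site_mask()
        ref_scores, _ = compute_burden_scores(base, mask, rarity, sample_ids=["s1", "s2"])
        rows = base.to_dict("records") + [base.to_dict("records")[0]]  # duplicate one
        rnd.shuffle(rows)
        shuffled = pd.DataFrame(rows)
        got, _ = compute_burden_scores(shuffled, mask, rarity, sample_ids=["s1", "s2"])
        pd.testing.assert_frame_equal(
            ref_scores.sort_values("sample_id").reset_index(drop=True),
            got.sort_values("sample_id").reset_index(drop=True),
        )

    def test_raising_min_coverage_is_monotone(self, rng):
        samples = [f"s{i}" for i in range(5)]
        calls = make_calls([
            (samples[rng.integers(5)], int(rng.integers(600, 16000)), "A", "G",
             float(rng.uniform(0.05, 0.95)), 1000)
            for _ in range(40)
        ])
        site_cov = pd.DataFrame({
            "sample_id": calls["sample_id"], "position": calls["position"],
            "coverage": rng.uniform(100, 600, len(calls)),
        }).drop_duplicates(["sample_id", "position"])
        rarity = classify_rarity(calls, 5)
        prev = None
        for min_cov in (100, 250, 400, 700):
            mask = SiteMask(excluded=frozenset(), min_coverage=min_cov)
            scores, _ = compute_burden_scores(
                calls, mask, rarity, site_coverage=site_cov, sample_ids=samples
            )
            tot = scores[["MHcount", "MSS", "MH_com_count"]].sum()
            if prev is not None:
                assert (tot <= prev + 1e-12).all()
            prev = tot

    def test_mss_never_exceeds_mhcount(self, small_study):
        import warnings

        from mitoage.heteroplasmy import score_study

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = score_study(
                small_study.mtdna.calls, small_study.cohort["sample_id"].tolist(),
                mlc=small_study.mtdna.mlc, panel=small_study.mtdna.panel,
                site_coverage=small_study.mtdna.site_coverage,
            )
        assert (res.scores["MSS"] <= res.scores["MHcount"] + 1e-12).all()
        assert (res.scores[["MHcount", "MSS", "MH_com_count"]] >= 0).all().all()
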