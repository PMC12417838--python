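"""Nonparametric statistics: rank-test oracles, multiplicity adjustment,
null calibration and infiltration stratification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ecogpipe import (dunn_posthoc, infiltration_stratum, kruskal_wallis,
                      mann_whitney, spearman_corr, stratify_and_correlate)

TOY_VALUES = [1, 2, 3, 4, 5, 6, 7, 8, 9]
TOY_LABELS = ["a"] * 3 + ["b"] * 3 + ["c"] * 3


class TestKruskalWallis:
    def test_hand_computed_h_on_toy_partition(self):
        # H = 12/(N(N+1)) * sum(R_j^2/n_j) - 3(N+1) = 7.2 for {1,2,3}/{4,5,6}/{7,8,9}
        h, p = kruskal_wallis(TOY_VALUES, TOY_LABELS)
        assert h == pytest.approx(7.2, abs=1e-9)
        assert 0 < p < 0.05

    def test_identical_values_defined_as_null(self):
        h, p = kruskal_wallis([5.0] * 9, TOY_LABELS)
        assert h == 0.0 and p == 1.0

    def test_two_identical_groups_h_zero(self):
        h, _ = kruskal_wallis([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1, 2, 3], ["a", "a", "a"])

    def test_null_type_one_error_calibrated(self, rng):
        # empirical size at alpha = .05 over 2000 null simulations, 30/group
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            vals = rng.standard_normal(90)
            _, p = kruskal_wallis(vals, ["a"] * 30 + ["b"] * 30 + ["c"] * 30)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07


class TestDunnPosthoc:
    def test_extreme_pair_has_largest_z(self):
        table = dunn_posthoc(TOY_VALUES, TOY_LABELS)
        zmax = table.loc[table["z"].abs().idxmax()]
        assert {zmax["group_a"], zmax["group_b"]} == {"a", "c"}

    def test_z_matches_direct_mean_rank_computation(self):
        # oracle: mean ranks 2, 5, 8; sigma = sqrt((N(N+1)/12)(1/3+1/3))
        table = dunn_posthoc(TOY_VALUES, TOY_LABELS, adjust="none")
        se = np.sqrt((9 * 10 / 12) * (2 / 3))
        row_ac = table[(table.group_a == "a") & (table.group_b == "c")].iloc[0]
        assert row_ac["z"] == pytest.approx((2 - 8) / se, abs=1e-12)
        row_ab = table[(table.group_a == "a") & (table.group_b == "b")].iloc[0]
        assert row_ab["z"] == pytest.approx((2 - 5) / se, abs=1e-12)

    def test_identical_groups_all_adjusted_p_one(self):
        table = dunn_posthoc([1, 2, 3] * 3, TOY_LABELS)
        np.testing.assert_allclose(table["p_adj"], 1.0)

    def test_adjusted_p_never_below_raw(self, rng):
        vals = rng.standard_normal(60)
        labels = ["a"] * 20 + ["b"] * 20 + ["c"] * 20
        for method in ("holm", "bonferroni"):
            table = dunn_posthoc(vals, labels, adjust=method)
            assert (table["p_adj"] >= table["p_raw"] - 1e-15).all()

    def test_result_independent_of_input_ordering(self, rng):
        vals = rng.standard_normal(45)
        labels = np.array(["a"] * 15 + ["b"] * 15 + ["c"] * 15)
        perm = rng.permutation(45)
        t1 = dunn_posthoc(vals, labels)
        t2 = dunn_posthoc(vals[perm], labels[perm])
        pd.testing.assert_frame_equal(t1, t2)

    def test_four_groups_give_six_pairs(self, rng):
        vals = rng.standard_normal(40)
        labels = ["a", "b", "c", "d"] * 10
        assert len(dunn_posthoc(vals, labels)) == 6


class TestMannWhitney:
    def test_exact_two_sided_p_on_disjoint_triplets(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u in (0.0, 9.0)
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples_p_near_one(self):
        _, p = mann_whitney([1.0, 2.0, 5.0, 9.0], [1.0, 2.0, 5.0, 9.0])
        assert p > 0.9

    def test_growing_shift_drives_p_down(self, rng):
        a = rng.standard_normal(40)
        ps = []
        for shift in (0.0, 0.8, 2.0):
            b = rng.standard_normal(40) + shift
            ps.append(mann_whitney(a, b)[1])
        assert ps[0] > ps[1] > ps[2]

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestSpearman:
    def test_textbook_value_on_four_points(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with sum(d^2) = 2 -> 0.8
        rho, _ = spearman_corr([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.8, abs=1e-12)

    def test_strictly_monotone_extremes(self):
        x = [1.0, 2.5, 3.0, 7.0, 11.0]
        assert spearman_corr(x, np.exp(x))[0] == pytest.approx(1.0)
        assert spearman_corr(x, [-v for v in x])[0] == pytest.approx(-1.0)

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(1.0, 1e6), min_size=5, max_size=30,
                    unique=True))
    def test_invariant_under_monotone_transform(self, xs):
        rng = np.random.default_rng(abs(hash(tuple(xs))) % 2**31)
        ys = rng.standard_normal(len(xs))
        rho1, _ = spearman_corr(xs, ys)
        rho2, _ = spearman_corr(np.log(xs), ys)  # strictly monotone map
        assert rho1 == pytest.approx(rho2, abs=1e-9)

    def test_degenerate_input_reported_missing(self):
        with pytest.warns(UserWarning):
            rho, p = spearman_corr([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
        assert np.isnan(rho) and np.isnan(p)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            spearman_corr([1, 2, 3], [1, 2, 3])


class TestInfiltration:
    @pytest.mark.parametrize("count,stratum", [
        (0, "healthy"), (1, "low"), (30, "low"), (49, "low"),
        (50, "high"), (120, "high"),
    ])
    def test_stratum_boundaries(self, count, stratum):
        assert infiltration_stratum(count) == stratum

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            infiltration_stratum(-1)

    def test_stratified_correlation_recovers_construction(self, rng):
        n = 40
        feature = rng.uniform(0, 1, n)
        # low stratum counts anti-monotone in the feature, plus noise
        counts = np.clip((45 - 40 * feature + rng.normal(0, 2, n)).astype(int), 1, 49)
        biopsies = pd.DataFrame({
            "channel_id": [f"c{i}" for i in range(n)], "count": counts})
        features = pd.DataFrame({
            "channel_id": [f"c{i}" for i in range(n)], "f": feature})
        res = stratify_and_correlate(biopsies, features, features=["f"])
        row = res[(res.stratum == "low") & (res.feature == "f")].iloc[0]
        assert row["rho"] < -0.8
        assert row["n"] == n

    def test_small_stratum_reported_missing(self):
        biopsies = pd.DataFrame({"channel_id": ["a", "b", "c"],
                                 "count": [0, 0, 60]})
        features = pd.DataFrame({"channel_id": ["a", "b", "c"],
                                 "f": [1.0, 2.0, 3.0]})
        res = stratify_and_correlate(biopsies, features, features=["f"])
        assert res["rho"].isna().all()
        assert set(res["stratum"]) == {"healthy", "high"}
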