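import numpy as np
import pandas as pd
import pytest

from hubdisrupt import (bootstrap_robustness, compare_kappa_across_costs,
                        nodal_group_difference, significance_stars,
                        wilcoxon_rank_sum)


class TestWilcoxonRankSum:
    def test_exact_small_sample_enumeration(self):
        z, p = wilcoxon_rank_sum([1.0, 2.0], [3.0, 4.0])
        assert p == pytest.approx(1 / 3)
        assert z < 0

    def test_swapping_groups_flips_z(self, rng):
        x = rng.standard_normal(15)
        y = rng.standard_normal(15) + 1
        z1, p1 = wilcoxon_rank_sum(x, y)
        z2, p2 = wilcoxon_rank_sum(y, x)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_large_shift_highly_significant(self, rng):
        x = rng.standard_normal(20)
        y = rng.standard_normal(20) + 2.0
        _, p = wilcoxon_rank_sum(x, y)
        assert p < 0.001

    def test_all_tied_gives_p_one(self):
        z, p = wilcoxon_rank_sum([1.0, 1.0], [1.0, 1.0, 1.0])
        assert (z, p) == (0.0, 1.0)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_stars(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.009) == "**"
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.2) == ""


def _kappa_frame(values, metric="D", cost=0.2):
    return pd.DataFrame({
        "metric": metric, "cost": cost, "kappa": values,
    })


class TestCompareAcrossCosts:
    def test_single_cell_equals_direct_call(self, rng):
        c = rng.standard_normal(12)
        p = rng.standard_normal(12) - 0.8
        table = compare_kappa_across_costs(
            _kappa_frame(c), _kappa_frame(p), ["D"], [0.2]
        ).table
        z, pv = wilcoxon_rank_sum(p, c)
        assert table["z"].iloc[0] == pytest.approx(z)
        assert table["p"].iloc[0] == pytest.approx(pv)

    def test_missing_cost_raises(self, rng):
        c = _kappa_frame(rng.standard_normal(5))
        p = _kappa_frame(rng.standard_normal(5))
        with pytest.raises(ValueError, match="missing"):
            compare_kappa_across_costs(c, p, ["D"], [0.3])

    def test_null_rejection_near_nominal(self):
        """Exchangeable groups reject at about the 5% level."""
        hits = total = 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            c = _kappa_frame(rng.standard_normal(20))
            p = _kappa_frame(rng.standard_normal(20))
            t = compare_kappa_across_costs(c, p, ["D"], [0.2]).table
            hits += int(t["p"].iloc[0] < 0.05)
            total += 1
        assert hits / total < 0.15


class TestNodalDifference:
    def test_threshold_is_one_over_n(self, rng):
        ctrl = rng.standard_normal((6, 44))
        pat = rng.standard_normal((6, 44))
        m = nodal_group_difference(ctrl, pat)
        assert m.threshold == pytest.approx(1 / 44)
        assert round(m.threshold, 3) == 0.023

    def test_identical_groups_flag_nothing(self, rng):
        vals = rng.standard_normal((8, 10))
        m = nodal_group_difference(vals, vals.copy())
        assert not m.significant.any()

    def test_shifted_node_detected(self):
        """A 5-SD shift at one node is flagged in >=95% of replicates;
        false flags elsewhere stay at the nominal per-node rate."""
        hits = 0
        extra = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            ctrl = rng.standard_normal((20, 44))
            pat = rng.standard_normal((20, 44))
            pat[:, 7] += 5.0
            m = nodal_group_difference(ctrl, pat)
            hits += int(m.significant[7])
            extra.append(m.significant.sum() - int(m.significant[7]))
        assert hits >= 38
        assert np.mean(extra) < 2.5  # ~1 expected false flag per replicate

    def test_frame_export(self, rng):
        m = nodal_group_difference(rng.standard_normal((5, 6)),
                                   rng.standard_normal((5, 6)),
                                   node_ids=[10, 11, 12, 13, 14, 15])
        df = m.to_frame()
        assert list(df.columns) == ["node_id", "mean_diff", "p", "significant"]
        assert list(df["node_id"]) == [10, 11, 12, 13, 14, 15]


def _healthy_profiles(n_subjects, n_nodes, rng):
    base = np.linspace(2, 20, n_nodes)
    left = base + rng.normal(0, 1.0, size=(n_subjects, n_nodes))
    right = base + rng.normal(0, 1.0, size=(n_subjects, n_nodes))
    return left, right


class TestBootstrapRobustness:
    def test_null_distribution_centered(self):
        rng = np.random.default_rng(0)
        left, right = _healthy_profiles(60, 30, rng)
        res = bootstrap_robustness(left, right, n_iter=1000, design="pooled",
                                   n_ref=20, n_test_left=9, n_test_right=11,
                                   seed=1)
        assert abs(res.null_z.mean()) < 0.1

    def test_median_observed_z_gives_half(self):
        rng = np.random.default_rng(2)
        left, right = _healthy_profiles(50, 25, rng)
        res = bootstrap_robustness(left, right, n_iter=400, design="pooled",
                                   n_ref=15, n_test_left=5, n_test_right=6,
                                   seed=3)
        obs = float(np.median(res.null_z))
        res2 = bootstrap_robustness(left, right, n_iter=400, design="pooled",
                                    n_ref=15, n_test_left=5, n_test_right=6,
                                    observed_z=obs, seed=3)
        assert res2.p_raw == pytest.approx(0.5, abs=0.05)

    def test_extreme_observed_z_counting_bound(self):
        rng = np.random.default_rng(4)
        left, right = _healthy_profiles(40, 20, rng)
        res = bootstrap_robustness(left, right, n_iter=100, design="pooled",
                                   n_ref=10, n_test_left=4, n_test_right=4,
                                   observed_z=-50.0, seed=5)
        assert res.p_raw == 0.0
        assert res.p_plus_one == pytest.approx(1 / 101)

    def test_seeded_runs_identical(self):
        rng = np.random.default_rng(6)
        left, right = _healthy_profiles(40, 20, rng)
        kw = dict(n_iter=50, design="pooled", n_ref=10, n_test_left=4,
                  n_test_right=4, seed=7)
        a = bootstrap_robustness(left, right, **kw)
        b = bootstrap_robustness(left, right, **kw)
        np.testing.assert_array_equal(a.null_z, b.null_z)

    def test_per_side_design(self):
        rng = np.random.default_rng(8)
        left, right = _healthy_profiles(40, 20, rng)
        res = bootstrap_robustness(left, right, n_iter=50, design="per-side",
                                   side="right", n_ref=10, n_test_right=6,
                                   seed=9)
        assert res.design == "per-side:right"
        assert abs(res.null_z.mean()) < 0.5

    def test_insufficient_cohort_raises(self):
        rng = np.random.default_rng(10)
        left, right = _healthy_profiles(10, 15, rng)
        with pytest.raises(ValueError, match="too small"):
            bootstrap_robustness(left, right, n_iter=5, n_ref=20, seed=0)
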