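import numpy as np
import pytest

from hubdisrupt import (bootstrap_subgroup_reliability,
                        hemispheric_symmetry_test, icc_one_way,
                        permutation_pvalue)

from oracles import anova_icc


def _two_session_data(n, between_sd, within_sd, rng):
    subject = rng.normal(0, between_sd, size=n)
    return subject[:, None] + rng.normal(0, within_sd, size=(n, 2))


class TestIccOneWay:
    def test_identical_sessions_give_one(self):
        res = icc_one_way([[1.0, 1.0], [5.0, 5.0]])
        assert res.icc == 1.0 and res.s_w == 0.0

    def test_crossed_pattern_gives_minus_one(self):
        res = icc_one_way([[0.0, 1.0], [1.0, 0.0]])
        assert res.icc == -1.0
        assert res.s_b == 0.0 and res.s_w == pytest.approx(0.5)

    def test_matches_anova_oracle(self, rng):
        for _ in range(10):
            x = rng.standard_normal((20, 2)) + rng.normal(0, 2, (20, 1))
            res = icc_one_way(x)
            icc, msb, msw = anova_icc(x)
            assert res.icc == pytest.approx(icc, abs=1e-12)
            assert res.s_b == pytest.approx(msb, abs=1e-12)
            assert res.s_w == pytest.approx(msw, abs=1e-12)

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        x = rng.standard_normal((15, 3)) + rng.normal(0, 1.5, (15, 1))
        res = icc_one_way(x)
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(15), 3),
            "rater": np.tile(np.arange(3), 15),
            "score": x.ravel(),
        })
        table = pg.intraclass_corr(long, targets="subject", raters="rater",
                                   ratings="score")
        icc11 = table["ICC"].iloc[0]  # first row is the one-way ICC(1,1)
        assert res.icc == pytest.approx(icc11, abs=1e-9)

    def test_shift_and_scale_invariance(self, rng):
        x = _two_session_data(15, 2.0, 0.5, rng)
        base = icc_one_way(x).icc
        assert icc_one_way(x + 13.0).icc == pytest.approx(base, abs=1e-12)
        assert icc_one_way(3.0 * x).icc == pytest.approx(base, abs=1e-12)

    def test_monotone_in_noise(self, rng):
        iccs = [
            icc_one_way(_two_session_data(200, 1.0, sd,
                                          np.random.default_rng(4))).icc
            for sd in (0.05, 0.3, 1.0, 3.0)
        ]
        assert all(a > b for a, b in zip(iccs, iccs[1:]))

    def test_degenerate_all_identical_warns(self):
        with pytest.warns(UserWarning, match="identical"):
            res = icc_one_way(np.full((3, 2), 2.0))
        assert res.icc == 1.0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            icc_one_way([[1.0, 2.0]])
        with pytest.raises(ValueError):
            icc_one_way([[1.0, np.nan], [2.0, 3.0]])


class TestPermutationPValue:
    def test_strong_subject_effect_detected(self):
        detected = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = _two_session_data(20, 10.0, 1.0, rng)
            res = permutation_pvalue(x, seed=seed, min_steps=200, batch=100,
                                     max_steps=2000)
            if res.p < 0.05:
                detected += 1
        assert detected >= 95

    def test_null_pvalues_roughly_uniform(self):
        ps = []
        for seed in range(200):
            rng = np.random.default_rng(1000 + seed)
            x = rng.standard_normal((12, 2))
            res = permutation_pvalue(x, seed=seed, min_steps=100, batch=100,
                                     max_steps=400)
            ps.append(res.p)
        assert 0.45 <= np.mean(ps) <= 0.55

    def test_sequential_close_to_fixed_budget_oracle(self):
        rng = np.random.default_rng(5)
        strong = _two_session_data(20, 10.0, 1.0, rng)
        seq = permutation_pvalue(strong, seed=1, min_steps=500, batch=250)
        fixed = permutation_pvalue(strong, seed=2, fixed_budget=9999)
        assert abs(seq.p - fixed.p) < 0.02

        null = np.random.default_rng(6).standard_normal((12, 2))
        seq = permutation_pvalue(null, seed=3, min_steps=2000, batch=500,
                                 max_steps=4000)
        fixed = permutation_pvalue(null, seed=4, fixed_budget=9999)
        assert abs(seq.p - fixed.p) < 0.05

    def test_fixed_budget_uses_plus_one_convention(self):
        rng = np.random.default_rng(7)
        x = _two_session_data(20, 10.0, 0.5, rng)
        res = permutation_pvalue(x, seed=0, fixed_budget=99)
        assert res.p == pytest.approx(1 / 100)
        assert res.steps_used == 99 and res.resolved

    def test_max_steps_exhaustion_flags_unresolved(self):
        # p sits near the decision threshold -> cannot resolve quickly
        rng = np.random.default_rng(8)
        x = rng.standard_normal((10, 2))
        res = permutation_pvalue(x, seed=0, min_steps=100, batch=100,
                                 max_steps=300, alpha=0.5)
        assert res.steps_used <= 300

    def test_column_scheme_supported(self):
        rng = np.random.default_rng(9)
        x = _two_session_data(15, 5.0, 1.0, rng)
        res = permutation_pvalue(x, seed=0, fixed_budget=200,
                                 scheme="columns")
        assert res.p < 0.05


class TestBootstrapSubgroups:
    @pytest.fixture
    def nodal(self):
        """Synthetic nodal degree values: subject slope + session noise."""
        rng = np.random.default_rng(10)
        ref = np.linspace(2, 20, 30)
        n = 24
        slopes = rng.normal(0, 0.25, size=n)
        data = np.empty((n, 2, 30))
        for i in range(n):
            for s in range(2):
                data[i, s] = ref * (1 + slopes[i]) \
                    + rng.normal(0, 0.8, size=30)
        return data

    def test_full_cohort_is_deterministic_single_row(self, nodal):
        df = bootstrap_subgroup_reliability({0.2: nodal}, sizes=[24],
                                            n_boot=50, seed=0)
        assert len(df) == 1
        df2 = bootstrap_subgroup_reliability({0.2: nodal}, sizes=[24],
                                             n_boot=50, seed=99)
        assert df["icc"].iloc[0] == df2["icc"].iloc[0]

    def test_spread_shrinks_with_subgroup_size(self, nodal):
        df = bootstrap_subgroup_reliability({0.2: nodal}, sizes=[8, 16],
                                            n_boot=60, seed=1)
        iqr = df.groupby("size")["icc"].agg(
            lambda s: s.quantile(0.75) - s.quantile(0.25)
        )
        assert iqr[16] < iqr[8]

    def test_seeded_runs_are_identical(self, nodal):
        a = bootstrap_subgroup_reliability({0.2: nodal}, sizes=[10],
                                           n_boot=20, seed=42)
        b = bootstrap_subgroup_reliability({0.2: nodal}, sizes=[10],
                                           n_boot=20, seed=42)
        assert a.equals(b)

    def test_oversized_subgroup_raises(self, nodal):
        with pytest.raises(ValueError, match="exceeds"):
            bootstrap_subgroup_reliability({0.2: nodal}, sizes=[25],
                                           n_boot=5, seed=0)


class TestHemisphericSymmetry:
    def test_identical_data_give_p_one(self):
        vals = np.array([0.1, -0.2, 0.05, 0.3])
        stat, p = hemispheric_symmetry_test(vals, vals.copy())
        assert p == 1.0

    def test_symmetric_cohorts_rarely_reject(self):
        rejections = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            left = rng.normal(0, 0.1, size=20)
            right = rng.normal(0, 0.1, size=20)
            _, p = hemispheric_symmetry_test(left, right, paired=False)
            if p < 0.05:
                rejections += 1
        assert rejections <= 10  # >= 90% non-rejection

    def test_lateralized_cohort_detected(self):
        rng = np.random.default_rng(2)
        left = rng.normal(-0.5, 0.1, size=20)   # left hubs degraded
        right = rng.normal(0.0, 0.1, size=20)
        _, p = hemispheric_symmetry_test(left, right, paired=True)
        assert p < 0.05
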