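import numpy as np
import pytest

from hubdisrupt import (CohortSpec, apply_hub_disruption, hub_indices,
                        make_hub_covariance, nearest_psd_correlation,
                        simulate_cohort, simulate_subject, threshold_to_cost,
                        degree)
from hubdisrupt.synthetic import SyntheticCohort
from hubdisrupt.wavelet import CorrelationMatrix
from hubdisrupt.regions import RegionDefinition


def _noiseless_degree(cov, cost=0.2):
    n = cov.shape[0]
    regions = [RegionDefinition(i + 1, f"r{i}", "left") for i in range(n)]
    cm = CorrelationMatrix(cov, regions)
    return degree(threshold_to_cost(cm, cost))


class TestHubCovariance:
    def test_zero_hub_fraction_without_spread_is_exchangeable(self):
        spec = CohortSpec(hub_fraction=0.0, loading_spread=0.0, n_nodes=20)
        cov = make_hub_covariance(spec)
        off = cov[~np.eye(20, dtype=bool)]
        np.testing.assert_allclose(off, spec.base_corr, atol=1e-8)

    def test_output_is_psd_with_unit_diagonal(self):
        cov = make_hub_covariance(CohortSpec())
        assert np.linalg.eigvalsh(cov).min() >= -1e-10
        np.testing.assert_allclose(np.diag(cov), 1.0)

    def test_hubs_rank_top_in_noiseless_degree(self):
        spec = CohortSpec()
        cov = make_hub_covariance(spec)
        d = _noiseless_degree(cov)
        hubs = hub_indices(spec)
        # every hub sits in the top degree quartile and hubs dominate
        assert (d[hubs] >= np.quantile(d, 0.75)).all()
        periphery = np.setdiff1d(np.arange(spec.n_nodes), hubs)
        assert d[hubs].mean() > 2 * d[periphery].mean()

    def test_psd_repair_restores_unit_diagonal(self):
        c = np.array([[1.0, 0.95, -0.9], [0.95, 1.0, 0.8], [-0.9, 0.8, 1.0]])
        fixed = nearest_psd_correlation(c)
        assert np.linalg.eigvalsh(fixed).min() >= -1e-10
        np.testing.assert_allclose(np.diag(fixed), 1.0)


class TestHubDisruption:
    def test_gamma_zero_is_identity(self):
        spec = CohortSpec()
        cov = make_hub_covariance(spec)
        np.testing.assert_allclose(apply_hub_disruption(cov, spec, gamma=0.0),
                                   cov, atol=1e-10)

    def test_gamma_one_reaches_all_periphery_model(self):
        from hubdisrupt import base_covariance

        spec = CohortSpec()
        cov = make_hub_covariance(spec)
        flat = apply_hub_disruption(cov, spec, gamma=1.0)
        np.testing.assert_allclose(flat, base_covariance(spec), atol=1e-10)
        # hub-hub pairs sit exactly at the base correlation level
        hubs = hub_indices(spec)
        hh = flat[np.ix_(hubs, hubs)][~np.eye(len(hubs), dtype=bool)]
        np.testing.assert_allclose(hh, spec.base_corr, atol=1e-8)

    def test_hub_degree_decreases_monotonically_in_gamma(self):
        spec = CohortSpec()
        cov = make_hub_covariance(spec)
        hubs = hub_indices(spec)
        means = []
        for gamma in (0.0, 0.5, 1.0):
            d = _noiseless_degree(apply_hub_disruption(cov, spec, gamma))
            means.append(d[hubs].mean())
        assert means[0] > means[1] > means[2]

    def test_periphery_boost_raises_nonhub_pairs(self):
        spec = CohortSpec()
        cov = make_hub_covariance(spec)
        boosted = apply_hub_disruption(cov, spec, gamma=0.0,
                                       periphery_boost=0.1)
        hubs = set(hub_indices(spec).tolist())
        i, j = 30, 40  # two non-hub nodes
        assert i not in hubs and j not in hubs
        assert boosted[i, j] > cov[i, j]

    def test_invalid_gamma_rejected(self):
        spec = CohortSpec()
        cov = make_hub_covariance(spec)
        with pytest.raises(ValueError):
            apply_hub_disruption(cov, spec, gamma=1.5)


class TestSimulateSubject:
    def test_same_seed_reproducible(self):
        cov = make_hub_covariance(CohortSpec(n_nodes=10))
        a = simulate_subject(cov, 128, 2.0, ar1=0.3, noise_sd=0.2, seed=5)
        b = simulate_subject(cov, 128, 2.0, ar1=0.3, noise_sd=0.2, seed=5)
        np.testing.assert_array_equal(a.data, b.data)

    def test_sample_correlation_converges_to_target(self):
        cov = make_hub_covariance(CohortSpec(n_nodes=20))
        ts = simulate_subject(cov, 10_000, 2.0, ar1=0.0, noise_sd=0.0, seed=0)
        sample = np.corrcoef(ts.data)
        mask = ~np.eye(20, dtype=bool)
        assert np.abs(sample[mask] - cov[mask]).mean() < 0.03

    def test_ar1_preserves_spatial_correlation(self):
        cov = make_hub_covariance(CohortSpec(n_nodes=15))
        ts = simulate_subject(cov, 10_000, 2.0, ar1=0.6, noise_sd=0.0, seed=1)
        sample = np.corrcoef(ts.data)
        mask = ~np.eye(15, dtype=bool)
        assert np.abs(sample[mask] - cov[mask]).mean() < 0.04

    def test_too_few_timepoints_rejected(self):
        cov = np.eye(4)
        with pytest.raises(ValueError, match="64"):
            simulate_subject(cov, 32, 2.0)


class TestSimulateCohort:
    def test_manifest_records_ground_truth(self, tiny_cohort):
        m = tiny_cohort.manifest
        assert len(m["controls"]) == 6
        assert set(m["lesion_side"].values()) <= {"left", "right"}
        assert m["disruption_gamma"] == tiny_cohort.spec.disruption_gamma

    def test_contralesional_side_opposes_lesion(self, tiny_cohort):
        for pid, side in tiny_cohort.manifest["lesion_side"].items():
            contra = tiny_cohort.contralesional_side(pid)
            assert {side, contra} == {"left", "right"}

    def test_expected_number_of_series(self, tiny_cohort):
        spec = tiny_cohort.spec
        n = (spec.n_controls + spec.n_patients) * spec.n_sessions * 2
        assert len(tiny_cohort.timeseries) == n

    def test_save_load_roundtrip_bit_exact(self, tiny_cohort, tmp_path):
        tiny_cohort.save(tmp_path / "cohort")
        back = SyntheticCohort.load(tmp_path / "cohort")
        assert back.manifest["lesion_side"] == \
            tiny_cohort.manifest["lesion_side"]
        key = next(iter(tiny_cohort.timeseries))
        np.testing.assert_array_equal(back.timeseries[key].data,
                                      tiny_cohort.timeseries[key].data)
        assert set(back.timeseries) == set(tiny_cohort.timeseries)

    def test_same_spec_reproduces_cohort(self):
        spec = CohortSpec(n_controls=2, n_patients=2,
                          n_patients_left_lesion=1, n_nodes=8,
                          n_timepoints=64, seed=3)
        a = simulate_cohort(spec)
        b = simulate_cohort(spec)
        for key in a.timeseries:
            np.testing.assert_array_equal(a.timeseries[key].data,
                                          b.timeseries[key].data)
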