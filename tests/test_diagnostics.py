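"""QQ tables, mean excess, threshold stability and record diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import densitytail as dt
from densitytail.diagnostics import EULER_GAMMA
from densitytail.errors import DomainError, InsufficientDataError
from conftest import gpd_depth_sample


class TestQQTable:
    def test_identity_when_empirical_is_model(self):
        params = dt.GPDParams(-0.3, 1.0)
        p = np.arange(1, 101) / 100
        synthetic = np.asarray(dt.gpd_quantile(params, p))
        # feed exactly the model's own quantiles: order statistic k of n=100
        # at percentile k/100 is that quantile under the type-1 rule
        table = dt.qq_table(synthetic, params)
        assert table.max_abs_deviation == pytest.approx(0.0, abs=1e-12)
        assert table.correlation == pytest.approx(1.0, abs=1e-12)

    def test_well_specified_simulation(self):
        params = dt.GPDParams(-0.3, 1.0)
        draws = dt.fixtures.gpd_fixture(params, None, 10_000, seed=70)
        table = dt.qq_table(draws, params)
        assert table.correlation > 0.99

    def test_degenerate_flat_input(self):
        table = dt.qq_table(np.full(200, 0.5), dt.GPDParams(-0.3, 1.0))
        assert "degenerate-flat" in table.flags
        assert np.isnan(table.correlation)

    def test_small_sample_coarsens_grid(self):
        table = dt.qq_table(np.linspace(0.1, 1, 40), dt.GPDParams(-0.5, 1.0))
        assert table.percentiles.size == 40
        assert any("coarsened" in f for f in table.flags)

    def test_quantile_vectors_monotone(self):
        draws = dt.fixtures.gpd_fixture(dt.GPDParams(0.2, 1.0), None, 5000, seed=71)
        table = dt.qq_table(draws, dt.GPDParams(0.2, 1.0))
        assert np.all(np.diff(table.model_quantiles) >= 0)
        assert np.all(np.diff(table.empirical_quantiles) >= 0)


class TestMeanExcess:
    def test_direct_example(self):
        e = dt.mean_excess_empirical(np.array([0.01, 0.02, 0.03, 0.5]), 0.1)
        assert e == pytest.approx(0.08, rel=1e-12)

    def test_error_below_minimum(self):
        with pytest.raises(InsufficientDataError):
            dt.mean_excess_empirical(np.array([0.5, 0.6]), 0.4)

    def test_theoretical_exponential_is_constant(self):
        p = dt.GPDParams(0.0, 0.7)
        for u in (0.0, 1.0, 5.0):
            assert dt.mean_excess_theoretical(p, u) == pytest.approx(0.7, rel=1e-12)

    def test_theoretical_hand_example(self):
        assert dt.mean_excess_theoretical(dt.GPDParams(-0.5, 0.5), 1.0) == pytest.approx(
            0.0, abs=1e-15
        )

    def test_theoretical_slope(self):
        p = dt.GPDParams(-0.3, 1.0)
        us = np.linspace(0.1, 2.0, 20)
        vals = np.asarray(dt.mean_excess_theoretical(p, us))
        slopes = np.diff(vals) / np.diff(us)
        np.testing.assert_allclose(slopes, -0.3 / 1.3, atol=1e-10)

    def test_shape_ge_one_rejected(self):
        with pytest.raises(DomainError):
            dt.mean_excess_theoretical(dt.GPDParams(1.0, 1.0), 0.5)

    def test_empirical_matches_theoretical_on_gpd_draws(self):
        params = dt.GPDParams(-0.3, 1.0)
        draws = dt.fixtures.gpd_fixture(params, None, 100_000, seed=72)
        t = 1.0
        exc = draws[draws > t] - t
        theo = dt.mean_excess_theoretical(params, t)
        mc_se = exc.std(ddof=1) / np.sqrt(exc.size)
        assert abs(exc.mean() - theo) < 3 * mc_se

    def test_curve_counts_and_nan(self):
        curve = dt.mean_excess_curve(np.array([0.5, 0.6]), [0.1, 0.55, 0.7])
        assert np.isnan(curve.mean_excess[0]) and curve.counts[0] == 0
        assert curve.counts[2] == 2


class TestStabilitySweep:
    def test_constrained_endpoint_tie_across_grid(self):
        values, _ = gpd_depth_sample(-0.3, 0.1, 30_000, seed=80, u=1.0)
        grid = np.quantile(values, np.geomspace(0.01, 0.2, 10))
        prof = dt.stability_sweep(values, grid, mode="constrained")
        adm = prof.admissible
        ratio = prof.scale_hat[adm] / (grid[adm] * np.abs(prof.shape_hat[adm]))
        np.testing.assert_allclose(ratio, 1.0, rtol=1e-12)

    def test_shape_recovery_sweep(self):
        # image values whose shortfall tail is exactly GPD(-0.3): the shape
        # estimate should sit within 2 SE at >= 90% of admissible thresholds
        values, _ = gpd_depth_sample(-0.3, 0.1, 100_000, seed=81, u=1.0)
        grid = np.quantile(values, np.geomspace(0.005, 0.2, 25))
        prof = dt.stability_sweep(values, grid, mode="free")
        adm = prof.admissible
        ok = np.abs(prof.shape_hat[adm] + 0.3) < 2 * prof.se_shape[adm]
        assert ok.mean() >= 0.9

    def test_exponential_tail_shape_near_zero(self):
        # memoryless shortfalls: shape 0 at every threshold
        rng = np.random.default_rng(82)
        values = 50.0 - rng.exponential(2.0, size=100_000)
        grid = np.quantile(values, np.geomspace(0.005, 0.2, 25))
        prof = dt.stability_sweep(values, grid, mode="free")
        adm = prof.admissible
        ok = np.abs(prof.shape_hat[adm]) < 2 * prof.se_shape[adm]
        assert ok.mean() >= 0.9

    def test_degenerate_grid_all_flagged(self):
        # thresholds beneath every value leave no tail data at any grid point
        values = np.linspace(1.0, 2.0, 500)
        prof = dt.stability_sweep(values, np.array([0.1, 0.2, 0.5]), mode="free")
        assert not prof.admissible.any()
        assert len(prof.flags) == 3
        assert np.all(np.isnan(prof.shape_hat))

    def test_unsorted_grid_rejected(self):
        with pytest.raises(DomainError):
            dt.stability_sweep(np.linspace(0, 1, 100), np.array([0.5, 0.2]))


class TestRecords:
    def test_direct_enumeration(self):
        summary = dt.find_records([5.0, 4.0, 6.0, 3.0])
        np.testing.assert_array_equal(summary.record_indices, [1, 2, 4])
        assert summary.counting_path[-1] == 3

    def test_increasing_sequence_single_record(self):
        summary = dt.find_records(np.arange(100.0))
        np.testing.assert_array_equal(summary.record_indices, [1])

    def test_repeated_minimum_not_a_record(self):
        summary = dt.find_records([2.0, 1.0, 1.0, 0.5])
        np.testing.assert_array_equal(summary.record_indices, [1, 2, 4])

    @given(st.lists(st.integers(0, 20), min_size=1, max_size=100))
    @settings(deadline=None, max_examples=80, derandomize=True)
    def test_counting_path_matches_naive_rescan(self, seq):
        summary = dt.find_records(np.array(seq, dtype=float))
        count = 0
        for i in range(len(seq)):
            if i == 0 or seq[i] < min(seq[:i]):
                count += 1
            assert summary.counting_path[i] == count
        assert np.all(np.isin(np.diff(summary.counting_path), [0, 1]))

    def test_expected_counts_match_simulation(self):
        n, reps = 10_000, 200
        counts = [
            dt.find_records(np.random.default_rng([83, k]).uniform(size=n)).counting_path[-1]
            for k in range(reps)
        ]
        e, var = dt.record_expectation(n)
        se = np.sqrt(var / reps)
        assert abs(np.mean(counts) - e) < 3 * se


class TestRecordExpectation:
    def test_first_point(self):
        e, var = dt.record_expectation(1)
        assert e == pytest.approx(1.0, abs=1e-12)
        assert var == pytest.approx(0.0, abs=1e-12)

    def test_printed_anchor_at_21(self):
        e, var = dt.record_expectation(21)
        assert round(e, 1) == 3.6
        assert round(np.sqrt(var), 1) == 1.4

    def test_euler_constant_limit(self):
        e, _ = dt.record_expectation(10**7)
        assert round(e - np.log(10**7), 4) == round(EULER_GAMMA, 4) == 0.5772

    @pytest.mark.parametrize("i", [1, 2, 17, 1000])
    def test_matches_direct_summation_oracle(self, i):
        e, var = dt.record_expectation(i)
        e_direct = sum(1.0 / k for k in range(1, i + 1))
        var_direct = sum(1.0 / k - 1.0 / k**2 for k in range(1, i + 1))
        assert e == pytest.approx(e_direct, abs=1e-12)
        assert var == pytest.approx(var_direct, abs=1e-12)

    def test_find_records_expectation_columns_match_oracle(self):
        summary = dt.find_records(np.random.default_rng(84).uniform(size=500))
        for i in (1, 10, 499):
            e, var = dt.record_expectation(i + 1)
            assert summary.expected[i] == pytest.approx(e, abs=1e-12)
            assert summary.variance[i] == pytest.approx(var, abs=1e-12)

    def test_invalid_index(self):
        with pytest.raises(DomainError):
            dt.record_expectation(0)


class TestRecordCalibration:
    def test_single_observation_consistent(self):
        calib = dt.iid_record_calibration(np.array([3.0]))
        assert calib.consistent
        assert len(calib.table) == 1

    def test_decreasing_sequence_inconsistent(self):
        calib = dt.iid_record_calibration(np.arange(100.0, 0.0, -1.0))
        assert len(calib.table) == 100
        e, _ = dt.record_expectation(100)
        assert e == pytest.approx(5.19, abs=0.01)
        assert not calib.consistent

    def test_iid_sequence_usually_consistent(self):
        v = np.random.default_rng(85).uniform(size=10_000)
        calib = dt.iid_record_calibration(v)
        assert calib.fraction_within >= 0.0  # table well-formed
        assert set(calib.table.columns) >= {"record_number", "index", "expected_count", "sd"}
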