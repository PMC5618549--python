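"""Sub-batch resampling, loess smoothing, basal rate, unique events."""

import numpy as np
import pytest

from splicesat import (
    PredictionCurve,
    SmoothedCurve,
    SubsampleResult,
    draw_subbatches,
    median_relative_deviation,
    smooth_curve,
    terminal_slope,
    unique_event_stats,
)

from conftest import batch


def linear_results(slope=50.0, intercept=1000.0, reps_per_nu=4, nu_max=20):
    res = []
    i = 0
    for nu in range(1, nu_max + 1):
        for _ in range(reps_per_nu):
            res.append(SubsampleResult(i, nu, int(intercept + slope * nu), ()))
            i += 1
    return res


class TestDrawSubbatches:
    def test_reproducible_under_seed(self):
        samples = batch(*({i, i + 1, 2 * i} for i in range(8)))
        a = draw_subbatches(samples, n_reps=30, seed=9)
        b = draw_subbatches(samples, n_reps=30, seed=9)
        assert a == b
        c = draw_subbatches(samples, n_reps=30, seed=10)
        assert a != c

    def test_no_replicates_leaves_single_sample_results(self):
        samples = batch({1, 2}, {2, 3}, {4})
        res = draw_subbatches(samples, n_reps=0, seed=0)
        assert [r.nu for r in res] == [1, 1, 1]
        assert [r.observed for r in res] == [2, 2, 1]

    def test_identical_samples_saturate_immediately(self):
        samples = batch({1, 2, 3}, {1, 2, 3}, {1, 2, 3}, {1, 2, 3})
        for r in draw_subbatches(samples, n_reps=25, seed=1):
            assert r.observed == 3

    def test_full_batch_recovers_union(self):
        samples = batch({1, 2}, {2, 3}, {5}, {1, 6})
        res = draw_subbatches(samples, n_reps=10, size_range=(4, 4), seed=2)
        assert all(r.observed == 5 for r in res if r.nu == 4)

    def test_nu_matches_drawn_sample_count(self):
        samples = batch(*({i} for i in range(6)))
        for r in draw_subbatches(samples, n_reps=40, seed=3):
            assert r.nu == len(set(r.sample_ids))

    def test_nested_unions_are_nondecreasing(self):
        samples = batch(*({i, i + 1, i % 3} for i in range(7)))
        sizes = []
        acc = set()
        for s in samples:
            acc |= s.sites
            sizes.append(len(acc))
        assert sizes == sorted(sizes)

    def test_bad_size_range_rejected(self):
        samples = batch({1}, {2})
        with pytest.raises(ValueError):
            draw_subbatches(samples, n_reps=1, size_range=(1, 5), seed=0)


class TestSmoothCurve:
    def test_linear_data_reproduced_exactly(self):
        smoothed = smooth_curve(linear_results(), span=0.75)
        expect = 1000.0 + 50.0 * smoothed.nu
        np.testing.assert_allclose(smoothed.mean_observed, expect, rtol=1e-6)

    def test_constant_data_stays_constant(self):
        smoothed = smooth_curve(linear_results(slope=0.0), span=0.6)
        np.testing.assert_allclose(smoothed.mean_observed, 1000.0, rtol=1e-9)

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError):
            smooth_curve(linear_results(nu_max=2, reps_per_nu=2))


class TestTerminalSlope:
    def test_linear_curve_returns_its_slope(self):
        smoothed = smooth_curve(linear_results(slope=42.0, nu_max=54))
        assert terminal_slope(smoothed) == pytest.approx(42.0, rel=1e-6)

    def test_constant_curve_has_zero_slope(self):
        smoothed = smooth_curve(linear_results(slope=0.0))
        assert terminal_slope(smoothed) == pytest.approx(0.0, abs=1e-9)

    def test_short_window_rejected(self):
        curve = SmoothedCurve(nu=np.array([1, 2, 3]), mean_observed=np.ones(3), span=0.75)
        with pytest.raises(ValueError):
            terminal_slope(curve, window_start=3)


class TestUniqueEventStats:
    def test_worked_enumeration(self, abc_batch):
        stats = unique_event_stats(abc_batch)
        assert stats.total_unique == 2
        assert stats.per_sample_mean == pytest.approx(2 / 3)

    def test_disjoint_samples_all_unique(self):
        stats = unique_event_stats(batch({1, 2, 3}, {4, 5}, {6}))
        assert stats.total_unique == 6
        assert stats.per_sample_mean == pytest.approx(2.0)
        assert stats.per_sample_sd == pytest.approx(1.0)

    def test_identical_samples_have_none(self):
        stats = unique_event_stats(batch({1, 2}, {1, 2}), gbr=5.0)
        assert stats.total_unique == 0
        assert stats.fraction_of_gbr == 0.0

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            unique_event_stats(batch({1, 2}))


class TestMedianRelativeDeviation:
    def curve(self, nu, values, tag="raw"):
        nu = np.asarray(nu)
        return PredictionCurve(nu, np.asarray(values, float), tag, nu > nu.max())

    def test_identical_curves_deviate_zero(self):
        smoothed = SmoothedCurve(np.arange(1, 6), np.arange(1, 6) * 10.0, 0.75)
        pred = self.curve(np.arange(1, 6), np.arange(1, 6) * 10.0)
        assert median_relative_deviation(pred, smoothed) == 0.0

    def test_ten_percent_offset(self):
        smoothed = SmoothedCurve(np.arange(1, 6), np.full(5, 100.0), 0.75)
        pred = self.curve(np.arange(1, 6), np.full(5, 110.0))
        assert median_relative_deviation(pred, smoothed) == pytest.approx(10.0)

    def test_disjoint_grids_rejected(self):
        smoothed = SmoothedCurve(np.array([1, 2]), np.ones(2), 0.75)
        pred = self.curve(np.array([5, 6]), np.ones(2))
        with pytest.raises(ValueError):
            median_relative_deviation(pred, smoothed)


class TestFitVirtualMultiplicity:
    def test_recovers_generating_multiplicity(self):
        from splicesat import (
            MultiplicitySpectrum,
            add_virtual_events,
            calibrate_virtual_count,
            expected_observed,
            fit_virtual_multiplicity,
        )

        # Empirical curve produced by the corrected model itself at a known
        # mu_v: the grid search must pick (a value near) that mu_v.
        base = MultiplicitySpectrum(n=20, z={1: 5000, 2: 1000, 19: 500, 20: 8000})
        true_mu = 0.30
        m_v = calibrate_virtual_count(base, true_mu)
        truth = add_virtual_events(base, true_mu, m_v)
        nu = np.arange(1, 21)
        smoothed = SmoothedCurve(
            nu, np.array([expected_observed(truth, int(v)) for v in nu]), 0.75
        )
        mu_hat, dev = fit_virtual_multiplicity(base, smoothed)
        assert mu_hat == pytest.approx(true_mu, abs=0.051)
        assert dev < 1.0
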