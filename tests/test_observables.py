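import numpy as np
import pytest

from epivertex.observables import (
    CorrelationCurve,
    aligned_t1_profiles,
    autocorr,
    cross_corr,
    cumulative_t1_curve,
    fit_exp_decay,
    fit_saturating,
    length_cv,
    polygon_fractions,
    snapshot_tension_cv,
    t1_rate,
    topological_disorder,
    windowed_rate,
)
from epivertex.tissue import build_honeycomb


class TestT1Rate:
    def test_zero_events(self):
        assert t1_rate(0, 100, 60.0) == 0.0

    def test_arithmetic(self):
        assert t1_rate(10, 200, 90.0) == pytest.approx(5.56e-4, rel=1e-3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            t1_rate(1, 100, 0.0)
        with pytest.raises(ValueError):
            t1_rate(1, 0, 10.0)


class TestDisorder:
    def test_honeycomb_zero(self):
        assert topological_disorder(build_honeycomb(4, 4, 1.0)) == 0.0

    def test_arithmetic(self):
        assert topological_disorder([5, 6, 7]) == pytest.approx(np.sqrt(2 / 3))

    def test_matches_brute_force(self, voronoi_small):
        sides = [len(c) for c in voronoi_small.cells]
        mean = sum(sides) / len(sides)
        expected = (sum((s - mean) ** 2 for s in sides) / len(sides)) ** 0.5
        assert topological_disorder(voronoi_small) == pytest.approx(expected)


class TestPolygonFractions:
    def test_honeycomb(self):
        assert polygon_fractions(build_honeycomb(4, 4, 1.0)) == {6: 1.0}

    def test_mixed(self):
        fr = polygon_fractions([5, 6, 6, 7])
        assert fr == {5: 0.25, 6: 0.5, 7: 0.25}

    def test_sums_to_one(self, voronoi_small):
        assert sum(polygon_fractions(voronoi_small).values()) == pytest.approx(1.0)


class TestCVs:
    def test_equal_lengths_zero(self):
        assert length_cv(np.full(10, 2.5)) == 0.0

    def test_arithmetic(self):
        assert length_cv(np.array([1.0, 2.0, 3.0])) == pytest.approx(0.408, abs=1e-3)

    def test_uniform_tension_zero(self):
        assert snapshot_tension_cv(np.ones(50)) == 0.0

    def test_variance_addition(self):
        # extrinsic CoV 0.13 + independent intrinsic CoV 0.08 -> 0.153
        rng = np.random.default_rng(0)
        n = 200_000
        values = rng.normal(1.0, 0.13, n) + rng.normal(0.0, 0.08, n)
        assert snapshot_tension_cv(values) == pytest.approx(
            np.sqrt(0.13**2 + 0.08**2), abs=0.002
        )

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            length_cv(np.zeros(5))


class TestAutocorr:
    def test_white_noise(self):
        rng = np.random.default_rng(1)
        c = 0.1
        series = 1.0 + rng.normal(0.0, c, size=(300, 200))
        curve = autocorr(series, 0.5, max_lag=3.0)
        assert curve.values[0] == pytest.approx(c**2, rel=0.1)
        # small negative finite-series bias (~ -c^2/T) plus noise
        assert abs(curve.values[2]) < c**2 / 20

    def test_lag0_equals_squared_cov(self):
        rng = np.random.default_rng(2)
        series = 1.0 + rng.normal(0.0, 0.05, size=(1, 500))
        curve = autocorr(series, 0.5, max_lag=2.0)
        cov = series.std(axis=1) / series.mean(axis=1)
        assert curve.values[0] == pytest.approx(float(cov[0] ** 2), rel=1e-6)

    def test_constant_series_zero_curve(self):
        curve = autocorr(np.full((3, 50), 4.0), 0.5, max_lag=2.0)
        assert np.allclose(curve.values, 0.0)

    def test_ou_closed_form(self):
        from epivertex.fixtures import TraceConfig, synth_traces

        tr, _ = synth_traces(
            TraceConfig(n_junctions=600, n_frames=600, cov_extrinsic=0.0, seed=3)
        )
        curve = autocorr(tr, 0.5, max_lag=4.0)
        expected = 0.08**2 * np.exp(-curve.lags / 2.2)
        assert np.allclose(curve.values, expected, atol=3 * 0.0064 / np.sqrt(600))


class TestFitExpDecay:
    def test_exact_recovery(self):
        lags = np.arange(0, 21) * 0.5
        values = 0.0064 * np.exp(-0.451 * lags)
        a, b, tau, _ = fit_exp_decay(CorrelationCurve(lags, values, 1))
        assert a == pytest.approx(0.0064, rel=1e-6)
        assert b == pytest.approx(0.451, rel=1e-6)
        assert tau == pytest.approx(1 / 0.451, rel=1e-6)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_exp_decay(CorrelationCurve(np.array([0.0, 1, 2]), np.ones(3), 1))

    def test_nonpositive_start_rejected(self):
        with pytest.raises(ValueError):
            fit_exp_decay(
                CorrelationCurve(np.arange(5.0), -np.ones(5), 1)
            )


class TestCrossCorr:
    def test_constructed_shift(self):
        # b(t) = -a(t - 1 min): minimum of -1 at lag +1 min
        rng = np.random.default_rng(4)
        n_t = 400
        a = rng.normal(0, 1, size=(20, n_t + 2))
        b = -a[:, :-2]
        a = a[:, 2:]
        curve = cross_corr(a, b, 0.5, max_lag=4.0)
        assert curve.lag_of_min() == pytest.approx(1.0)
        i = np.argmin(np.abs(curve.lags - 1.0))
        assert curve.values[i] == pytest.approx(-1.0, abs=0.05)

    def test_independent_noise_flat(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, size=(50, 300))
        b = rng.normal(0, 1, size=(50, 300))
        curve = cross_corr(a, b, 0.5, max_lag=3.0)
        assert np.abs(curve.values).max() < 4 / np.sqrt(50 * 300)

    def test_zero_variance_excluded(self):
        a = np.vstack([np.ones(100), np.random.default_rng(0).normal(size=100)])
        b = np.random.default_rng(1).normal(size=(2, 100))
        curve = cross_corr(a, b, 0.5, max_lag=2.0)
        assert curve.n_junctions == 1

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            cross_corr(np.ones((2, 10)), np.ones((3, 10)), 0.5)


class TestCumulativeCurves:
    def test_linear_windowed_rate(self):
        r = 0.02
        times = np.arange(1, 201) / r / 200  # events every 0.25 min
        t, c = cumulative_t1_curve(times, 200)  # C(t) = r t per junction
        grid = np.linspace(10, 40, 7)
        _, rates = windowed_rate(t, c, window=10.0, grid=grid)
        assert np.allclose(rates, r, rtol=0.15)

    def test_saturating_fit_recovery(self):
        t = np.linspace(0, 80, 200)
        c = 2.0 * (1 - np.exp(-0.05 * t))
        a, b = fit_saturating(t, c)
        assert a == pytest.approx(2.0, rel=1e-5)
        assert b == pytest.approx(0.05, rel=1e-5)

    def test_initial_slope_identity(self):
        a, b = fit_saturating(
            np.linspace(0, 50, 100), 3.0 * (1 - np.exp(-0.1 * np.linspace(0, 50, 100)))
        )
        assert a * b == pytest.approx(0.3, rel=1e-5)


class _Ev:
    def __init__(self, t, e):
        self.time = t
        self.edge_id = e


class TestAlignedProfiles:
    def test_conserving_construction(self):
        # neighbor gains exactly offset the focal loss -> flat total
        times = np.arange(0, 20.0, 0.5)
        focal = np.maximum(2.0 - 0.2 * np.abs(times - 10.0), 0.5)
        nb = (8.0 - focal) / 4.0
        series = {0: focal, 1: nb, 2: nb, 3: nb, 4: nb}
        prof = aligned_t1_profiles(
            series, times, [_Ev(10.0, 0)], {0: [1, 2, 3, 4]},
            half_window=3.0, frame_interval=0.5,
        )
        assert prof["n_used"] == 1
        assert np.allclose(prof["total"], 8.0)
        assert prof["focal"].min() < prof["focal"].max()  # real excursion

    def test_window_exceeding_track_excluded(self):
        times = np.arange(0, 5.0, 0.5)
        series = {0: np.ones_like(times)}
        prof = aligned_t1_profiles(
            series, times, [_Ev(0.5, 0)], {0: [1, 2, 3, 4]},
            half_window=3.0, frame_interval=0.5,
        )
        assert prof["n_used"] == 0
        assert prof["n_excluded"] == 1
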