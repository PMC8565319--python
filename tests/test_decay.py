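import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dropfret.decay import (DecayCurve, InstrumentResponse, MultiExponentialModel,
                            average_lifetime, fit_decay, model_decay, reduced_chi2,
                            sigma_for_window, stitch_windows, weighted_chi2)
from dropfret.errors import (DataError, InvalidParameterError, StitchError)

from .oracles import convolution_oracle


def make_curve(model, irf, window=20.0, n_bins=1000, total=1e6, seed=None,
               dark=0.0, **kw):
    t = (np.arange(n_bins) + 0.5) * (window / n_bins)
    shape = model_decay(model, irf, t)
    expected = shape * (total / shape.sum()) + dark
    if seed is None:
        counts = expected
    else:
        counts = np.random.default_rng(seed).poisson(expected).astype(float)
    return DecayCurve(times=t, counts=counts, window=window, **kw)


class TestModelDecay:
    def test_sigma_to_zero_limit(self):
        # single component, sigma -> 0: plain exponential, 1/e at t0 + tau
        m = MultiExponentialModel.from_arrays([1.0], [0.5])
        irf = InstrumentResponse(sigma=1e-6, t0=0.3)
        val = model_decay(m, irf, [0.3 + 0.5])[0]
        assert val == pytest.approx(np.exp(-1.0), rel=1e-9)

    def test_pre_pulse_baseline_is_offset(self):
        m = MultiExponentialModel.from_arrays([2.0, 1.0], [0.2, 3.0], offset=7.5)
        irf = InstrumentResponse(sigma=0.05, t0=1.0)
        val = model_decay(m, irf, [irf.t0 - 10 * irf.sigma])[0]
        assert val == pytest.approx(7.5, rel=1e-10)

    def test_matches_numerical_convolution_at_t0(self):
        # frozen from the trapezoidal/quad convolution oracle (0.1 ps grid)
        m = MultiExponentialModel.from_arrays([1.0], [0.1])
        irf = InstrumentResponse(sigma=0.01, t0=0.0)
        val = model_decay(m, irf, [0.0])[0]
        assert val == pytest.approx(0.4624787852875358, rel=1e-6)

    @settings(max_examples=15, deadline=None)
    @given(
        taus=st.lists(st.floats(0.05, 5.0), min_size=1, max_size=3),
        amps=st.lists(st.floats(0.05, 3.0), min_size=3, max_size=3),
        sigma=st.floats(0.01, 0.3),
        t0=st.floats(-0.5, 0.5),
        offset=st.floats(0.0, 5.0),
    )
    def test_property_matches_convolution_oracle(self, taus, amps, sigma, t0, offset):
        taus = np.array(sorted(set(np.round(taus, 6))))
        amps = np.array(amps[: len(taus)])
        m = MultiExponentialModel.from_arrays(amps, taus, offset=offset)
        irf = InstrumentResponse(sigma=sigma, t0=t0)
        t = np.linspace(t0 - 3 * sigma, t0 + 10 * taus.max(), 25)
        got = model_decay(m, irf, t)
        want = convolution_oracle(t, t0, sigma, m.amplitudes, m.lifetimes, offset)
        np.testing.assert_allclose(got, want, rtol=1e-6, atol=1e-9 * amps.sum())

    def test_monotone_after_pulse(self):
        m = MultiExponentialModel.from_arrays([1.0, 0.5], [0.3, 2.0])
        irf = InstrumentResponse(sigma=0.05, t0=0.2)
        t = np.linspace(irf.t0 + 5 * irf.sigma, 15.0, 500)
        vals = model_decay(m, irf, t)
        assert np.all(np.diff(vals) <= 0)

    def test_per_bin_sigma_array(self):
        m = MultiExponentialModel.from_arrays([1.0], [1.0])
        irf = InstrumentResponse(sigma=0.01, t0=0.1)
        t = np.linspace(0.0, 5.0, 50)
        sig = np.full(50, 0.05)
        a = model_decay(m, irf, t, sigma=sig)
        b = model_decay(m, InstrumentResponse(sigma=0.05, t0=0.1), t)
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_invalid_parameters(self):
        m = MultiExponentialModel.from_arrays([1.0], [1.0])
        with pytest.raises(InvalidParameterError):
            InstrumentResponse(sigma=-0.1, t0=0.0)
        with pytest.raises(InvalidParameterError):
            model_decay(m, InstrumentResponse(sigma=0.1, t0=0.0), [np.nan])
        with pytest.raises(InvalidParameterError):
            model_decay(m, InstrumentResponse(sigma=0.1, t0=0.0), [1.0], sigma=0.0)


class TestChi2:
    def test_perfect_fit_is_zero(self):
        t = np.linspace(0, 1, 50)
        c = DecayCurve(times=t, counts=np.full(50, 5.0), window=1.0)
        assert reduced_chi2(c, np.full(50, 5.0), n_free=3) == 0.0

    def test_single_bin_arithmetic(self):
        # one bin y=4, f=2: (4-2)^2/4 = 1
        assert weighted_chi2(np.array([4.0]), np.array([2.0])) == pytest.approx(1.0)

    def test_poisson_expectation_near_one(self):
        # 2000 bins sampled from a known model, predicted = truth, n_free=0
        m = MultiExponentialModel.from_arrays([1.0, 0.4], [0.5, 3.0])
        irf = InstrumentResponse(sigma=0.05, t0=0.5)
        t = (np.arange(2000) + 0.5) * (20.0 / 2000)
        shape = model_decay(m, irf, t)
        expected = shape * (2e6 / shape.sum()) + 5.0
        counts = np.random.default_rng(123).poisson(expected).astype(float)
        curve = DecayCurve(times=t, counts=counts, window=20.0)
        red = weighted_chi2(counts, expected) / curve.n_bins
        assert red == pytest.approx(1.0, abs=0.05)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(100.0, 200).astype(float)
        f = y + rng.normal(0, 5, 200)
        perm = rng.permutation(200)
        assert weighted_chi2(y, f) == pytest.approx(weighted_chi2(y[perm], f[perm]))

    def test_shape_mismatch(self):
        with pytest.raises(DataError):
            weighted_chi2(np.ones(5), np.ones(4))


class TestAverageLifetime:
    def test_reference_stem_loop_value(self):
        m = MultiExponentialModel.from_arrays([0.46, 0.44, 0.10], [0.11, 0.71, 2.66])
        assert round(average_lifetime(m), 2) == 0.63

    def test_single_component_identity(self):
        m = MultiExponentialModel.from_arrays([1.0], [4.19])
        assert average_lifetime(m) == pytest.approx(4.19)

    def test_symmetric_mean(self):
        m = MultiExponentialModel.from_arrays([0.5, 0.5], [1.0, 3.0])
        assert average_lifetime(m) == pytest.approx(2.0)

    @given(
        amps=st.lists(st.floats(0.01, 5.0), min_size=1, max_size=4),
        taus=st.lists(st.floats(0.01, 10.0), min_size=4, max_size=4),
    )
    def test_bounded_by_lifetime_range(self, amps, taus):
        taus = np.array(sorted(set(np.round(taus, 6))))[: len(amps)]
        amps = np.array(amps[: len(taus)])
        m = MultiExponentialModel.from_arrays(amps, taus)
        av = average_lifetime(m)
        assert taus.min() - 1e-12 <= av <= taus.max() + 1e-12

    def test_zero_amplitudes_rejected(self):
        m = MultiExponentialModel.from_arrays([0.0, 0.0], [1.0, 2.0])
        with pytest.raises(InvalidParameterError):
            average_lifetime(m)


class TestFitDecay:
    def test_noiseless_monoexponential_recovery(self):
        m = MultiExponentialModel.from_arrays([1000.0], [4.19])
        irf = InstrumentResponse(sigma=0.2, t0=0.1)
        curve = make_curve(m, irf, total=1e6)
        res = fit_decay(curve, InstrumentResponse(sigma=0.15, t0=0.2),
                        max_components=2, n_starts=2)
        assert res.model.n_components == 1
        assert res.model.lifetimes[0] == pytest.approx(4.19, rel=1e-6)
        assert res.irf.sigma == pytest.approx(0.2, rel=1e-4)

    def test_noiseless_insensitive_to_initialisation(self):
        m = MultiExponentialModel.from_arrays([500.0], [2.0])
        irf = InstrumentResponse(sigma=0.1, t0=0.3)
        curve = make_curve(m, irf, total=5e5)
        for sig0, t00 in [(0.05, 0.1), (0.3, 0.6)]:
            res = fit_decay(curve, InstrumentResponse(sigma=sig0, t0=t00),
                            max_components=1, n_starts=3, seed=5)
            assert res.model.lifetimes[0] == pytest.approx(2.0, rel=1e-6)

    def test_triexponential_poisson_recovery(self, signatures):
        m = MultiExponentialModel.from_arrays(
            signatures.sl_amplitudes, signatures.sl_lifetimes)
        irf = InstrumentResponse(sigma=0.01, t0=0.1)
        curve = make_curve(m, irf, window=5.0, total=1e6, seed=11, dark=1.0)
        res = fit_decay(curve, InstrumentResponse(sigma=0.02, t0=0.05),
                        max_components=4, seed=1)
        assert res.model.n_components == 3
        amps = res.model.amplitudes / res.model.amplitudes.sum()
        np.testing.assert_allclose(res.model.lifetimes,
                                   signatures.sl_lifetimes, rtol=0.10)
        np.testing.assert_allclose(amps, signatures.sl_amplitudes, atol=0.05)

    def test_underfit_biexponential_flagged_by_chi2(self):
        m = MultiExponentialModel.from_arrays([800.0, 800.0], [0.3, 3.0])
        irf = InstrumentResponse(sigma=0.05, t0=0.2)
        curve = make_curve(m, irf, total=1e6, seed=3)
        res = fit_decay(curve, irf, max_components=1, n_starts=2)
        assert res.chi2_reduced > 2.0

    def test_all_zero_counts_rejected(self):
        t = np.linspace(0, 1, 200)
        curve = DecayCurve(times=t, counts=np.zeros(200), window=1.0)
        with pytest.raises(DataError):
            fit_decay(curve, InstrumentResponse(sigma=0.01, t0=0.1))

    def test_too_few_bins_rejected(self):
        t = np.linspace(0, 1, 40)
        curve = DecayCurve(times=t, counts=np.ones(40), window=1.0)
        with pytest.raises(DataError):
            fit_decay(curve, InstrumentResponse(sigma=0.01, t0=0.1), max_components=4)


class TestStitchWindows:
    def windows(self, model, sigma_by_window, scale_by_window=None, n_bins=400):
        curves = []
        for w, sig in sigma_by_window.items():
            t = (np.arange(n_bins) + 0.5) * (w / n_bins)
            irf = InstrumentResponse(sigma=sig, t0=0.05)
            counts = model_decay(model, irf, t)
            if scale_by_window:
                counts = counts * scale_by_window.get(w, 1.0)
            curves.append(DecayCurve(times=t, counts=counts, window=w,
                                     propagation_time=1.0,
                                     sigma_bins=np.full(n_bins, sig)))
        return curves

    def test_noiseless_shared_sigma_scales_are_unity(self):
        # commensurate windows (successive ratio 5) share bin centres, so the
        # overlap comparison is exact and the scale factors are exactly 1
        m = MultiExponentialModel.from_arrays([1000.0, 300.0], [0.4, 3.0])
        curves = self.windows(m, {1.0: 0.01, 5.0: 0.01, 25.0: 0.01})
        stitched = stitch_windows(curves)
        for s in stitched.meta["stitch_scales"].values():
            assert s == pytest.approx(1.0, abs=1e-9)
        # stitched trace equals the model piecewise on its own grid
        want = model_decay(m, InstrumentResponse(sigma=0.01, t0=0.05), stitched.times)
        np.testing.assert_allclose(stitched.counts, want, rtol=1e-9)

    def test_noiseless_default_windows_scales_near_unity(self):
        # the 5 -> 20 ns grids interleave, so the overlap is resampled by
        # interpolation; scale factors are 1 to interpolation accuracy only
        m = MultiExponentialModel.from_arrays([1000.0, 300.0], [0.4, 3.0])
        curves = self.windows(m, {1.0: 0.01, 5.0: 0.01, 20.0: 0.01})
        stitched = stitch_windows(curves)
        for s in stitched.meta["stitch_scales"].values():
            assert s == pytest.approx(1.0, abs=1e-3)

    def test_noiseless_per_window_sigma_piecewise_model(self):
        m = MultiExponentialModel.from_arrays([1000.0, 300.0], [0.4, 3.0])
        sig = {1.0: 0.01, 5.0: 0.05, 20.0: 0.2}
        stitched = stitch_windows(self.windows(m, sig))
        # each segment equals the model evaluated with its source-window sigma
        want = model_decay(m, InstrumentResponse(sigma=1.0, t0=0.05),
                           stitched.times, sigma=stitched.sigma_bins)
        scales = stitched.meta["stitch_scales"]
        bounds = {1.0: (0.0, 1.0), 5.0: (1.0, 5.0), 20.0: (5.0, 20.0)}
        for w, (lo, hi) in bounds.items():
            seg = (stitched.times > lo) & (stitched.times <= hi)
            np.testing.assert_allclose(stitched.counts[seg],
                                       want[seg] * scales[w], rtol=1e-9)
        # sigma differences between windows alter the overlap region (the
        # tail enhancement exp(sigma^2/2 tau^2) grows with sigma), so the
        # recovered scales absorb a systematic of a few percent
        for s in scales.values():
            assert s == pytest.approx(1.0, abs=0.1)

    def test_constructed_scaling_recovered(self):
        m = MultiExponentialModel.from_arrays([1000.0], [2.0])
        curves = self.windows(m, {1.0: 0.01, 5.0: 0.01}, scale_by_window={5.0: 2.0})
        stitched = stitch_windows(curves)
        assert stitched.meta["stitch_scales"][5.0] == pytest.approx(0.5, abs=1e-9)

    def test_poisson_round_trip_through_fit(self):
        m = MultiExponentialModel.from_arrays([1000.0], [4.19])
        rng = np.random.default_rng(21)
        curves = []
        for w, sig in {1.0: 0.01, 5.0: 0.05, 20.0: 0.2}.items():
            n = 500
            t = (np.arange(n) + 0.5) * (w / n)
            irf = InstrumentResponse(sigma=sig, t0=0.05)
            shape = model_decay(m, irf, t)
            expected = shape * (1e6 / shape.sum()) + 1.0
            curves.append(DecayCurve(times=t, counts=rng.poisson(expected).astype(float),
                                     window=w, propagation_time=0.5,
                                     sigma_bins=np.full(n, sig)))
        stitched = stitch_windows(curves)
        # per-bin sigma varies along the stitched trace; fit with fixed sigma
        # from the dominant early segment recovers the lifetime
        res = fit_decay(stitched, InstrumentResponse(sigma=0.05, t0=0.05),
                        max_components=2, n_starts=2, fit_sigma=False)
        assert res.model.lifetimes[-1] == pytest.approx(4.19, rel=0.10)

    def test_missing_window_errors(self):
        m = MultiExponentialModel.from_arrays([10.0], [1.0])
        (only,) = self.windows(m, {1.0: 0.01})
        with pytest.raises(StitchError):
            stitch_windows([only])

    def test_mismatched_propagation_time_errors(self):
        m = MultiExponentialModel.from_arrays([10.0], [1.0])
        c1, c5 = self.windows(m, {1.0: 0.01, 5.0: 0.05})
        c5.propagation_time = 9.0
        with pytest.raises(StitchError):
            stitch_windows([c1, c5])

    def test_sigma_scaling_with_window(self):
        assert sigma_for_window(1.0) == pytest.approx(0.010)
        assert sigma_for_window(20.0) == pytest.approx(0.200)
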