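import numpy as np
import pytest

from ribbonca import (
    RasterScan,
    SpatialProfileFit,
    TemporalTrace,
    compute_dff,
    define_region_windows,
    fit_biexponential_decay,
    fit_rise_sigmoid,
    fit_spatial_profile,
    max_influx_amplitude,
    ribbon_intensity_ratio,
)


PX = 0.02  # µm per pixel for the synthetic profiles


def _profile(b, c, d, x_half, a, x0, w, n=256):
    """Forward model with extracellular space at low x (d < 0 branch)."""
    x = np.arange(n) * PX
    s = b - c / (1.0 + np.exp((x_half - x) / d))
    return x, s + a * np.exp(-((x - x0) ** 2) / w**2)


class TestSpatialProfileFit:
    def test_pure_gaussian_on_flat_background_recovered_exactly(self):
        x = np.arange(256) * PX
        y = 10.0 + 150.0 * np.exp(-((x - 2.0) ** 2) / 0.23**2)
        fit = fit_spatial_profile(y, PX)
        assert fit.a == pytest.approx(150.0, rel=1e-6)
        assert fit.x0 == pytest.approx(2.0, abs=1e-6)
        assert fit.w == pytest.approx(0.23, rel=1e-6)
        assert "no-edge" in fit.flags  # c == 0: no membrane transition exists

    def test_generate_and_refit_localizes_membrane_and_ribbon(self):
        rng = np.random.default_rng(42)
        # membrane at 3.0 µm, emitter 0.2 µm inside, extracellular at high x
        _, clean = _profile(100, 80, 0.05, 3.0, 150, 2.8, 0.23)
        for _ in range(3):
            noisy = clean + rng.normal(0.0, 0.01 * clean.max(), clean.size)
            fit = fit_spatial_profile(noisy, PX, psf_fwhm=0.268)
            assert abs(fit.x_half - 3.0) < PX
            assert abs(fit.x0 - 2.8) < PX

    def test_flat_noise_is_flagged_low_amplitude(self):
        rng = np.random.default_rng(0)
        y = 100.0 + rng.normal(0, 1.0, 256)
        fit = fit_spatial_profile(y, PX)
        assert "low-amplitude" in fit.flags

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError):
            fit_spatial_profile(np.ones(10), PX)


class TestRegionWindows:
    def _fit(self, px_half, px0):
        return SpatialProfileFit(
            b=100, c=80, d=0.05, x_half=px_half * PX, a=50, x0=px0 * PX,
            w=0.2, residual=0.1, pixel_size=PX,
        )

    def test_window_placement_follows_the_five_pixel_convention(self):
        wins = define_region_windows(self._fit(40, 50), 5, 256)
        assert wins.proximal == (43, 48)  # pixels 43-47
        assert wins.distal == (51, 56)  # pixels 51-55
        assert wins.cytoplasmic == (56, 61)

    def test_narrow_gap_shrinks_proximal_to_minimum_three(self):
        wins = define_region_windows(self._fit(40, 44), 5, 256)
        start, stop = wins.proximal
        assert stop - start == 3

    @pytest.mark.parametrize("px0", [46, 50, 60, 80])
    def test_windows_never_overlap(self, px0):
        wins = define_region_windows(self._fit(40, px0), 5, 256)
        regions = sorted(wins.as_dict().values())
        for (s1, e1), (s2, e2) in zip(regions, regions[1:]):
            assert e1 <= s2

    def test_flagged_fit_rejected(self):
        bad = self._fit(40, 50)
        bad.flags.append("low-amplitude")
        with pytest.raises(ValueError, match="flagged"):
            define_region_windows(bad, 5, 256)

    def test_clipping_warns(self):
        with pytest.warns(UserWarning, match="clipped"):
            define_region_windows(self._fit(245, 252), 5, 256)


class TestDff:
    def _raster(self, ca):
        return RasterScan(
            marker=np.ones_like(ca), ca=ca, pixel_size=PX,
            stimulus_onset_line=10,
        )

    def _windows(self):
        return define_region_windows(
            SpatialProfileFit(100, 80, 0.05, 40 * PX, 50, 50 * PX, 0.2, 0.1, PX),
            5, 256,
        )

    def test_constant_raster_gives_zero_dff(self):
        traces = compute_dff(self._raster(np.full((256, 40), 7.0)), self._windows())
        for tr in traces.values():
            assert np.allclose(tr.dff, 0.0)
            assert tr.time[10] == 0.0  # onset line maps to t = 0

    def test_step_doubling_gives_unit_dff(self):
        ca = np.full((256, 40), 5.0)
        ca[:, 10:] = 10.0
        traces = compute_dff(self._raster(ca), self._windows())
        for tr in traces.values():
            assert np.allclose(tr.dff[:10], 0.0)
            assert np.allclose(tr.dff[10:], 1.0)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            compute_dff(self._raster(np.zeros((256, 40))), self._windows())


class TestRiseFit:
    def _trace(self, y, dt=3.02, onset=10):
        t = (np.arange(y.size) - onset) * dt
        return TemporalTrace(time=t, dff=y, region="proximal",
                             baseline_lines=(0, onset))

    def test_exact_logistic_recovered(self):
        t = (np.arange(60) - 10) * 3.02
        y = 2.5 / (1.0 + np.exp(-(t - 20.0) / 4.0))
        fit = fit_rise_sigmoid(self._trace(y))
        assert fit.amplitude == pytest.approx(2.5, rel=1e-3)
        assert fit.t_half == pytest.approx(20.0, abs=0.5)
        assert not fit.flags

    def test_noisy_plateau_recovered_at_20db(self):
        rng = np.random.default_rng(3)
        t = (np.arange(80) - 10) * 3.02
        clean = 2.0 / (1.0 + np.exp(-(t - 15.0) / 3.0))
        recovered = []
        for _ in range(5):
            y = clean + rng.normal(0, 0.2, t.size)  # 20 dB SNR
            fit = fit_rise_sigmoid(self._trace(y))
            recovered.append(fit.amplitude)
        assert np.mean(recovered) == pytest.approx(2.0, rel=0.05)

    def test_flat_trace_flagged_low_signal(self):
        fit = fit_rise_sigmoid(self._trace(np.zeros(50)))
        assert fit.amplitude == pytest.approx(0.0, abs=1e-9)
        assert "low-signal" in fit.flags

    def test_decreasing_trace_flagged(self):
        y = np.linspace(1.0, 0.0, 50)
        fit = fit_rise_sigmoid(self._trace(y))
        assert "no-rise" in fit.flags


class TestBiexponentialDecay:
    def _trace(self, taus, weights, f_peak=1.0, t_max=600.0, dt=3.02):
        t = np.arange(0.0, t_max, dt)
        y = f_peak * sum(
            w * np.exp(-t / tau) for w, tau in zip(weights, taus)
        )
        return TemporalTrace(time=t, dff=y, region="proximal",
                             baseline_lines=(0, 1))

    def test_single_exponential_degenerates_cleanly(self):
        trace = self._trace([50.0, 50.0], [0.7, 0.3])  # effectively one tau
        fit = fit_biexponential_decay(trace, restarts=20, seed=0)
        assert fit.a_fast + fit.a_slow == pytest.approx(100.0)
        # the dominant component carries >= 99% at tau within 2%
        tau_dom = fit.tau_fast if fit.a_fast >= fit.a_slow else fit.tau_slow
        a_dom = max(fit.a_fast, fit.a_slow)
        if a_dom < 99.0:  # weights split across two nearly equal taus
            assert fit.tau_fast == pytest.approx(50.0, rel=0.05)
            assert fit.tau_slow == pytest.approx(50.0, rel=0.25)
        else:
            assert tau_dom == pytest.approx(50.0, rel=0.02)
        assert "poorly-identified" in fit.flags

    def test_two_component_recovery_noiseless(self):
        trace = self._trace([10.0, 200.0], [0.6, 0.4])
        fit = fit_biexponential_decay(trace, restarts=30, seed=1)
        assert fit.tau_fast == pytest.approx(10.0, rel=0.05)
        assert fit.tau_slow == pytest.approx(200.0, rel=0.05)
        assert fit.a_fast == pytest.approx(60.0, rel=0.05)
        assert fit.a_slow == pytest.approx(40.0, rel=0.05)
        assert not fit.flags

    def test_restart_determinism(self):
        trace = self._trace([10.0, 200.0], [0.6, 0.4])
        f1 = fit_biexponential_decay(trace, restarts=10, seed=7)
        f2 = fit_biexponential_decay(trace, restarts=10, seed=7)
        assert (f1.tau_fast, f1.tau_slow, f1.a_fast) == (
            f2.tau_fast, f2.tau_slow, f2.a_fast,
        )

    def test_close_time_constants_are_flagged_not_silent(self):
        trace = self._trace([20.0, 40.0], [0.5, 0.5])  # ratio 2 < 3
        fit = fit_biexponential_decay(trace, restarts=20, seed=2)
        assert "poorly-identified" in fit.flags

    def test_short_record_rejected(self):
        trace = self._trace([10.0, 200.0], [0.6, 0.4], t_max=60.0)
        short = TemporalTrace(
            time=trace.time[:20], dff=trace.dff[:20], region="p",
            baseline_lines=(0, 1),
        )
        with pytest.raises(ValueError, match="post-peak"):
            fit_biexponential_decay(short, restarts=5, seed=0)


class TestFrameMetrics:
    def test_uniform_image_ratio_is_one(self):
        img = np.full((64, 64), 5.0)
        assert ribbon_intensity_ratio(img, (30, 30), offset=8) == pytest.approx(1.0)

    def test_peak_over_background_ratio(self):
        img = np.full((64, 64), 100.0)
        img[20, 20] = 300.0
        assert ribbon_intensity_ratio(img, (20, 20), offset=9) == pytest.approx(3.0)

    def test_reference_outside_mask_rejected(self):
        img = np.full((32, 32), 10.0)
        mask = np.zeros_like(img, dtype=bool)
        mask[10:15, 10:15] = True
        with pytest.raises(ValueError, match="mask"):
            ribbon_intensity_ratio(img, (12, 12), offset=8, mask=mask)

    def test_max_influx_no_change_is_zero(self):
        frames = np.full((6, 32, 32), 3.0)
        assert max_influx_amplitude(frames, 3) == pytest.approx(0.0)

    def test_max_influx_single_pixel_doubling(self):
        frames = np.ones((4, 32, 32))
        frames[2:, 16, 16] = 2.0
        # 3×3 window: (2 + 8×1)/9 over background 1
        assert max_influx_amplitude(frames, 2) == pytest.approx(1.0 / 9.0)

    def test_max_influx_requires_stimulus_frames(self):
        frames = np.ones((4, 32, 32))
        with pytest.raises(ValueError):
            max_influx_amplitude(frames, 4)


def test_ca_centroid_sits_between_membrane_and_marker_centroid(egta02_bundle):
    """During the pulse the Ca2+ bump is pulled toward the membrane."""
    from ribbonca.linescan import fit_spatial_profile

    raster = egta02_bundle.noiseless
    onset = raster.stimulus_onset_line
    marker_fit = fit_spatial_profile(
        raster.marker.mean(axis=1), raster.pixel_size, psf_fwhm=0.268
    )
    pulse_lines = raster.ca[:, onset + 1 : onset + 3]  # during depolarization
    ca_fit = fit_spatial_profile(
        pulse_lines.mean(axis=1), raster.pixel_size, psf_fwhm=0.268
    )
    assert marker_fit.x_half < ca_fit.x0 < marker_fit.x0
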