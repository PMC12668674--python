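import numpy as np
import pytest

from ribbonca import (
    CAL520_HA,
    CAL520_LA,
    DyeSpec,
    OpticalModel,
    Probe,
    SimulationConfig,
    add_photon_noise,
    blur_with_psf,
    build_domain,
    render_fluorescence,
    simulate_dye_response,
)
from ribbonca.linescan import RasterScan
from ribbonca.solver import FieldMovie

from conftest import no_ribbon_geometry


def _uniform_movie(ca_values, times, shape=(8, 8, 8)):
    """A FieldMovie with spatially uniform [Ca2+] per frame."""
    cfg = SimulationConfig(
        box_dims=tuple(s * 0.04 for s in shape),
        grid_spacing=0.04,
        ribbon=no_ribbon_geometry(),
        probes=[Probe("p", (0.0, 0.0, 0.02))],
    )
    grid = build_domain(cfg)
    fields = np.stack([np.full(shape, c) for c in ca_values])
    return FieldMovie(times=np.asarray(times, float), fields=fields, grid=grid)


class TestDyeResponse:
    def test_equilibrium_at_kd_is_half_occupancy(self):
        dye = CAL520_LA()
        movie = _uniform_movie([dye.kd] * 5, np.arange(5.0))
        bound = simulate_dye_response(movie, dye)
        assert np.allclose(bound / dye.total, 0.5, atol=1e-9)

    def test_step_relaxation_follows_scalar_ode(self):
        """Occupancy relaxes at rate k_on·C + k_off after a [Ca2+] step."""
        dye = DyeSpec("toy", kd=1.0, on_rate=0.1, total=10.0)
        c_lo, c_hi = 0.1, 10.0
        times = np.linspace(0.0, 8.0, 33)
        ca = np.where(times > 0, c_hi, c_lo)
        movie = _uniform_movie(ca, times)
        bound = simulate_dye_response(movie, dye)[:, 0, 0, 0]
        rate = dye.on_rate * c_hi + dye.off_rate
        eq_lo = dye.total * c_lo / (c_lo + dye.kd)
        eq_hi = dye.total * c_hi / (c_hi + dye.kd)
        expected = eq_hi + (eq_lo - eq_hi) * np.exp(-rate * np.clip(times, 0, None))
        assert np.allclose(bound[1:], expected[1:], rtol=1e-6)

    def test_low_affinity_dye_decays_faster_after_pulse(self):
        """Fast unbinding makes the low-affinity readout track the decay."""
        times = np.arange(0.0, 40.0, 0.5)
        ca = np.where((times >= 2.0) & (times < 12.0), 20.0, 0.1)  # 10 ms pulse
        movie = _uniform_movie(ca, times)
        half_times = {}
        for dye in (CAL520_HA("ribbon-bound"), CAL520_LA("ribbon-bound")):
            occ = simulate_dye_response(movie, dye)[:, 0, 0, 0] / dye.total
            dff = occ / occ[0] - 1.0
            assert dff.max() > 0.5  # the pulse is clearly visible
            post = times >= 12.0
            peak = dff[post][0]
            below = np.flatnonzero(dff[post] <= peak / 2.0)
            half_times[dye.name] = times[post][below[0]] - 12.0 if below.size else np.inf
        assert half_times["Cal520LA"] < half_times["Cal520HA"]


class TestFluorescence:
    def test_fluorescence_rendering_is_affine_in_occupancy(self):
        dye = CAL520_LA()
        zero = render_fluorescence(np.zeros((2, 2, 2)), dye, brightness=2.0)
        full = render_fluorescence(np.full((2, 2, 2), dye.total), dye, brightness=2.0)
        half = render_fluorescence(np.full((2, 2, 2), dye.total / 2), dye, brightness=2.0)
        assert np.allclose(zero, 2.0)
        assert np.allclose(full, 2.0 * dye.dynamic_range)
        assert np.allclose(half, (zero + full) / 2.0)

    def test_out_of_range_occupancy_rejected(self):
        dye = CAL520_LA()
        with pytest.raises(ValueError):
            render_fluorescence(np.full((2, 2, 2), 2 * dye.total), dye)


class TestPsfBlur:
    def test_point_emitter_blurred_to_psf_fwhm(self):
        h = 0.02
        vol = np.zeros((129, 65, 65))
        vol[64, 32, 32] = 1.0
        optics = OpticalModel()
        out = blur_with_psf(vol, optics, h)
        prof = out[:, 32, 32]
        half = prof.max() / 2.0
        above = np.flatnonzero(prof >= half)
        fwhm = (above[-1] - above[0] + 1) * h  # ± half-pixel quantization
        assert fwhm == pytest.approx(optics.fwhm_x, abs=2 * h)

    def test_uniform_field_unchanged(self):
        out = blur_with_psf(np.full((32, 32, 32), 3.3), OpticalModel(), 0.02)
        assert np.allclose(out, 3.3, rtol=1e-12)

    def test_interior_emitter_intensity_conserved(self):
        # > 5 sigma of clearance to every face, including the wide axial axis
        vol = np.zeros((64, 64, 144))
        vol[32, 32, 72] = 7.0
        out = blur_with_psf(vol, OpticalModel(), 0.02, mode="constant")
        assert out.sum() == pytest.approx(7.0, rel=1e-6)

    def test_undersampled_grid_rejected(self):
        with pytest.raises(ValueError, match="undersample"):
            blur_with_psf(np.zeros((16, 16, 16)), OpticalModel(), 0.2)


class TestPhotonNoise:
    def _raster(self, value=10.0):
        img = np.full((64, 30), value)
        return RasterScan(marker=img, ca=img.copy(), pixel_size=0.01,
                          stimulus_onset_line=10)

    def test_same_seed_reproduces_exactly(self):
        r = self._raster()
        n1 = add_photon_noise(r, 50.0, seed=11)
        n2 = add_photon_noise(r, 50.0, seed=11)
        assert np.array_equal(n1.ca, n2.ca)
        assert np.array_equal(n1.marker, n2.marker)

    def test_variance_matches_mean_poisson_statistics(self):
        budget = 40.0
        r = self._raster(value=1.0)  # baseline == 1 -> scale == budget
        counts = []
        for seed in range(1000):
            noisy = add_photon_noise(r, budget, seed=seed)
            counts.append(noisy.ca[0, 0] * budget)
        counts = np.asarray(counts)
        assert counts.var() == pytest.approx(counts.mean(), rel=0.05)

    def test_large_budget_recovers_noiseless(self):
        r = self._raster()
        noisy = add_photon_noise(r, 1e8, seed=0)
        assert np.allclose(noisy.ca, r.ca, rtol=1e-3)


class TestLinescanRendering:
    def test_static_field_renders_identical_lines(self, egta02_bundle):
        marker = egta02_bundle.noiseless.marker
        assert np.allclose(marker, marker[:, :1])

    def test_channel_interleave_timing(self, egta02_bundle):
        raster = egta02_bundle.noiseless
        assert raster.line_period == pytest.approx(1.51)
        assert raster.same_channel_period == pytest.approx(3.02)
        times = raster.line_times()
        assert np.allclose(np.diff(times), 3.02)

    def test_marker_fit_recovers_generator_truth_within_one_pixel(
        self, egta02_bundle
    ):
        from ribbonca.linescan import fit_spatial_profile

        raster = egta02_bundle.noiseless
        truth = egta02_bundle.truth
        fit = fit_spatial_profile(
            raster.marker.mean(axis=1), raster.pixel_size, psf_fwhm=0.268
        )
        assert abs(fit.x_half - truth.membrane_pos) <= truth.pixel_size
        assert abs(fit.x0 - truth.ribbon_centroid_pos) <= truth.pixel_size
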