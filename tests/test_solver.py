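import numpy as np
import pytest

from ribbonca import (
    ExtrusionSpec,
    Probe,
    SimulationConfig,
    boundary_flux,
    buffer_equilibrium,
    endogenous_buffer,
    linear_steady_oracle,
    resting_leak,
    run_simulation,
    slice_field,
    source_strength,
)
from ribbonca.config import BufferSpec, ChannelClusterLayout, SurfaceExtrusion

from conftest import coarse_config, no_ribbon_geometry


# ---------------------------------------------------------------------------
# closed-form pieces


@pytest.mark.parametrize(
    "current,fraction,expected",
    [
        (0.0, 0.25, 0.0),
        # 1 pA of divalent ions: 1e-15 C/ms / (2 × 1.602177e-19 C) ≈ 3121/ms
        (1.0, 1.0, 3120.76),
        (1.0, 0.25, 780.19),
    ],
)
def test_source_strength_matches_charge_arithmetic(current, fraction, expected):
    assert source_strength(current, fraction) == pytest.approx(expected, rel=1e-4)


def test_source_strength_rejects_bad_inputs():
    with pytest.raises(ValueError):
        source_strength(-1.0, 0.5)
    with pytest.raises(ValueError):
        source_strength(1.0, 1.5)


def test_resting_leak_closed_form():
    spec = SurfaceExtrusion(
        exchanger_rate=1.0, exchanger_affinity=10.0,
        pump_rate=0.0, pump_affinity=0.2, hill_coefficient=1,
    )
    assert resting_leak(spec, 0.1) == pytest.approx(0.1 / 10.1)
    zero = SurfaceExtrusion(0.0, 10.0, 0.0, 0.2, 1)
    assert resting_leak(zero, 0.1) == 0.0


def test_boundary_flux_zero_at_rest_and_saturates():
    spec = SurfaceExtrusion(2.0, 1.0, 1.0, 0.5, 2)
    c0 = 0.1
    assert boundary_flux(c0, spec, c0) == pytest.approx(0.0, abs=1e-15)
    sat = boundary_flux(1e9, spec, c0)
    leak = resting_leak(spec, c0)
    assert sat == pytest.approx(2.0 + 1.0 - leak, rel=1e-6)
    # hand evaluation at C=0.5: (2·0.5/1.5 + 0.25/0.5) − (0.2/1.1 + 0.01/0.26)
    assert boundary_flux(0.5, spec, c0) == pytest.approx(0.9463870, rel=1e-6)


def test_buffer_equilibrium_examples():
    spec = BufferSpec("b", 1440.0, 2.0, 0.1)
    free, bound = buffer_equilibrium(spec, 2.0)
    assert bound == pytest.approx(720.0)
    assert free + bound == pytest.approx(1440.0)
    assert buffer_equilibrium(spec, 0.0)[1] == 0.0
    assert buffer_equilibrium(spec, 0.1)[1] == pytest.approx(68.5714, rel=1e-4)


def test_linear_steady_oracle_closed_form():
    assert linear_steady_oracle(0.1, 0.0, 0.22, 0.1) == pytest.approx(0.1)
    # σ/(2πDr) ions/µm³ → µM: 3121/(2π·0.22·0.1)/602.2 + 0.1
    assert linear_steady_oracle(0.1, 3121.0, 0.22, 0.1) == pytest.approx(37.6, abs=0.1)
    ex1 = linear_steady_oracle(0.1, 3121.0, 0.22, 0.1) - 0.1
    ex2 = linear_steady_oracle(0.2, 3121.0, 0.22, 0.1) - 0.1
    assert ex1 == pytest.approx(2.0 * ex2, rel=1e-12)
    with pytest.raises(ValueError):
        linear_steady_oracle(0.0, 1.0, 0.22, 0.1)


# ---------------------------------------------------------------------------
# full runs (small/coarse domains keep these at the seconds scale)


def _small_config(**kwargs):
    defaults = dict(
        box_dims=(0.64, 0.64, 0.6),
        grid_spacing=0.04,
        ribbon=no_ribbon_geometry(),
        probes=[Probe("near", (0.02, 0.0, 0.01)), Probe("far", (0.2, 0.0, 0.3))],
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


def test_zero_current_stays_at_rest():
    cfg = _small_config(total_current=0.0, duration=20.0)
    series = run_simulation(cfg)
    for trace in series.traces.values():
        assert np.max(np.abs(trace - 0.1)) < 1e-3


def test_resting_fixed_point_with_leak_balance():
    """The leak term must exactly cancel extrusion at C0 (no drift)."""
    cfg = _small_config(
        total_current=0.0,
        duration=20.0,
        extrusion=ExtrusionSpec(
            bottom=SurfaceExtrusion(0.5, 5.0, 0.1, 0.2, 1),
            other=SurfaceExtrusion(0.5, 5.0, 0.1, 0.2, 2),
        ),
    )
    series = run_simulation(cfg)
    for trace in series.traces.values():
        assert np.max(np.abs(trace - 0.1)) < 1e-3


def test_mass_conservation_in_sealed_box():
    """Free + bound Ca2+ must track the injected charge to 1%."""
    cfg = _small_config(
        buffers=[endogenous_buffer(200.0)],
        extrusion=ExtrusionSpec.disabled(),
        pulse_duration=2.0,
        duration=3.0,
    )
    series = run_simulation(cfg)
    grid = series.grid
    state = series.final_state
    vol = grid.voxel_volume
    total = (state["ca"].sum() + sum(b.sum() for b in state["bound"])) * vol
    free0, bound0 = buffer_equilibrium(cfg.buffers[0], cfg.resting_ca)
    initial = (cfg.resting_ca + bound0) * grid.n_free * vol
    injected = series.total_influx_rate_um3 * cfg.pulse_duration
    assert total - initial == pytest.approx(injected, rel=0.01)


def test_buffer_free_field_matches_linear_oracle(point_source_run):
    """Sim vs half-space point-source closed form within 15% at 50-200 nm."""
    radii, series = point_source_run
    sigma = source_strength(1.0, 1.0)
    for r in radii:
        got = series.traces[f"r{r}"][-1]
        expected = linear_steady_oracle(r, sigma, 0.22, 0.1)
        assert got == pytest.approx(expected, rel=0.15)


def test_probe_inside_obstacle_rejected():
    cfg = SimulationConfig(
        grid_spacing=0.03,
        box_dims=(1.29, 1.29, 1.11),
        probes=[Probe("inside", (0.0, 0.0, 0.22))],  # ellipsoid centre
        duration=0.1,
    )
    with pytest.raises(ValueError, match="obstacle"):
        run_simulation(cfg)


def test_slice_snapshots_symmetry_and_source_location():
    cfg = coarse_config(
        buffers=[endogenous_buffer()],
        pulse_duration=1.0,
        duration=1.0,
        sample_interval=0.5,
    )
    series = run_simulation(cfg, snapshot_times=(0.0, 1.0))
    before = slice_field(series, 0.0)
    inside = ~np.isnan(before)
    assert np.allclose(before[inside], 0.1, atol=1e-6)

    end = slice_field(series, 1.0)
    # the hottest pixel sits on the bottom boundary next to a cluster
    flat = np.nanargmax(end)
    ix, iz = np.unravel_index(flat, end.shape)
    assert iz == 0
    h = series.grid.spacing
    cluster_x = [(c[0][0] + 0.5) * h for c in series.grid.source_cells]
    assert min(abs((ix + 0.5) * h - x) for x in cluster_x) <= h

    # mirror symmetry of the symmetric default layout
    mirrored = end[::-1, :]
    peak = np.nanmax(end)
    asym = np.nanmax(np.abs(end - mirrored))
    assert asym < 0.01 * peak

    with pytest.raises(KeyError, match="available"):
        slice_field(series, 0.123)


def test_grid_refinement_changes_peak_by_less_than_ten_percent():
    peaks = {}
    for h in (0.02, 0.01):
        cfg = SimulationConfig(
            buffers=[endogenous_buffer()],
            grid_spacing=h,
            pulse_duration=1.2,
            duration=1.2,
        )
        peaks[h] = run_simulation(cfg).peak("proximal")
    assert peaks[0.01] == pytest.approx(peaks[0.02], rel=0.10)


def test_immobile_buffer_concentration_is_a_weak_lever(immobile_buffer_peaks):
    """A 7.2-fold rise in immobile buffer moves the proximal peak < 25%."""
    low = immobile_buffer_peaks["200uM"]
    high = immobile_buffer_peaks["1.44mM"]
    assert abs(high - low) / low < 0.25


def test_chelator_strength_orders_signal_localization(localization_snapshots):
    """Spatial extent above 5 µM: 0.2 mM EGTA ≥ 10 mM EGTA ≥ 2 mM BAPTA."""
    extents = {
        name: int(np.sum(np.nan_to_num(img) > 5.0))
        for name, img in localization_snapshots.items()
    }
    assert extents["egta-0.2"] >= extents["egta-10"] >= extents["bapta-2"]
    assert extents["bapta-2"] >= 1  # the microdomain core survives BAPTA
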