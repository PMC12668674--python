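"""Shared fixtures.

Expensive simulations are session-scoped and reused by the module tests
and the acceptance suite: a full-resolution run costs tens of seconds and
several properties can be read off the same fields.
"""

from __future__ import annotations

import numpy as np
import pytest

from ribbonca import (
    ExtrusionSpec,
    Probe,
    RibbonGeometry,
    SimulationConfig,
    egta,
    endogenous_buffer,
    generate_fixture,
    run_simulation,
)
from ribbonca.config import ChannelClusterLayout, bapta


def no_ribbon_geometry() -> RibbonGeometry:
    return RibbonGeometry(0.0, 0.0, 0.0, (0.0, 0.0, 0.0))


def coarse_config(**kwargs) -> SimulationConfig:
    """Desk-scale configuration: full box, 30 nm grid, 20 µs step."""
    defaults = dict(
        grid_spacing=0.03,
        box_dims=(1.29, 1.29, 1.11),
        time_step=0.02,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def egta02_bundle():
    """Synthetic fixture for the reference condition (noise seed 1)."""
    return generate_fixture("egta-0.2", seed=1)


@pytest.fixture(scope="session")
def point_source_run():
    """Buffer-free run with one centred source: the linear-oracle regime.

    Sampled at 1 ms, inside the quasi-steady window of the closed box
    (late enough for the near field to equilibrate, early enough that
    boundary accumulation stays small).
    """
    radii = (0.05, 0.1, 0.15, 0.2)
    cfg = SimulationConfig(
        buffers=[],
        ribbon=no_ribbon_geometry(),
        clusters=ChannelClusterLayout(side_length=0.0, current_fractions=(1.0,)),
        extrusion=ExtrusionSpec.disabled(),
        probes=[Probe(f"r{r}", (r, 0.0, 0.01)) for r in radii],
        pulse_duration=1.0,
        duration=1.0,
    )
    return radii, run_simulation(cfg)


@pytest.fixture(scope="session")
def localization_snapshots():
    """Mid-plane [Ca2+] slices at pulse end for the three chelator loads."""
    out = {}
    for name, bufs in [
        ("egta-0.2", [endogenous_buffer(), egta(200.0)]),
        ("egta-10", [endogenous_buffer(), egta(10000.0)]),
        ("bapta-2", [endogenous_buffer(), bapta(2000.0)]),
    ]:
        cfg = coarse_config(buffers=bufs, pulse_duration=10.0, duration=10.0)
        series = run_simulation(cfg, snapshot_times=(10.0,))
        out[name] = series.snapshots[10.0]
    return out


@pytest.fixture(scope="session")
def immobile_buffer_peaks():
    """Peak proximal [Ca2+] at low vs high immobile-buffer concentration."""
    peaks = {}
    for label, total in [("200uM", 200.0), ("1.44mM", 1440.0)]:
        cfg = coarse_config(
            buffers=[endogenous_buffer(total)], pulse_duration=4.0, duration=4.0
        )
        peaks[label] = run_simulation(cfg).peak("proximal")
    return peaks


@pytest.fixture(scope="session")
def recovery_replicates(egta02_bundle):
    """Twenty noise replicates of the reference fixture, fitted."""
    from ribbonca.imaging import add_photon_noise
    from ribbonca.pipeline import analyze_raster

    results = []
    for seed in range(20):
        noisy = add_photon_noise(egta02_bundle.noiseless, 50.0, seed=seed)
        _, _, traces, _ = analyze_raster(
            noisy, baseline_lines=noisy.stimulus_onset_line
        )
        results.append({region: tr.peak for region, tr in traces.items()})
    return results
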