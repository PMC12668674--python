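"""Named synthetic-imaging scenarios with known ground truth.

Each scenario fixes the buffering condition and indicator of one study
condition and runs the full generative chain: reaction–diffusion
simulation → indicator binding → fluorescence → PSF blur → interleaved
two-channel line scan → Poisson noise.  The result bundles the noisy
raster with the noiseless ground truth, so fitting-pipeline recovery can
be scored without any recorded microscope data.

Scenario simulations default to a 30 nm grid and a 20 µs step — coarser
than the headline simulations but resolving every geometry feature — to
keep a full fixture generation at the tens-of-seconds scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import SimulationConfig, bapta, egta, endogenous_buffer
from .imaging import (
    CAL520_HA,
    CAL520_LA,
    DyeSpec,
    GroundTruth,
    OpticalModel,
    ScanGeometry,
    add_photon_noise,
    render_fluorescence,
    render_linescan,
    simulate_dye_response,
)
from .linescan import RasterScan, compute_dff, define_region_windows, fit_spatial_profile
from .solver import run_simulation

__all__ = ["Scenario", "SCENARIOS", "generate_fixture", "FixtureBundle"]


def _scenario_config(buffers, total_current=1.0) -> SimulationConfig:
    return SimulationConfig(
        buffers=buffers,
        total_current=total_current,
        grid_spacing=0.03,
        box_dims=(1.29, 1.29, 1.11),
        time_step=0.02,
        pulse_duration=10.0,
        duration=20.0,
    )


@dataclass
class Scenario:
    """One named study condition for the synthetic-imaging generator."""

    name: str
    config: SimulationConfig
    dye: DyeSpec
    description: str = ""
    n_lines: int = 28
    pre_lines: int = 12
    photons_per_baseline: float = 50.0


def _make_scenarios() -> dict[str, Scenario]:
    lp = {}

    def add(name, buffers, dye, description, **kw):
        lp[name] = Scenario(
            name=name,
            config=_scenario_config(buffers, **kw.pop("config_kwargs", {})),
            dye=dye,
            description=description,
            **kw,
        )

    add(
        "flat-control",
        [endogenous_buffer()],
        CAL520_LA("ribbon-bound"),
        "zero-current control: every trace stays at baseline",
        config_kwargs={"total_current": 0.0},
    )
    add(
        "egta-0.2",
        [endogenous_buffer(), egta(200.0)],
        CAL520_LA("ribbon-bound"),
        "reference condition: 1.44 mM immobile buffer + 0.2 mM EGTA, "
        "low-affinity ribbon-bound indicator",
    )
    add(
        "egta-10",
        [endogenous_buffer(), egta(10000.0)],
        CAL520_LA("ribbon-bound"),
        "10 mM EGTA: slow chelator at high concentration",
    )
    add(
        "bapta-2",
        [endogenous_buffer(), bapta(2000.0)],
        CAL520_LA("ribbon-bound"),
        "2 mM BAPTA: fast chelator, signal confined to the ribbon base",
    )
    add(
        "bapta-2-free-dye",
        [endogenous_buffer(), bapta(2000.0)],
        CAL520_LA("free"),
        "2 mM BAPTA read out with the freely diffusing indicator",
    )
    add(
        "egta-0.2-ha",
        [endogenous_buffer(), egta(200.0)],
        CAL520_HA("ribbon-bound"),
        "reference condition with the high-affinity indicator",
    )
    return lp


SCENARIOS: dict[str, Scenario] = _make_scenarios()


@dataclass
class FixtureBundle:
    """A generated raster plus its paired ground truth."""

    scenario: str
    raster: RasterScan  # noisy
    noiseless: RasterScan
    truth: GroundTruth
    seed: int

    def write(self, out_dir: str | Path) -> Path:
        from .io import write_raster

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        stem = out_dir / self.scenario
        write_raster(self.raster, stem, fmt="tiff")
        write_raster(
            self.noiseless, out_dir / f"{self.scenario}-noiseless", fmt="csv"
        )
        import json
        from dataclasses import asdict

        truth_path = out_dir / f"{self.scenario}-truth.json"
        truth_path.write_text(json.dumps(asdict(self.truth), indent=2, default=float))
        return truth_path


def generate_fixture(
    name: str,
    seed: int = 0,
    optics: OpticalModel | None = None,
    geometry: ScanGeometry | None = None,
    out_dir: str | Path | None = None,
) -> FixtureBundle:
    """Run a named scenario end to end and return (optionally write) it.

    The seed controls only the photon noise; the simulation and rendering
    are deterministic, so the noiseless raster and ground truth depend on
    the scenario alone.
    """
    if name not in SCENARIOS:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        )
    sc = SCENARIOS[name]
    optics = optics or OpticalModel()
    geometry = geometry or ScanGeometry()

    series = run_simulation(sc.config, store_fields=True, field_interval=0.5)
    movie = series.movie
    bound = simulate_dye_response(movie, sc.dye)
    fluor = render_fluorescence(bound, sc.dye)
    fluor[:, ~movie.grid.free_mask] = 0.0
    noiseless, truth = render_linescan(
        fluor,
        movie,
        geometry,
        optics,
        n_lines=sc.n_lines,
        pre_lines=sc.pre_lines,
        dye_name=sc.dye.name,
    )
    truth.seed = seed
    truth.peak_ca = {k: float(np.max(v)) for k, v in series.traces.items()}
    truth.peak_dff = _noiseless_region_peaks(noiseless, optics)
    truth.extras["scenario"] = name
    noisy = add_photon_noise(noiseless, sc.photons_per_baseline, seed=seed)
    bundle = FixtureBundle(
        scenario=name, raster=noisy, noiseless=noiseless, truth=truth, seed=seed
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


def _noiseless_region_peaks(raster: RasterScan, optics: OpticalModel) -> dict:
    """Region peak ΔF/F_rest of the noiseless rendering.

    Uses the same marker-fit → window → ΔF/F chain the analysis pipeline
    applies, evaluated without noise: this is the amplitude a perfect
    (noise-free) measurement of this raster would report.
    """
    profile = raster.marker.mean(axis=1)
    fit = fit_spatial_profile(profile, raster.pixel_size, psf_fwhm=optics.fwhm_x)
    if fit.flags:
        return {}
    windows = define_region_windows(fit, 5, raster.n_pixels)
    traces = compute_dff(raster, windows)
    return {region: tr.peak for region, tr in traces.items()}
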