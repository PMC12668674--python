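"""End-to-end recovery driver: generate a synthetic scan, fit it, score it.

``recover`` is the round-trip harness used for validation: it renders a
named scenario with a known ground truth, runs the full fitting pipeline
(marker-profile fit → region windows → ΔF/F traces → rise fit) on the
noisy raster, and reports whether the fitted quantities recover the
generator's truth within stated tolerances.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .imaging import OpticalModel
from .linescan import (
    RasterScan,
    compute_dff,
    define_region_windows,
    fit_rise_sigmoid,
    fit_spatial_profile,
)
from .scenarios import FixtureBundle, generate_fixture

__all__ = ["RecoveryReport", "analyze_raster", "recover"]

#: relative tolerance on the proximal-amplitude round trip
AMPLITUDE_RTOL = 0.15
#: absolute ΔF/F_rest floor below which a trace counts as flat
FLAT_ATOL = 0.05


@dataclass
class RecoveryReport:
    scenario: str
    seed: int
    fitted_x_half: float
    fitted_x0: float
    true_membrane: float
    true_centroid: float
    fitted_peaks: dict[str, float]
    true_peaks: dict[str, float]
    proximal_error: float | None
    proximal_exceeds_distal: bool
    passed: bool
    notes: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2))
        return path


def analyze_raster(
    raster: RasterScan,
    optics: OpticalModel | None = None,
    window_width: int = 5,
    baseline_lines: int = 20,
):
    """Run the standard fitting chain on one two-channel raster.

    Returns (marker_fit, windows, traces, rise_fits).
    """
    optics = optics or OpticalModel()
    profile = raster.marker.mean(axis=1)
    marker_fit = fit_spatial_profile(
        profile, raster.pixel_size, psf_fwhm=optics.fwhm_x
    )
    windows = define_region_windows(marker_fit, window_width, raster.n_pixels)
    traces = compute_dff(raster, windows, baseline_lines=baseline_lines)
    rises = {region: fit_rise_sigmoid(tr) for region, tr in traces.items()}
    return marker_fit, windows, traces, rises


def recover(
    scenario: str,
    seed: int = 0,
    bundle: FixtureBundle | None = None,
    out: str | Path | None = None,
) -> RecoveryReport:
    """Synthesize (or reuse) a fixture, fit it, and score the round trip.

    For a stimulated scenario the report passes when the fitted proximal
    peak ΔF/F_rest is within ``AMPLITUDE_RTOL`` of the generator's
    noiseless value and the proximal peak exceeds the distal peak; for
    the flat control it passes when all region amplitudes are ≈ 0.
    """
    if bundle is None:
        bundle = generate_fixture(scenario, seed=seed)
    truth = bundle.truth
    marker_fit, windows, traces, rises = analyze_raster(
        bundle.raster, baseline_lines=bundle.raster.stimulus_onset_line
    )
    fitted_peaks = {region: tr.peak for region, tr in traces.items()}
    notes: list[str] = []

    flat = all(abs(v) < FLAT_ATOL for v in truth.peak_dff.values()) if (
        truth.peak_dff
    ) else False
    prox_err = None
    prox_gt_dist = fitted_peaks.get("proximal", np.nan) > fitted_peaks.get(
        "distal", np.nan
    )
    if flat:
        # amplitudes must stay within the photon-noise floor: compare each
        # region's post-onset peak against its own pre-onset fluctuations
        passed = True
        for region, tr in traces.items():
            pre = tr.dff[tr.time < 0]
            noise = float(np.std(pre)) if pre.size else 0.0
            bound = max(4.0 * noise, FLAT_ATOL)
            if abs(fitted_peaks[region]) > bound:
                passed = False
                notes.append(
                    f"flat control: {region} amplitude "
                    f"{fitted_peaks[region]:.3f} exceeds noise bound {bound:.3f}"
                )
    else:
        true_prox = truth.peak_dff.get("proximal")
        if true_prox is None:
            passed = False
            notes.append("ground truth lacks a proximal amplitude")
        else:
            prox_err = abs(fitted_peaks["proximal"] - true_prox) / abs(true_prox)
            passed = prox_err <= AMPLITUDE_RTOL and bool(prox_gt_dist)
            if prox_err > AMPLITUDE_RTOL:
                notes.append(
                    f"proximal amplitude error {prox_err:.1%} exceeds "
                    f"{AMPLITUDE_RTOL:.0%}"
                )
            if not prox_gt_dist:
                notes.append("proximal does not exceed distal")

    report = RecoveryReport(
        scenario=bundle.scenario,
        seed=seed,
        fitted_x_half=marker_fit.x_half,
        fitted_x0=marker_fit.x0,
        true_membrane=truth.membrane_pos,
        true_centroid=truth.ribbon_centroid_pos,
        fitted_peaks=fitted_peaks,
        true_peaks=dict(truth.peak_dff),
        proximal_error=prox_err,
        proximal_exceeds_distal=bool(prox_gt_dist),
        passed=bool(passed),
        notes=notes,
    )
    if out is not None:
        report.write(out)
    return report
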