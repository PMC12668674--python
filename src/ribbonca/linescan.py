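"""Fitting of dual-channel x-t line scans at ribbon synapses.

A scan raster holds two channels sampled alternately along one spatial
line crossing the plasma membrane: a ribbon-marker channel (fluorescent
ribbon-binding peptide) and a Ca2+-indicator channel.  The spatial
profile of each line is modelled as a cell-edge sigmoid plus a Gaussian
emitter,

    f(x) = s(x) + g(x),   g(x) = a · exp(−(x − x0)² / w²),

where ``x_half`` (the sigmoid midpoint) localizes the plasma membrane and
``x0`` the ribbon centroid, and ``w`` is √2 times the Gaussian SD, in
practice pinned near the microscope PSF.  The sigmoid is the saturating
form s(x) = b − c/(1 + exp((x_half − x)/d)); both signs of the slope ``d``
are explored and the lower-residual branch kept, so either scan
orientation fits.  Windows of five pixels between the membrane and the
ribbon centroid (proximal), just past the centroid (distal), and beyond
(cytoplasmic) yield ΔF/F_rest traces whose rise is fit by a logistic and
whose decay by a bi-exponential found by repeated differential-evolution
global optimization.

Pixel indexing is 0-based; positions are reported in µm from the first
scanned pixel.  The window conventions assume the scan is oriented with
the extracellular space at low pixel index and the cytoplasm at high
index (``x_half < x0``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import differential_evolution, least_squares

__all__ = [
    "RasterScan",
    "SpatialProfileFit",
    "RegionWindows",
    "TemporalTrace",
    "RiseFit",
    "DecayFit",
    "fit_spatial_profile",
    "define_region_windows",
    "compute_dff",
    "fit_rise_sigmoid",
    "fit_biexponential_decay",
    "ribbon_intensity_ratio",
    "max_influx_amplitude",
]

_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548


@dataclass
class RasterScan:
    """Two-channel x-t raster with scan metadata.

    ``marker`` and ``ca`` are indexed ``[x_pixel, line]``.  ``line_period``
    is the time per line for ONE channel; with two interleaved channels,
    consecutive same-channel lines are ``2 * line_period`` apart.
    """

    marker: np.ndarray
    ca: np.ndarray
    pixel_size: float  # µm
    line_period: float = 1.51  # ms per line per channel
    stimulus_onset_line: int = 0
    n_channels: int = 2
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.marker = np.asarray(self.marker, dtype=float)
        self.ca = np.asarray(self.ca, dtype=float)
        if self.marker.shape != self.ca.shape:
            raise ValueError("marker and ca channels must have the same shape")
        if self.pixel_size <= 0 or self.line_period <= 0:
            raise ValueError("pixel_size and line_period must be positive")
        if not 0 <= self.stimulus_onset_line < self.n_lines:
            raise ValueError("stimulus onset must lie within the scan")

    @property
    def n_pixels(self) -> int:
        return self.marker.shape[0]

    @property
    def n_lines(self) -> int:
        return self.marker.shape[1]

    @property
    def same_channel_period(self) -> float:
        return self.line_period * self.n_channels

    def line_times(self) -> np.ndarray:
        """Times of the Ca-channel lines (ms) relative to stimulus onset."""
        idx = np.arange(self.n_lines) - self.stimulus_onset_line
        return idx * self.same_channel_period


@dataclass
class SpatialProfileFit:
    """Parameters of the membrane-sigmoid + ribbon-Gaussian spatial model."""

    b: float  # intracellular background
    c: float  # drop to the extracellular background
    d: float  # sigmoid slope scale (µm, signed)
    x_half: float  # membrane position (µm from first pixel)
    a: float  # emitter peak amplitude
    x0: float  # emitter centroid (µm)
    w: float  # Gaussian width, √2 × SD (µm)
    residual: float  # RMS of the fit residual
    pixel_size: float
    flags: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.flags

    @property
    def x_half_px(self) -> float:
        return self.x_half / self.pixel_size

    @property
    def x0_px(self) -> float:
        return self.x0 / self.pixel_size

    def model(self, x: np.ndarray) -> np.ndarray:
        return _sigmoid_gaussian(
            x, self.b, self.c, self.d, self.x_half, self.a, self.x0, self.w
        )


def _sigmoid_gaussian(x, b, c, d, x_half, a, x0, w):
    s = b - c / (1.0 + np.exp(np.clip((x_half - x) / d, -500, 500)))
    g = a * np.exp(-((x - x0) ** 2) / w**2)
    return s + g


def fit_spatial_profile(
    profile: np.ndarray,
    pixel_size: float,
    psf_fwhm: float | None = None,
) -> SpatialProfileFit:
    """Fit one x-axis intensity profile with the Sigmoid-Gaussian model.

    Parameters
    ----------
    profile
        Intensity per pixel along the scanned line (≥ 20 pixels spanning
        both backgrounds).
    pixel_size
        µm per pixel.
    psf_fwhm
        Lateral PSF FWHM (µm).  When given, the Gaussian width ``w`` is
        constrained near the PSF-limited value (an emitter smaller than
        the PSF cannot appear narrower, and only moderately wider), which
        leaves ``x_half`` and ``x0`` as the effectively free parameters.

    The returned fit carries descriptive ``flags`` (empty for a clean
    fit): ``"low-amplitude"`` when the Gaussian bump is within the noise
    floor, ``"no-edge"`` when no intra/extracellular background contrast
    is detectable.
    """
    y = np.asarray(profile, dtype=float)
    n = y.size
    if n < 20:
        raise ValueError("profile must have at least 20 pixels")
    x = np.arange(n) * pixel_size

    # data-driven initialization
    k = max(3, n // 10)
    lo_end = float(np.mean(y[:k]))
    hi_end = float(np.mean(y[-3 * k:]))
    extra, intra = (lo_end, hi_end) if lo_end < hi_end else (hi_end, lo_end)
    b0 = intra
    c0 = max(intra - extra, 1e-6)
    smoothed = np.convolve(y, np.ones(5) / 5.0, mode="same")
    grad = np.gradient(smoothed)
    # candidate membrane seeds: the background mid-crossing approached from
    # the extracellular end (robust to the ribbon bump, whose flanks can be
    # steeper than the cell edge) and the steepest-gradient position
    mid = (extra + intra) / 2.0
    above = smoothed > mid
    if lo_end < hi_end:  # extracellular at low x
        idx = np.flatnonzero(above)
        x_half_mid = x[idx[0]] if idx.size else x[n // 2]
    else:
        idx = np.flatnonzero(above)
        x_half_mid = x[idx[-1]] if idx.size else x[n // 2]
    x_half_grad = x[int(np.argmax(np.abs(grad)))]
    x_half_seeds = (x_half_mid, x_half_grad)

    if psf_fwhm is not None:
        w_psf = psf_fwhm / _FWHM_PER_SIGMA * np.sqrt(2.0)
        w0, w_lo, w_hi = w_psf, 0.8 * w_psf, 2.5 * w_psf
    else:
        w0 = 5 * pixel_size
        w_lo, w_hi = pixel_size, (n * pixel_size) / 2

    span = n * pixel_size

    def run_branch(d_sign: float, x_half0: float):
        d0 = d_sign * max(3 * pixel_size, 0.02)
        # subtract the provisional edge to seed the Gaussian
        s0 = b0 - c0 / (1.0 + np.exp(np.clip((x_half0 - x) / d0, -500, 500)))
        resid0 = y - s0
        i_pk = int(np.argmax(resid0))
        a0 = max(float(resid0[i_pk]), 1e-6)
        x00 = x[i_pk]
        p0 = [b0, c0, d0, x_half0, a0, x00, w0]
        if d_sign > 0:
            d_lo, d_hi = 1e-4, span
        else:
            d_lo, d_hi = -span, -1e-4
        lower = [-np.inf, 0.0, d_lo, 0.0, 0.0, 0.0, w_lo]
        upper = [np.inf, np.inf, d_hi, span, np.inf, span, w_hi]
        p0 = np.clip(p0, lower, upper)
        res = least_squares(
            lambda p: _sigmoid_gaussian(x, *p) - y,
            p0,
            bounds=(lower, upper),
            method="trf",
            max_nfev=2000,
        )
        return res

    candidates = [
        run_branch(s, xh) for s in (+1.0, -1.0) for xh in x_half_seeds
    ]
    flags: list[str] = []

    def emitter_intracellular(res) -> bool:
        # the emitter must sit on the side where the sigmoid tends to the
        # intracellular background b, i.e. opposite the decay direction of
        # the edge; this rejects the degenerate mode where the Gaussian
        # impersonates the cell edge itself
        _, c_, d_, xh_, _, x0_, _ = res.x
        if c_ <= 3.0 * float(np.sqrt(np.mean(res.fun**2))):
            return True  # no detectable edge: nothing to be on the wrong side of
        intra_sign = -np.sign(d_)
        return (x0_ - xh_) * intra_sign >= 0

    ordered = sorted(candidates, key=lambda r: float(np.sum(r.fun**2)))
    plausible = [r for r in ordered if emitter_intracellular(r)]
    if plausible:
        best = plausible[0]
    else:
        best = ordered[0]
        flags.append("emitter-extracellular")
    b, c, d, x_half, a, x0, w = best.x
    rms = float(np.sqrt(np.mean(best.fun**2)))
    if a < 3.0 * rms:
        flags.append("low-amplitude")
    if c < 3.0 * rms:
        flags.append("no-edge")
    return SpatialProfileFit(
        b=float(b), c=float(c), d=float(d), x_half=float(x_half),
        a=float(a), x0=float(x0), w=float(w), residual=rms,
        pixel_size=pixel_size, flags=flags,
    )


@dataclass
class RegionWindows:
    """Pixel windows (half-open ``[start, stop)``) for the three regions."""

    proximal: tuple[int, int]
    distal: tuple[int, int]
    cytoplasmic: tuple[int, int]
    window_width: int = 5

    def as_dict(self) -> dict[str, tuple[int, int]]:
        return {
            "proximal": self.proximal,
            "distal": self.distal,
            "cytoplasmic": self.cytoplasmic,
        }


def define_region_windows(
    marker_fit: SpatialProfileFit,
    width: int = 5,
    n_pixels: int | None = None,
) -> RegionWindows:
    """Place the proximal/distal/cytoplasmic pixel windows from a marker fit.

    The proximal window is ``width`` pixels centred at the midpoint of
    (x_half, x0), rounding toward the membrane; when the membrane-centroid
    gap is narrower than ``width`` it shrinks to the available gap with a
    floor of 3 pixels.  The distal window starts one pixel past x0 toward
    the cytoplasm and the cytoplasmic window one further window beyond.
    Windows are clipped to the scanned range with a warning.
    """
    if marker_fit.flags:
        raise ValueError(f"marker fit is flagged: {marker_fit.flags}")
    if width < 1:
        raise ValueError("width must be >= 1")
    px_half = marker_fit.x_half_px
    px0 = marker_fit.x0_px
    if px0 <= px_half:
        raise ValueError(
            "expected the ribbon centroid on the cytoplasmic side of the "
            "membrane (x0 > x_half); reorder the scan"
        )
    gap = int(round(px0)) - int(round(px_half)) - 1  # strictly-between pixels
    w_prox = width if gap >= width else max(3, gap)
    center = int(np.floor((px_half + px0) / 2.0))  # rounding toward membrane
    p_start = center - (w_prox - 1) // 2
    p_stop = p_start + w_prox
    d_start = int(round(px0)) + 1
    d_stop = d_start + width
    c_start = d_stop
    c_stop = c_start + width

    if n_pixels is not None:
        clipped = False
        for s, e in ((p_start, p_stop), (d_start, d_stop), (c_start, c_stop)):
            if s < 0 or e > n_pixels:
                clipped = True
        if clipped:
            warnings.warn("region windows clipped to the scanned range")
        p_start, p_stop = max(p_start, 0), min(p_stop, n_pixels)
        d_start, d_stop = max(d_start, 0), min(d_stop, n_pixels)
        c_start, c_stop = max(c_start, 0), min(c_stop, n_pixels)
    return RegionWindows(
        proximal=(p_start, p_stop),
        distal=(d_start, d_stop),
        cytoplasmic=(c_start, c_stop),
        window_width=width,
    )


@dataclass
class TemporalTrace:
    """ΔF/F_rest over time for one spatial region."""

    time: np.ndarray  # ms, relative to stimulus onset
    dff: np.ndarray
    region: str
    baseline_lines: tuple[int, int]  # half-open line-index window used

    @property
    def peak(self) -> float:
        return float(np.max(self.dff))


def compute_dff(
    raster: RasterScan,
    windows: RegionWindows,
    baseline_lines: int = 20,
) -> dict[str, TemporalTrace]:
    """Region-averaged ΔF/F_rest traces from the Ca-indicator channel.

    For each region the five (or clipped) window pixels are averaged per
    line; F_rest is the spatiotemporal mean of the same window over the
    ``baseline_lines`` lines immediately preceding stimulus onset.
    """
    onset = raster.stimulus_onset_line
    if onset <= 0:
        raise ValueError("no pre-stimulus lines available for the baseline")
    b0 = max(0, onset - baseline_lines)
    times = raster.line_times()
    out: dict[str, TemporalTrace] = {}
    for region, (s, e) in windows.as_dict().items():
        if e <= s:
            raise ValueError(f"empty window for region {region!r}")
        per_line = raster.ca[s:e, :].mean(axis=0)
        f_rest = float(per_line[b0:onset].mean())
        if f_rest <= 0:
            raise ValueError(
                f"non-positive baseline fluorescence ({f_rest}) in region "
                f"{region!r}; check offset/background subtraction"
            )
        out[region] = TemporalTrace(
            time=times,
            dff=(per_line - f_rest) / f_rest,
            region=region,
            baseline_lines=(b0, onset),
        )
    return out


@dataclass
class RiseFit:
    """Logistic fit of the rising phase of a Ca2+ transient."""

    amplitude: float  # plateau of the logistic = peak amplitude
    t_half: float  # ms
    tau: float  # ms, logistic time scale
    residual: float
    flags: list[str] = field(default_factory=list)


def fit_rise_sigmoid(trace: TemporalTrace) -> RiseFit:
    """Fit the post-onset rising phase with A / (1 + exp(−(t−t½)/τ)).

    The logistic plateau ``A`` is reported as the peak amplitude.  A flat
    trace returns amplitude ~0 flagged ``"low-signal"``; a decreasing
    trace is flagged ``"no-rise"``.
    """
    mask = trace.time >= 0
    t = trace.time[mask]
    y = trace.dff[mask]
    if t.size < 5:
        raise ValueError("trace has too few post-onset samples")
    # locate the peak on a lightly smoothed copy so a single noise
    # excursion cannot truncate the fitted rising segment
    if y.size >= 7:
        y_smooth = np.convolve(y, np.ones(5) / 5.0, mode="same")
        y_smooth[:2] = y[:2]
        y_smooth[-2:] = y[-2:]
    else:
        y_smooth = y
    i_peak = int(np.argmax(y_smooth))
    flags: list[str] = []
    noise = float(np.std(trace.dff[trace.time < 0])) if np.any(trace.time < 0) else 0.0
    if y[i_peak] <= max(3.0 * noise, 1e-12):
        flags.append("low-signal")
    if i_peak == 0 or y[i_peak] <= y[0]:
        flags.append("no-rise")
    if flags:
        return RiseFit(
            amplitude=float(max(y[i_peak], 0.0)), t_half=float("nan"),
            tau=float("nan"), residual=float(np.std(y)), flags=flags,
        )
    # fit through the full plateau: extend the segment to the last sample
    # still within the noise band of the maximum, so a plateau is used in
    # its entirety while a decaying transient keeps only its rise
    band = max(0.05 * abs(y_smooth[i_peak]), 2.0 * noise)
    near_max = np.flatnonzero(y_smooth >= y_smooth[i_peak] - band)
    i_end = int(near_max.max()) if near_max.size else i_peak
    i_end = max(i_end, i_peak)
    seg_t = t[: i_end + 1]
    seg_y = y[: i_end + 1]
    a0 = float(y_smooth[i_peak])
    above = np.flatnonzero(seg_y >= a0 / 2.0)
    t50_0 = float(seg_t[above[0]]) if above.size else float(seg_t[-1] / 2.0)
    tau0 = max((seg_t[-1] - seg_t[0]) / 6.0, 1e-3)

    def model(p, tt):
        a, t50, tau = p
        return a / (1.0 + np.exp(-np.clip((tt - t50) / tau, -500, 500)))

    res = least_squares(
        lambda p: model(p, seg_t) - seg_y,
        [a0, t50_0, tau0],
        bounds=([0, seg_t[0] - 100, 1e-4], [np.inf, seg_t[-1] + 100, 1e4]),
        max_nfev=2000,
    )
    a, t50, tau = res.x
    return RiseFit(
        amplitude=float(a), t_half=float(t50), tau=float(tau),
        residual=float(np.sqrt(np.mean(res.fun**2))), flags=[],
    )


@dataclass
class DecayFit:
    """Bi-exponential decay of a fluorescence transient past its peak."""

    f_peak: float
    t_peak: float  # ms
    a_fast: float  # percent; a_fast + a_slow = 100
    a_slow: float
    tau_fast: float  # ms
    tau_slow: float  # ms
    residual: float
    restarts: int
    flags: list[str] = field(default_factory=list)


#: search bounds for the decay time constants (ms)
_TAU_BOUNDS = (1.0, 1000.0)


def fit_biexponential_decay(
    trace: TemporalTrace,
    restarts: int = 400,
    seed: int | None = None,
) -> DecayFit:
    """Global bi-exponential fit of the decay phase.

    The model is F(t) = F_peak · [a_f·exp(−(t−t_peak)/τ_f) +
    a_s·exp(−(t−t_peak)/τ_s)] with the weights constrained to sum to 100%
    (one weight parameterized) and τ_f ≤ τ_s enforced by construction.
    The optimizer is differential evolution restarted ``restarts`` times
    from seeded initial populations; the best-of-restarts solution is
    polished and returned.  Identical ``seed`` and ``restarts`` reproduce
    the fit exactly.

    Flags: ``"short-record"`` when the post-peak record is shorter than
    three times the smallest allowed τ; ``"poorly-identified"`` when
    τ_slow/τ_fast < 3, where the two components are not separable —
    bi-exponential fitting is ill-conditioned and such fits should not be
    interpreted quantitatively.
    """
    t = trace.time
    y = trace.dff
    i_peak = int(np.argmax(y))
    post_t = t[i_peak:] - t[i_peak]
    post_y = y[i_peak:]
    if post_t.size < 30:
        raise ValueError("need at least 30 post-peak samples for a decay fit")
    f_peak_obs = float(post_y[0])
    flags: list[str] = []
    if post_t[-1] < 3.0 * _TAU_BOUNDS[0]:
        flags.append("short-record")

    def model(params):
        f_peak, frac_fast, tau_fast, tau_gap = params
        tau_slow = tau_fast + tau_gap
        return f_peak * (
            frac_fast * np.exp(-post_t / tau_fast)
            + (1.0 - frac_fast) * np.exp(-post_t / tau_slow)
        )

    def sse(params):
        return float(np.sum((model(params) - post_y) ** 2))

    bounds = [
        (0.2 * abs(f_peak_obs) + 1e-12, 2.0 * abs(f_peak_obs) + 1e-9),
        (0.0, 1.0),
        (_TAU_BOUNDS[0], _TAU_BOUNDS[1]),
        (0.0, _TAU_BOUNDS[1] - _TAU_BOUNDS[0]),
    ]
    seeds = np.random.SeedSequence(seed).spawn(restarts)
    best = None
    for ss in seeds:
        rng = np.random.Generator(np.random.PCG64(ss))
        res = differential_evolution(
            sse,
            bounds=bounds,
            seed=rng,
            popsize=10,
            maxiter=60,
            tol=1e-7,
            polish=True,
            init="sobol",
        )
        if best is None or res.fun < best.fun:
            best = res
    f_peak, frac_fast, tau_fast, tau_gap = best.x
    tau_slow = tau_fast + tau_gap
    if tau_slow / tau_fast < 3.0:
        flags.append("poorly-identified")
    return DecayFit(
        f_peak=float(f_peak),
        t_peak=float(t[i_peak]),
        a_fast=float(100.0 * frac_fast),
        a_slow=float(100.0 * (1.0 - frac_fast)),
        tau_fast=float(tau_fast),
        tau_slow=float(tau_slow),
        residual=float(np.sqrt(best.fun / post_t.size)),
        restarts=restarts,
        flags=flags,
    )


def ribbon_intensity_ratio(
    image: np.ndarray,
    peak_pixel: tuple[int, int],
    offset: int = 8,
    direction: tuple[int, int] = (0, 1),
    mask: np.ndarray | None = None,
) -> float:
    """Ratio of ribbon-peak intensity to nearby cytoplasm (F_ribbon/F_nearby).

    ``offset`` pixels (8–9 in practice) along ``direction`` from the peak
    pixel define the cytoplasmic reference.  ``mask``, when given, marks
    the terminal interior; a reference outside it is rejected.
    """
    img = np.asarray(image, dtype=float)
    i, j = peak_pixel
    if not (0 <= i < img.shape[0] and 0 <= j < img.shape[1]):
        raise ValueError("peak pixel outside the image")
    ri, rj = i + offset * direction[0], j + offset * direction[1]
    if not (0 <= ri < img.shape[0] and 0 <= rj < img.shape[1]):
        raise ValueError("nearby reference pixel outside the image")
    if mask is not None and not (mask[i, j] and mask[ri, rj]):
        raise ValueError("peak or reference pixel outside the cell mask")
    ref = img[ri, rj]
    if ref <= 0:
        raise ValueError("non-positive reference intensity")
    return float(img[i, j] / ref)


def max_influx_amplitude(frames: np.ndarray, onset_frame: int) -> float:
    """Peak stimulus-evoked ΔF/F_rest from an x-y frame series.

    Averages the pre-stimulus frames into F_rest and the stimulus frames
    into F, finds the pixel with the greatest increase, and returns the
    ΔF/F_rest of the nine pixels (3×3) centred on it.
    """
    stack = np.asarray(frames, dtype=float)
    if stack.ndim != 3:
        raise ValueError("frames must be a (time, y, x) stack")
    if not 0 < onset_frame < stack.shape[0]:
        raise ValueError("need at least one pre-stimulus and one stimulus frame")
    pre = stack[:onset_frame].mean(axis=0)
    stim = stack[onset_frame:].mean(axis=0)
    diff = stim - pre
    # restrict the argmax to pixels with a full 3×3 neighbourhood
    interior = diff[1:-1, 1:-1]
    i, j = np.unravel_index(int(np.argmax(interior)), interior.shape)
    i += 1
    j += 1
    win = (slice(i - 1, i + 2), slice(j - 1, j + 2))
    f_rest = float(pre[win].mean())
    if f_rest <= 0:
        raise ValueError("non-positive resting fluorescence at the hotspot")
    return float(stim[win].mean() / f_rest - 1.0)
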