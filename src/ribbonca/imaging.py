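"""Synthetic confocal imaging of simulated Ca2+ fields.

Generates ground-truth-known two-channel x-t line-scan rasters from a
simulated free-[Ca2+] field movie: indicator binding kinetics per voxel,
fluorescence rendering, 3D Gaussian PSF blur, interleaved two-channel
line sampling at the confocal line rate, and Poisson photon noise.  The
ribbon-marker channel renders the labelled ribbon itself (ribbon voxels
as emitters over a cytoplasmic background), so its blurred profile shows
the Gaussian-bump-on-cell-edge shape the spatial fitting expects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .linescan import RasterScan
from .solver import FieldMovie

__all__ = [
    "OpticalModel",
    "DyeSpec",
    "ScanGeometry",
    "GroundTruth",
    "CAL520_HA",
    "CAL520_LA",
    "simulate_dye_response",
    "render_fluorescence",
    "blur_with_psf",
    "render_linescan",
    "add_photon_noise",
]

_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class OpticalModel:
    """Gaussian confocal PSF, specified by FWHM per axis (µm)."""

    fwhm_x: float = 0.268
    fwhm_y: float = 0.273
    fwhm_z: float = 0.561

    def __post_init__(self) -> None:
        if min(self.fwhm_x, self.fwhm_y, self.fwhm_z) <= 0:
            raise ValueError("PSF FWHMs must be positive")

    def sigmas(self) -> tuple[float, float, float]:
        return (
            self.fwhm_x / _FWHM_PER_SIGMA,
            self.fwhm_y / _FWHM_PER_SIGMA,
            self.fwhm_z / _FWHM_PER_SIGMA,
        )


@dataclass
class DyeSpec:
    """Fluorescent Ca2+ indicator.

    ``mobility`` is ``"free"`` for a soluble dye or ``"ribbon-bound"`` for
    a ribbon-anchored conjugate, which cannot diffuse (diffusivity forced
    to 0).
    """

    name: str
    kd: float  # µM
    on_rate: float  # µM⁻¹ms⁻¹
    total: float = 50.0  # µM
    dynamic_range: float = 100.0  # R_f
    mobility: str = "free"
    diffusivity: float = 0.1  # µm²/ms, ignored for ribbon-bound dye

    def __post_init__(self) -> None:
        if min(self.kd, self.on_rate, self.total) <= 0:
            raise ValueError("kd, on_rate and total must be positive")
        if self.mobility not in ("free", "ribbon-bound"):
            raise ValueError("mobility must be 'free' or 'ribbon-bound'")
        if self.mobility == "ribbon-bound":
            self.diffusivity = 0.0

    @property
    def off_rate(self) -> float:
        return self.on_rate * self.kd


def CAL520_HA(mobility: str = "free") -> DyeSpec:
    """High-affinity indicator (K_D 0.32 µM)."""
    return DyeSpec("Cal520HA", kd=0.32, on_rate=0.45, mobility=mobility)


def CAL520_LA(mobility: str = "free") -> DyeSpec:
    """Low-affinity indicator (K_D 90 µM)."""
    return DyeSpec("Cal520LA", kd=90.0, on_rate=0.1, mobility=mobility)


@dataclass
class ScanGeometry:
    """Placement and timing of the x-t scan line in the simulation frame.

    The default line runs perpendicular to the membrane (bottom face)
    through the ribbon centroid, starting ``overhang`` µm outside the
    cell; ``n_pixels`` samples span the line, so pixel size is line
    length / n_pixels.
    """

    start: tuple[float, float, float] | None = None  # box coords; None -> default
    end: tuple[float, float, float] | None = None
    n_pixels: int = 256
    line_period: float = 1.51  # ms per line per channel
    overhang: float = 0.4  # µm outside the cell for the default line
    marker_first: bool = True

    def resolve(self, movie: FieldMovie) -> tuple[np.ndarray, np.ndarray]:
        if self.start is not None and self.end is not None:
            return np.asarray(self.start, float), np.asarray(self.end, float)
        grid = movie.grid
        cx, cy = grid.base_center
        top = grid.shape[2] * grid.spacing
        return np.asarray([cx, cy, -self.overhang]), np.asarray([cx, cy, top])


@dataclass
class GroundTruth:
    """What the generator actually drew, stored beside every raster."""

    membrane_pos: float  # µm along the scan line
    ribbon_centroid_pos: float  # µm along the scan line
    pixel_size: float
    peak_ca: dict[str, float]  # probe name -> peak free [Ca2+], µM
    peak_dff: dict[str, float]  # region -> noiseless rendered peak ΔF/F_rest
    dye: str = ""
    seed: int | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------


def simulate_dye_response(movie: FieldMovie, dye: DyeSpec) -> np.ndarray:
    """Bound-dye concentration (µM) over the field movie, per voxel.

    Integrates d[CaD]/dt = k_on·C·(D_T − [CaD]) − k_off·[CaD] per voxel
    with [Ca2+] held at its frame value between frames, using the exact
    exponential relaxation of that scalar ODE — unconditionally stable for
    any frame interval, so no explicit sub-stepping is needed.  Free dye
    of a mobile indicator additionally diffuses between frames.  The dye
    is initialized in equilibrium with the first frame.
    """
    fields = movie.fields
    ca0 = np.nan_to_num(fields[0], nan=0.0)
    occ_k = dye.kd
    bound = dye.total * ca0 / (ca0 + occ_k)
    out = np.empty_like(fields)
    out[0] = bound
    diffuse = dye.diffusivity > 0
    if diffuse:
        from .solver import _AxisDiffusion

        axes = [_AxisDiffusion(movie.grid.free_mask, a) for a in range(3)]
        h = movie.grid.spacing
    for i in range(1, fields.shape[0]):
        dt = movie.times[i] - movie.times[i - 1]
        ca = np.nan_to_num(fields[i], nan=0.0)
        rate = dye.on_rate * ca + dye.off_rate
        eq = dye.total * dye.on_rate * ca / rate
        bound = eq + (bound - eq) * np.exp(-rate * dt)
        if diffuse:
            lam = dye.diffusivity * dt / h**2
            free_dye = np.where(movie.grid.free_mask, dye.total - bound, 0.0)
            for op in axes:
                bound = op.solve(bound, lam)
                free_dye = op.solve(free_dye, lam)
            # renormalize: total dye is conserved and uniform at equilibrium
            tot = bound + free_dye
            bound = np.where(tot > 0, dye.total * bound / np.where(tot > 0, tot, 1.0), 0.0)
        bound[~movie.grid.free_mask] = 0.0
        out[i] = bound
    return out


def render_fluorescence(
    bound_dye: np.ndarray, dye: DyeSpec, brightness: float = 1.0
) -> np.ndarray:
    """Photon-rate field F = brightness · (1 + (R_f − 1) · occupancy)."""
    occ = np.asarray(bound_dye, dtype=float) / dye.total
    if occ.min() < -1e-9 or occ.max() > 1 + 1e-9:
        raise ValueError("occupancy must lie in [0, 1]")
    return brightness * (1.0 + (dye.dynamic_range - 1.0) * np.clip(occ, 0.0, 1.0))


def blur_with_psf(
    field_arr: np.ndarray,
    optics: OpticalModel,
    spacing: float,
    mode: str = "nearest",
) -> np.ndarray:
    """3D Gaussian convolution of a (possibly time-stacked) field.

    ``spacing`` must resolve the PSF (≤ half the smallest FWHM).  The
    default ``"nearest"`` edge handling continues each face's boundary
    value outward, appropriate when the volume is a subregion of a larger
    terminal (pad the array explicitly where the true surroundings are
    dark, e.g. below the membrane).
    """
    smallest = min(optics.fwhm_x, optics.fwhm_y, optics.fwhm_z)
    if spacing > smallest / 2.0 + 1e-12:
        raise ValueError(
            f"grid spacing {spacing} µm undersamples the PSF (smallest FWHM "
            f"{smallest} µm); need spacing <= FWHM/2"
        )
    sig = tuple(s / spacing for s in optics.sigmas())
    arr = np.asarray(field_arr, dtype=float)
    if arr.ndim == 3:
        return gaussian_filter(arr, sigma=sig, mode=mode)
    if arr.ndim == 4:
        return np.stack(
            [gaussian_filter(f, sigma=sig, mode=mode) for f in arr]
        )
    raise ValueError("field must be 3D or a 4D time stack")


def _sample_line(
    volume: np.ndarray,
    start: np.ndarray,
    end: np.ndarray,
    n_pixels: int,
    spacing: float,
    outside_value: float,
) -> np.ndarray:
    """Linear interpolation of a 3D volume along a line (box coordinates)."""
    s = np.linspace(0.0, 1.0, n_pixels)
    pts = start[None, :] + s[:, None] * (end - start)[None, :]
    coords = pts.T / spacing - 0.5  # voxel-centre index space
    return map_coordinates(volume, coords, order=1, mode="nearest")


def render_linescan(
    fluor_movie: np.ndarray,
    movie: FieldMovie,
    geometry: ScanGeometry,
    optics: OpticalModel,
    marker_brightness: float = 2.0,
    background: float = 1.0,
    n_lines: int = 100,
    pre_lines: int = 20,
    dye_name: str = "",
) -> tuple[RasterScan, GroundTruth]:
    """Sample a blurred fluorescence movie into a two-channel x-t raster.

    ``fluor_movie`` is the unblurred Ca-indicator photon-rate movie on the
    simulation grid (frames aligned with ``movie.times``); the marker
    channel is rendered from a static volume with the ribbon voxels as
    emitters of ``marker_brightness`` (relative to the ``background``
    cytoplasmic level) — its blurred line profile is the
    Gaussian-on-cell-edge shape the spatial fit expects.  Channels are
    sampled alternately: with ``marker_first``, the marker line of scan
    row j is taken at t = (j − pre_lines)·2·T and the Ca line half a
    period (T = ``line_period``) later.  Lines before ``pre_lines`` rows
    sample the resting field (times clamp to the movie start).

    Returns the noiseless raster and its paired ground truth.
    """
    grid = movie.grid
    h = grid.spacing
    start, end = geometry.resolve(movie)
    top = np.asarray(grid.shape) * h
    for pt in (start, end):
        for a in range(3):
            lo = -geometry.overhang - 1e-9 if a == 2 else -1e-9
            if not (lo <= pt[a] <= top[a] + 1e-9):
                raise ValueError("scan line exits the simulated volume")
    length = float(np.linalg.norm(end - start))
    pixel_size = length / geometry.n_pixels

    # The scan line lies in the microscope's imaging plane together with
    # the box X axis, so the lateral FWHMs apply along the line (box Z)
    # and along X, while the axial FWHM applies along box Y (the optical
    # axis is perpendicular to the imaging plane).
    blur_optics = OpticalModel(
        fwhm_x=optics.fwhm_y, fwhm_y=optics.fwhm_z, fwhm_z=optics.fwhm_x
    )

    # pad below the membrane so the PSF sees dark extracellular space
    pad = int(np.ceil(geometry.overhang / h)) + 1
    pad_widths = ((0, 0), (0, 0), (pad, 0))

    def pad_vol(vol, cval):
        return np.pad(vol, pad_widths, constant_values=cval)

    shift = np.asarray([0.0, 0.0, pad * h])

    # --- marker channel (static) ------------------------------------------
    marker_vol = np.where(grid.free_mask, background, 0.0)
    marker_vol[grid.ribbon_mask | grid.ridge_mask] = marker_brightness
    marker_blur = blur_with_psf(pad_vol(marker_vol, 0.0), blur_optics, h)
    marker_line = _sample_line(
        marker_blur, start + shift, end + shift, geometry.n_pixels, h, 0.0
    )
    # background-only rendering isolates the ribbon bump for the ground truth
    bg_vol = np.where(grid.free_mask | grid.ribbon_mask | grid.ridge_mask,
                      background, 0.0)
    bg_line = _sample_line(
        blur_with_psf(pad_vol(bg_vol, 0.0), blur_optics, h),
        start + shift, end + shift, geometry.n_pixels, h, 0.0,
    )
    bump = np.clip(marker_line - bg_line, 0.0, None)
    s_axis = np.linspace(0.0, length, geometry.n_pixels)
    if bump.sum() > 0:
        centroid_pos = float(np.sum(bump * s_axis) / bump.sum())
    else:
        centroid_pos = float("nan")

    # --- Ca channel (dynamic) ---------------------------------------------
    ca_blur = blur_with_psf(
        np.stack([pad_vol(f, 0.0) for f in fluor_movie]), blur_optics, h
    )
    period = geometry.line_period
    marker_img = np.tile(marker_line[:, None], (1, n_lines))
    ca_img = np.empty((geometry.n_pixels, n_lines))
    ca_offset = period if geometry.marker_first else 0.0
    t0 = movie.times[0]
    t1 = movie.times[-1]
    times = movie.times
    for j in range(n_lines):
        t = (j - pre_lines) * 2.0 * period + ca_offset
        t = min(max(t, t0), t1)
        i = int(np.searchsorted(times, t))
        if i == 0:
            frame = ca_blur[0]
        elif times[i - 1] == t or i >= len(times):
            frame = ca_blur[min(i - 1, len(times) - 1)]
        else:
            wgt = (t - times[i - 1]) / (times[i] - times[i - 1])
            frame = (1 - wgt) * ca_blur[i - 1] + wgt * ca_blur[i]
        ca_img[:, j] = _sample_line(
            frame, start + shift, end + shift, geometry.n_pixels, h, 0.0
        )

    raster = RasterScan(
        marker=marker_img,
        ca=ca_img,
        pixel_size=pixel_size,
        line_period=period,
        stimulus_onset_line=pre_lines,
        metadata={"dye": dye_name, "line_length_um": length},
    )
    # membrane truth: where the scan line crosses the z=0 plane
    if abs(end[2] - start[2]) > 1e-12:
        membrane_pos = float(
            length * (0.0 - start[2]) / (end[2] - start[2])
        )
    else:
        membrane_pos = float("nan")
    truth = GroundTruth(
        membrane_pos=membrane_pos,
        ribbon_centroid_pos=centroid_pos,
        pixel_size=pixel_size,
        peak_ca={},
        peak_dff={},
        dye=dye_name,
    )
    return raster, truth


def add_photon_noise(
    raster: RasterScan,
    photons_per_baseline: float = 50.0,
    seed: int | None = None,
) -> RasterScan:
    """Poisson photon noise at a given baseline photon budget.

    Each channel is scaled so that its pre-stimulus intracellular mean
    corresponds to ``photons_per_baseline`` expected counts per pixel,
    Poisson-sampled, and scaled back.  Seeded and reproducible.
    """
    if photons_per_baseline <= 0:
        raise ValueError("photon budget must be positive")
    rng = np.random.default_rng(seed)
    out = {}
    onset = raster.stimulus_onset_line
    for name in ("marker", "ca"):
        img = getattr(raster, name)
        base_region = img[:, : max(onset, 1)]
        baseline = float(np.median(base_region[base_region > 0])) if (
            base_region > 0
        ).any() else 1.0
        scale = photons_per_baseline / baseline
        counts = rng.poisson(np.clip(img * scale, 0.0, None))
        out[name] = counts / scale
    return RasterScan(
        marker=out["marker"],
        ca=out["ca"],
        pixel_size=raster.pixel_size,
        line_period=raster.line_period,
        stimulus_onset_line=raster.stimulus_onset_line,
        n_channels=raster.n_channels,
        metadata={**raster.metadata, "photons_per_baseline": photons_per_baseline,
                  "noise_seed": seed},
    )
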