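"""Ratiometric and single-wavelength conversion between fluorescence and [Ca2+].

The ratiometric path is the standard Grynkiewicz relation

    [Ca2+] = K_eff · (R − R_min) / (R_max − R),

with the effective in-cell half-saturation constant ``K_eff`` replacing the
cuvette K_D.  The single-wavelength path models indicator fluorescence as
F ∝ 1 + (R_f − 1)·y with occupancy y = C/(C + K), anchors F_rest at the
resting [Ca2+], and inverts ΔF/F_rest for C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CalibrationParams", "ratio_to_ca", "dff_to_ca", "ca_to_dff", "SaturationError"]


class SaturationError(ValueError):
    """Requested conversion lies at or beyond indicator saturation."""


@dataclass
class CalibrationParams:
    """Indicator calibration constants (concentrations in µM)."""

    k_eff: float = 0.795  # effective in-cell half-saturation
    r_min: float = 1.0
    r_max: float = 11.0
    dye_kd: float = 0.32  # cuvette dissociation constant
    dynamic_range: float = 100.0  # R_f = F_max / F_min
    resting_ca: float = 0.1

    def __post_init__(self) -> None:
        if self.k_eff <= 0:
            raise ValueError("k_eff must be > 0")
        if not self.r_min < self.r_max:
            raise ValueError("r_min must be below r_max")
        if self.dynamic_range <= 1:
            raise ValueError("dynamic_range must exceed 1")
        if self.resting_ca < 0:
            raise ValueError("resting_ca must be >= 0")


def ratio_to_ca(ratio: float, calib: CalibrationParams) -> float:
    """[Ca2+] (µM) from a fluorescence ratio via the Grynkiewicz relation."""
    if ratio >= calib.r_max:
        raise SaturationError(
            f"ratio {ratio} at or above R_max={calib.r_max}: indicator saturated"
        )
    if ratio < calib.r_min:
        raise SaturationError(
            f"ratio {ratio} below R_min={calib.r_min}: implies negative [Ca2+]"
        )
    return calib.k_eff * (ratio - calib.r_min) / (calib.r_max - ratio)


def _occupancy(ca: float, k: float) -> float:
    return ca / (ca + k)


def ca_to_dff(ca: float, calib: CalibrationParams, k: float | None = None) -> float:
    """Forward model: ΔF/F_rest produced by [Ca2+]=``ca`` (µM)."""
    if ca < 0:
        raise ValueError("ca must be >= 0")
    k = calib.dye_kd if k is None else k
    rf = calib.dynamic_range
    f = 1.0 + (rf - 1.0) * _occupancy(ca, k)
    f_rest = 1.0 + (rf - 1.0) * _occupancy(calib.resting_ca, k)
    return f / f_rest - 1.0


def dff_to_ca(dff: float, calib: CalibrationParams, k: float | None = None) -> float:
    """Invert a single-wavelength ΔF/F_rest to [Ca2+] (µM).

    Raises :class:`SaturationError` when the implied occupancy reaches 1,
    naming the largest resolvable ΔF/F_rest for these parameters.
    """
    k = calib.dye_kd if k is None else k
    rf = calib.dynamic_range
    f_rest = 1.0 + (rf - 1.0) * _occupancy(calib.resting_ca, k)
    f = f_rest * (1.0 + dff)
    occ = (f - 1.0) / (rf - 1.0)
    if occ < 0:
        raise ValueError(f"dff {dff} implies negative occupancy")
    if occ >= 1.0:
        max_dff = rf / f_rest - 1.0
        raise SaturationError(
            f"dff {dff} implies occupancy >= 1; maximum resolvable dff is "
            f"{max_dff:.4g} at this resting level"
        )
    return k * occ / (1.0 - occ)


def dff_to_ca_array(dff: np.ndarray, calib: CalibrationParams, k: float | None = None) -> np.ndarray:
    """Vectorized :func:`dff_to_ca`; saturating samples become NaN."""
    k = calib.dye_kd if k is None else k
    rf = calib.dynamic_range
    f_rest = 1.0 + (rf - 1.0) * _occupancy(calib.resting_ca, k)
    occ = (f_rest * (1.0 + np.asarray(dff, dtype=float)) - 1.0) / (rf - 1.0)
    out = np.where((occ >= 0) & (occ < 1), k * occ / (1.0 - occ + 1e-300), np.nan)
    return out
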