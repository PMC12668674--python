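"""Voxelization of the single-ribbon simulation domain.

The box is discretized into cubic voxels of side ``grid_spacing``; voxel
``(i, j, k)`` is centred at ``((i+0.5)h, (j+0.5)h, (k+0.5)h)`` with Z the
height above the bottom (membrane) face.  The ribbon ellipsoid and its
ridge are obstacles: their voxels carry no concentration state and their
surfaces reflect diffusing species.  Each channel cluster is mapped to the
bottom-boundary face of the free voxel nearest its (x, y) position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ConfigError, SimulationConfig

__all__ = ["DomainGrid", "build_domain", "GeometryResolutionError"]


class GeometryResolutionError(ConfigError):
    """Grid spacing too coarse to resolve an enabled geometry feature."""


@dataclass
class DomainGrid:
    """Static geometry of a voxelized simulation domain."""

    shape: tuple[int, int, int]
    spacing: float
    free_mask: np.ndarray  # True where concentration state lives
    ribbon_mask: np.ndarray
    ridge_mask: np.ndarray
    base_center: tuple[float, float]  # box coordinates, µm
    source_cells: list[tuple[tuple[int, int], float]]  # ((ix, iy), fraction)

    @property
    def obstacle_mask(self) -> np.ndarray:
        return self.ribbon_mask | self.ridge_mask

    @property
    def n_free(self) -> int:
        return int(self.free_mask.sum())

    @property
    def voxel_volume(self) -> float:
        return self.spacing**3

    def centers(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates along one axis."""
        return (np.arange(self.shape[axis]) + 0.5) * self.spacing

    def to_box_coords(self, point_rel: tuple[float, float, float]) -> np.ndarray:
        """Convert a point relative to the ribbon base centre to box coords."""
        cx, cy = self.base_center
        return np.asarray([cx + point_rel[0], cy + point_rel[1], point_rel[2]])


def _snap_to_center(x: float, h: float, n: int) -> float:
    """Snap a coordinate to the nearest voxel centre (ties toward zero)."""
    i = int(np.floor(x / h))
    i = min(max(i, 0), n - 1)
    c_lo = (i + 0.5) * h
    if i + 1 < n and abs((i + 1.5) * h - x) < abs(c_lo - x) - 1e-12:
        return (i + 1.5) * h
    return c_lo


def build_domain(config: SimulationConfig) -> DomainGrid:
    """Voxelize the box, ribbon obstacle, ridge, and channel-cluster sources.

    Raises :class:`GeometryResolutionError` when the grid spacing exceeds an
    enabled geometry feature (ribbon semi-axis, ridge edge or cluster
    square), which would degenerate the voxelized shape.
    """
    h = config.grid_spacing
    shape = tuple(int(round(d / h)) for d in config.box_dims)
    nx, ny, nz = shape

    features = []
    rib = config.ribbon
    if rib.enabled:
        features += [rib.semi_axis_x, rib.semi_axis_y, rib.semi_axis_z]
        if min(rib.ridge_dims) > 0:
            features += list(rib.ridge_dims)
    if config.clusters.side_length > 0:
        features.append(config.clusters.side_length)
    if features and h > min(features) + 1e-12:
        raise GeometryResolutionError(
            f"grid spacing {h} µm exceeds smallest geometry feature "
            f"{min(features)} µm; refine the grid or disable the feature"
        )

    if rib.base_center is not None:
        cx, cy = rib.base_center
    else:
        cx = _snap_to_center(config.box_dims[0] / 2.0, h, nx)
        cy = _snap_to_center(config.box_dims[1] / 2.0, h, ny)

    x = (np.arange(nx) + 0.5) * h
    y = (np.arange(ny) + 0.5) * h
    z = (np.arange(nz) + 0.5) * h
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")

    ribbon_mask = np.zeros(shape, dtype=bool)
    ridge_mask = np.zeros(shape, dtype=bool)
    if rib.enabled:
        zc = rib.ridge_dims[2] + rib.semi_axis_z  # ellipsoid centre height
        ribbon_mask = (
            ((X - cx) / rib.semi_axis_x) ** 2
            + ((Y - cy) / rib.semi_axis_y) ** 2
            + ((Z - zc) / rib.semi_axis_z) ** 2
        ) <= 1.0
        rx, ry, rz = rib.ridge_dims
        if min(rib.ridge_dims) > 0:
            ridge_mask = (
                (np.abs(X - cx) <= rx / 2 + 1e-12)
                & (np.abs(Y - cy) <= ry / 2 + 1e-12)
                & (Z <= rz - 1e-12)
            )
    free_mask = ~(ribbon_mask | ridge_mask)

    # Map each cluster to the nearest free bottom-face voxel.
    source_cells: list[tuple[tuple[int, int], float]] = []
    for (px, py), frac in zip(
        config.clusters.positions_about((cx, cy)), config.clusters.current_fractions
    ):
        ix = int(np.clip(np.floor(px / h), 0, nx - 1))
        iy = int(np.clip(np.floor(py / h), 0, ny - 1))
        if not free_mask[ix, iy, 0]:
            # walk outward to the nearest free bottom cell
            found = False
            for radius in range(1, max(nx, ny)):
                best = None
                for dx in range(-radius, radius + 1):
                    for dy in range(-radius, radius + 1):
                        jx, jy = ix + dx, iy + dy
                        if 0 <= jx < nx and 0 <= jy < ny and free_mask[jx, jy, 0]:
                            d2 = (x[jx] - px) ** 2 + (y[jy] - py) ** 2
                            if best is None or d2 < best[0]:
                                best = (d2, jx, jy)
                if best is not None:
                    ix, iy = best[1], best[2]
                    found = True
                    break
            if not found:
                raise ConfigError("no free bottom-face cell available for a cluster")
        source_cells.append(((ix, iy), float(frac)))

    return DomainGrid(
        shape=shape,
        spacing=h,
        free_mask=free_mask,
        ribbon_mask=ribbon_mask,
        ridge_mask=ridge_mask,
        base_center=(cx, cy),
        source_cells=source_cells,
    )
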