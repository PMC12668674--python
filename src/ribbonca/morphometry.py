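"""Inter-ribbon distance morphometry from layered serial-section coordinates.

Ribbon sites are traced in serial block-face EM stacks as in-plane (x, y)
positions plus an integer section (layer) index; sections are 50 nm thick
by default.  Distances between ribbons in different layers use the
Pythagorean combination of the in-plane distance and the layer-height
difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "RibbonSite",
    "read_sites_csv",
    "pairwise_distance",
    "distance_matrix",
    "nearest_k_distances",
    "fraction_below",
    "per_cell_summary",
]

DEFAULT_LAYER_THICKNESS = 0.05  # µm; one 50 nm serial section


@dataclass(frozen=True)
class RibbonSite:
    """One traced ribbon: cell id, in-plane position (µm), layer index."""

    cell_id: str
    x: float
    y: float
    layer: int
    layer_thickness: float = DEFAULT_LAYER_THICKNESS
    az_area: float | None = None  # µm², optional
    length: float | None = None  # µm, optional
    width: float | None = None  # µm, optional

    def __post_init__(self) -> None:
        if self.layer_thickness <= 0:
            raise ValueError("layer thickness must be positive")

    @property
    def xyz(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.layer * self.layer_thickness)


def read_sites_csv(path) -> list[RibbonSite]:
    """Load ribbon sites from a CSV with columns cell_id, x_um, y_um, layer
    and optional az_area_um2, length_um, width_um, layer_thickness_um."""
    df = pd.read_csv(path)
    required = {"cell_id", "x_um", "y_um", "layer"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sites CSV missing columns: {sorted(missing)}")
    sites = []
    for row in df.itertuples(index=False):
        sites.append(
            RibbonSite(
                cell_id=str(row.cell_id),
                x=float(row.x_um),
                y=float(row.y_um),
                layer=int(row.layer),
                layer_thickness=float(
                    getattr(row, "layer_thickness_um", DEFAULT_LAYER_THICKNESS)
                ),
                az_area=_opt(row, "az_area_um2"),
                length=_opt(row, "length_um"),
                width=_opt(row, "width_um"),
            )
        )
    return sites


def _opt(row, name):
    val = getattr(row, name, None)
    if val is None or (isinstance(val, float) and np.isnan(val)):
        return None
    return float(val)


def pairwise_distance(a: RibbonSite, b: RibbonSite) -> float:
    """Centre-to-centre distance (µm) between two ribbons of one cell.

    Same-layer pairs reduce to the in-plane distance; cross-layer pairs
    combine the in-plane distance with the layer-height difference by the
    Pythagorean theorem.
    """
    if a.cell_id != b.cell_id:
        raise ValueError("pairwise distances are defined within one cell")
    if a.layer_thickness != b.layer_thickness:
        raise ValueError("sites have mixed layer thicknesses")
    d_plane = float(np.hypot(a.x - b.x, a.y - b.y))
    dz = (a.layer - b.layer) * a.layer_thickness
    return float(np.hypot(d_plane, dz))


def _coords(sites: list[RibbonSite]) -> np.ndarray:
    return np.asarray([s.xyz for s in sites], dtype=float)


def distance_matrix(sites: list[RibbonSite]) -> np.ndarray:
    pts = _coords(sites)
    diff = pts[:, None, :] - pts[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def nearest_k_distances(sites: list[RibbonSite], k: int = 5) -> pd.DataFrame:
    """The k smallest inter-ribbon distances for each ribbon of one cell.

    Returns a tidy frame with one row per (ribbon, rank).  Duplicate
    (zero-distance) sites are allowed with a warning.  Requires more than
    k ribbons.
    """
    if len({s.cell_id for s in sites}) != 1:
        raise ValueError("nearest_k_distances expects the sites of one cell")
    n = len(sites)
    if k < 1 or k >= n:
        raise ValueError(f"k must satisfy 1 <= k < number of ribbons ({n})")
    thicknesses = {s.layer_thickness for s in sites}
    if len(thicknesses) > 1:
        raise ValueError("sites have mixed layer thicknesses")
    pts = _coords(sites)
    tree = cKDTree(pts)
    dist, idx = tree.query(pts, k=k + 1)  # first hit is the point itself
    if np.any(dist[:, 1] == 0.0):
        warnings.warn("duplicate ribbon positions found (zero distances)")
    rows = []
    for i in range(n):
        for rank in range(1, k + 1):
            rows.append(
                {
                    "cell_id": sites[i].cell_id,
                    "ribbon": i,
                    "rank": rank,
                    "neighbor": int(idx[i, rank]),
                    "distance_um": float(dist[i, rank]),
                }
            )
    return pd.DataFrame(rows)


def fraction_below(distances, threshold: float) -> tuple[int, int, float]:
    """(count, total, percentage) of distances below ``threshold`` µm.

    The percentage is rounded to one decimal, matching how such fractions
    are conventionally reported.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    arr = np.asarray(list(distances), dtype=float)
    if arr.size == 0:
        raise ValueError("empty distance list")
    count = int(np.sum(arr < threshold))
    return count, arr.size, round(100.0 * count / arr.size, 1)


def per_cell_summary(sites: list[RibbonSite]) -> pd.DataFrame:
    """Nearest-neighbour distance statistics per cell plus a pooled row.

    Cells with fewer than two ribbons are skipped with a warning.  SEM is
    the sample standard deviation over √n.
    """
    by_cell: dict[str, list[RibbonSite]] = {}
    for s in sites:
        by_cell.setdefault(s.cell_id, []).append(s)
    rows = []
    pooled: list[float] = []
    for cell_id in sorted(by_cell):
        cell_sites = by_cell[cell_id]
        if len(cell_sites) < 2:
            warnings.warn(f"cell {cell_id!r} has a single ribbon; skipped")
            continue
        nn = nearest_k_distances(cell_sites, k=1)["distance_um"].to_numpy()
        pooled.extend(nn.tolist())
        rows.append(_summary_row(cell_id, nn))
    if not rows:
        raise ValueError("no cell with at least two ribbons")
    rows.append(_summary_row("pooled", np.asarray(pooled)))
    return pd.DataFrame(rows)


def _summary_row(label: str, nn: np.ndarray) -> dict:
    n = nn.size
    sem = float(np.std(nn, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return {
        "cell_id": label,
        "n": n,
        "mean_um": float(np.mean(nn)),
        "sem_um": sem,
        "min_um": float(np.min(nn)),
        "max_um": float(np.max(nn)),
    }
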