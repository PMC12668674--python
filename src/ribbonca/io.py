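"""Readers/writers for rasters, probe series and run manifests.

Formats: two-page TIFF (marker, Ca) or a pair of CSV matrices, both with a
JSON sidecar carrying scan metadata; HDF5 containers for simulation
output; CSV export of probe traces.  Every CLI run writes a JSON manifest
sufficient to re-execute it exactly.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .config import config_from_dict, config_to_dict
from .linescan import RasterScan
from .solver import ProbeSeries

__all__ = [
    "read_raster",
    "write_raster",
    "save_probe_series",
    "load_probe_series",
    "probe_traces_frame",
    "RunManifest",
]

_SIDECAR_KEYS = ("pixel_size", "line_period", "stimulus_onset_line", "n_channels")


def write_raster(raster: RasterScan, path: str | Path, fmt: str = "tiff") -> Path:
    """Write a raster as TIFF (two pages) or CSV pair, plus a JSON sidecar.

    Returns the sidecar path.  CSV files are written as ``<stem>.marker.csv``
    and ``<stem>.ca.csv``.
    """
    path = Path(path)
    meta = {
        "pixel_size": raster.pixel_size,
        "line_period": raster.line_period,
        "stimulus_onset_line": raster.stimulus_onset_line,
        "n_channels": raster.n_channels,
        "format": fmt,
        **{k: v for k, v in raster.metadata.items() if _jsonable(v)},
    }
    if fmt == "tiff":
        img_path = path.with_suffix(".tif")
        tifffile.imwrite(
            img_path, np.stack([raster.marker, raster.ca]).astype(np.float32)
        )
    elif fmt == "csv":
        img_path = path
        np.savetxt(path.with_suffix(".marker.csv"), raster.marker, delimiter=",")
        np.savetxt(path.with_suffix(".ca.csv"), raster.ca, delimiter=",")
    else:
        raise ValueError(f"unknown raster format {fmt!r}")
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(meta, indent=2))
    return sidecar


def read_raster(path: str | Path, sidecar: str | Path | None = None) -> RasterScan:
    """Read a raster written by :func:`write_raster` (TIFF or CSV + JSON)."""
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing metadata sidecar {sidecar}; scan metadata is required"
        )
    meta = json.loads(sidecar.read_text())
    missing = [k for k in _SIDECAR_KEYS if k not in meta]
    if missing:
        raise ValueError(f"sidecar {sidecar} missing keys: {missing}")
    fmt = meta.get("format", "tiff")
    if fmt == "tiff":
        stack = tifffile.imread(path.with_suffix(".tif"))
        if stack.ndim != 3 or stack.shape[0] != meta["n_channels"]:
            raise ValueError(
                f"TIFF page count {stack.shape} does not match declared "
                f"{meta['n_channels']} channels"
            )
        marker, ca = stack[0], stack[1]
    else:
        marker = np.loadtxt(path.with_suffix(".marker.csv"), delimiter=",")
        ca = np.loadtxt(path.with_suffix(".ca.csv"), delimiter=",")
    if marker.shape != ca.shape:
        raise ValueError("channel shapes disagree")
    extra = {
        k: v for k, v in meta.items() if k not in (*_SIDECAR_KEYS, "format")
    }
    return RasterScan(
        marker=np.asarray(marker, float),
        ca=np.asarray(ca, float),
        pixel_size=float(meta["pixel_size"]),
        line_period=float(meta["line_period"]),
        stimulus_onset_line=int(meta["stimulus_onset_line"]),
        n_channels=int(meta["n_channels"]),
        metadata=extra,
    )


def probe_traces_frame(series: ProbeSeries) -> pd.DataFrame:
    df = pd.DataFrame({"time_ms": series.time})
    for name, trace in series.traces.items():
        df[name] = trace
    return df


def save_probe_series(series: ProbeSeries, path: str | Path) -> None:
    """Store probe traces, snapshots and the config echo in an HDF5 file."""
    with h5py.File(path, "w") as f:
        f.create_dataset("time_ms", data=series.time)
        grp = f.create_group("traces")
        for name, trace in series.traces.items():
            grp.create_dataset(name, data=trace)
        snaps = f.create_group("snapshots")
        for t, img in series.snapshots.items():
            snaps.create_dataset(f"t_{t:g}", data=img)
            snaps[f"t_{t:g}"].attrs["time_ms"] = t
        if series.config is not None:
            f.attrs["config_json"] = json.dumps(config_to_dict(series.config))


def load_probe_series(path: str | Path) -> ProbeSeries:
    with h5py.File(path, "r") as f:
        time = f["time_ms"][()]
        traces = {name: ds[()] for name, ds in f["traces"].items()}
        snapshots = {
            float(ds.attrs["time_ms"]): ds[()] for ds in f["snapshots"].values()
        }
        config = None
        if "config_json" in f.attrs:
            config = config_from_dict(json.loads(f.attrs["config_json"]))
    return ProbeSeries(time=time, traces=traces, snapshots=snapshots, config=config)


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


@dataclass
class RunManifest:
    """Provenance record written for every CLI run."""

    command: str
    seed: int | None
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    config_echo: dict | None = None
    package_version: str = ""
    timestamp: str = ""

    def write(self, path: str | Path) -> Path:
        from . import __version__

        self.package_version = self.package_version or __version__
        self.timestamp = self.timestamp or datetime.datetime.now(
            datetime.timezone.utc
        ).isoformat()
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, default=str))
        return path


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed fan-out from one root seed.

    Uses SeedSequence with a stable hash of the stage name so re-running a
    single stage reproduces its stream exactly; result is < 2**31.
    """
    tag = int.from_bytes(stage.encode()[:4].ljust(4, b"\0"), "little")
    ss = np.random.SeedSequence([int(root_seed), tag])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
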