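"""Simulation configuration for single-ribbon Ca2+ microdomain models.

Units throughout the package: lengths in µm, times in ms, concentrations in
µM, currents in pA, diffusivities in µm²/ms, surface fluxes in µM·µm/ms.

The default configuration describes a (1.28 × 1.28 × 1.1) µm³ box — the
synaptic-terminal volume per ribbon for a ~5 µm bouton with ~36 ribbons —
containing an ellipsoidal ribbon (semi-axes 70/190/190 nm) standing on a
small ridge (arciform density) on the bottom (membrane) face, with Ca2+
entering through four channel clusters arranged in an 80 nm square under
the ribbon base.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from pathlib import Path
import yaml

__all__ = [
    "BufferSpec",
    "SurfaceExtrusion",
    "ExtrusionSpec",
    "RibbonGeometry",
    "ChannelClusterLayout",
    "Probe",
    "SimulationConfig",
    "load_config",
    "dump_config",
    "ConfigError",
]


class ConfigError(ValueError):
    """Raised when a configuration violates its schema or invariants."""


@dataclass
class BufferSpec:
    """A single-site Ca2+ buffer.

    ``off_rate`` is always derived as ``on_rate * dissociation_constant``
    and never stored independently.  ``diffusivity`` 0 means immobile.
    """

    name: str
    total_concentration: float  # µM
    dissociation_constant: float  # µM
    on_rate: float  # µM⁻¹·ms⁻¹
    diffusivity: float = 0.0  # µm²/ms

    def __post_init__(self) -> None:
        if self.total_concentration < 0:
            raise ConfigError(f"buffer {self.name}: total_concentration must be >= 0")
        if self.dissociation_constant <= 0:
            raise ConfigError(f"buffer {self.name}: dissociation_constant must be > 0")
        if self.on_rate <= 0:
            raise ConfigError(f"buffer {self.name}: on_rate must be > 0")
        if self.diffusivity < 0:
            raise ConfigError(f"buffer {self.name}: diffusivity must be >= 0")

    @property
    def off_rate(self) -> float:
        """Unbinding rate k_off = k_on · K_D (ms⁻¹)."""
        return self.on_rate * self.dissociation_constant

    @property
    def mobile(self) -> bool:
        return self.diffusivity > 0


def endogenous_buffer(total_concentration: float = 1440.0) -> BufferSpec:
    """Immobile endogenous buffer: K_D 2 µM, default 1.44 mM (capacity 720)."""
    return BufferSpec("endogenous", total_concentration, 2.0, 0.1, 0.0)


def egta(total_concentration: float) -> BufferSpec:
    """Mobile EGTA (slow chelator): K_D 0.18 µM, k_on 0.0027 µM⁻¹ms⁻¹."""
    return BufferSpec("EGTA", total_concentration, 0.18, 0.0027, 0.2)


def bapta(total_concentration: float) -> BufferSpec:
    """Mobile BAPTA (fast chelator): K_D 0.22 µM, k_on 0.4 µM⁻¹ms⁻¹."""
    return BufferSpec("BAPTA", total_concentration, 0.22, 0.4, 0.2)


@dataclass
class SurfaceExtrusion:
    """Hill-type clearance on one surface group.

    Two saturable processes act in parallel: a high-capacity/low-affinity
    exchanger term and a lower-capacity/high-affinity pump term with Hill
    coefficient ``hill_coefficient`` (1 on the bottom/membrane face, 2 on
    the remaining surfaces).  A constant leak, computed at run time, zeroes
    the net flux at the resting concentration.
    """

    exchanger_rate: float = 0.1  # A_NCX, µM·µm/ms
    exchanger_affinity: float = 10.0  # K_NCX, µM
    pump_rate: float = 0.01  # A_P, µM·µm/ms
    pump_affinity: float = 0.2  # K_P, µM
    hill_coefficient: int = 2

    def __post_init__(self) -> None:
        if self.exchanger_affinity <= 0 or self.pump_affinity <= 0:
            raise ConfigError("extrusion affinities must be > 0")
        if self.exchanger_rate < 0 or self.pump_rate < 0:
            raise ConfigError("extrusion rates must be >= 0")
        if self.hill_coefficient not in (1, 2):
            raise ConfigError("hill_coefficient must be 1 or 2")


@dataclass
class ExtrusionSpec:
    """Per-surface-group clearance: bottom (membrane) face vs the rest."""

    bottom: SurfaceExtrusion = field(
        default_factory=lambda: SurfaceExtrusion(hill_coefficient=1)
    )
    other: SurfaceExtrusion = field(
        default_factory=lambda: SurfaceExtrusion(hill_coefficient=2)
    )

    @classmethod
    def disabled(cls) -> "ExtrusionSpec":
        """No clearance on any surface (sealed box apart from sources)."""
        return cls(
            bottom=SurfaceExtrusion(0.0, 10.0, 0.0, 0.2, 1),
            other=SurfaceExtrusion(0.0, 10.0, 0.0, 0.2, 2),
        )


@dataclass
class RibbonGeometry:
    """Ellipsoidal ribbon on a ridge, attached to the bottom face.

    The ellipsoid has semi-axes (x, y, z) and sits with its lowest point on
    top of the ridge, i.e. its centre is at height ``ridge_dims[2] +
    semi_axis_z`` above the membrane.  The ridge's long (60 nm) edge runs
    along Y, the ribbon's long horizontal axis.  ``base_center`` is the
    (x, y) point on the bottom face below the ribbon centre; ``None`` snaps
    it to the voxel centre nearest the box centre so the default layout is
    mirror-symmetric on the grid.
    """

    semi_axis_x: float = 0.07
    semi_axis_y: float = 0.19
    semi_axis_z: float = 0.19
    ridge_dims: tuple[float, float, float] = (0.03, 0.06, 0.03)
    base_center: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if min(self.semi_axis_x, self.semi_axis_y, self.semi_axis_z) < 0:
            raise ConfigError("ribbon semi-axes must be >= 0")
        if any(d < 0 for d in self.ridge_dims):
            raise ConfigError("ridge dimensions must be >= 0")
        if self.enabled:
            if self.ridge_dims[0] > 2 * self.semi_axis_x or (
                self.ridge_dims[1] > 2 * self.semi_axis_y
            ):
                raise ConfigError("ridge footprint must fit under the ellipsoid")

    @property
    def enabled(self) -> bool:
        """A zero-measure ellipsoid disables the obstacle entirely."""
        return self.semi_axis_x > 0 and self.semi_axis_y > 0 and self.semi_axis_z > 0

    @property
    def total_height(self) -> float:
        return self.ridge_dims[2] + 2 * self.semi_axis_z if self.enabled else 0.0


@dataclass
class ChannelClusterLayout:
    """Four Ca2+-channel clusters on the membrane under the ribbon base.

    Default positions are the corners of a square of ``side_length`` centred
    on the ribbon base; each cluster passes ``current_fractions`` of the
    total current.
    """

    side_length: float = 0.08
    current_fractions: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    cluster_positions: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.side_length < 0:
            raise ConfigError("cluster side_length must be >= 0")
        if any(f < 0 for f in self.current_fractions):
            raise ConfigError("current fractions must be >= 0")
        if abs(sum(self.current_fractions) - 1.0) > 1e-9:
            raise ConfigError("current fractions must sum to 1")
        if self.cluster_positions is not None and len(self.cluster_positions) != len(
            self.current_fractions
        ):
            raise ConfigError("one position per current fraction required")

    def positions_about(self, base_center: tuple[float, float]) -> list[tuple[float, float]]:
        """Cluster (x, y) positions on the bottom face, in box coordinates."""
        if self.cluster_positions is not None:
            return [tuple(p) for p in self.cluster_positions]
        h = self.side_length / 2.0
        cx, cy = base_center
        return [(cx + sx * h, cy + sy * h) for sx in (-1, 1) for sy in (-1, 1)]


@dataclass
class Probe:
    """A named sampling point, in µm relative to the ribbon base centre."""

    name: str
    position: tuple[float, float, float]


def default_probes() -> list[Probe]:
    """Five sampling points from the membrane microdomain up along the ribbon.

    The proximal probe sits 20 nm lateral of the base centre-line and 10 nm
    above the membrane, ~45 nm from the nearest channel cluster.
    """
    return [
        Probe("proximal", (0.02, 0.0, 0.01)),
        Probe("mid_ribbon", (0.09, 0.0, 0.15)),
        Probe("upper_ribbon", (0.09, 0.0, 0.30)),
        Probe("ribbon_top", (0.02, 0.0, 0.43)),
        Probe("cytosol", (0.40, 0.0, 0.30)),
    ]


@dataclass
class SimulationConfig:
    box_dims: tuple[float, float, float] = (1.28, 1.28, 1.1)
    grid_spacing: float = 0.02
    time_step: float = 0.01  # ms
    pulse_duration: float = 10.0  # ms
    duration: float | None = None  # ms; None -> pulse_duration + 5
    total_current: float = 1.0  # pA
    resting_ca: float = 0.1  # µM
    ca_diffusivity: float = 0.22  # µm²/ms
    buffers: list[BufferSpec] = field(default_factory=lambda: [endogenous_buffer()])
    extrusion: ExtrusionSpec = field(default_factory=ExtrusionSpec)
    ribbon: RibbonGeometry = field(default_factory=RibbonGeometry)
    clusters: ChannelClusterLayout = field(default_factory=ChannelClusterLayout)
    probes: list[Probe] = field(default_factory=default_probes)
    sample_interval: float = 0.1  # ms between recorded probe samples
    seed: int = 0  # recorded for provenance; the solver is deterministic

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.box_dims):
            raise ConfigError("box_dims must all be positive")
        if self.grid_spacing <= 0:
            raise ConfigError("grid_spacing must be positive")
        for dim in self.box_dims:
            n = dim / self.grid_spacing
            # the voxelized box must match the requested one to within a cell
            if round(n) < 4 or abs(dim - round(n) * self.grid_spacing) > self.grid_spacing:
                raise ConfigError(
                    f"grid_spacing {self.grid_spacing} does not resolve box dim {dim}"
                )
        if self.pulse_duration < 0:
            raise ConfigError("pulse_duration must be >= 0")
        if self.total_current < 0:
            raise ConfigError("total_current must be >= 0")
        if self.resting_ca <= 0:
            raise ConfigError("resting_ca must be > 0")
        if self.time_step <= 0 or self.sample_interval <= 0:
            raise ConfigError("time_step and sample_interval must be > 0")

    @property
    def run_duration(self) -> float:
        return self.duration if self.duration is not None else self.pulse_duration + 5.0

    def replace(self, **kwargs) -> "SimulationConfig":
        """Return a deep copy with the given top-level fields replaced."""
        new = copy.deepcopy(self)
        for key, value in kwargs.items():
            if not hasattr(new, key):
                raise ConfigError(f"unknown config field {key!r}")
            setattr(new, key, value)
        new.__post_init__()
        return new


# ---------------------------------------------------------------------------
# Serialization

_TOP_LEVEL_KEYS = {
    "box_dims", "grid_spacing", "time_step", "pulse_duration", "duration",
    "total_current", "resting_ca", "ca_diffusivity", "buffers", "extrusion",
    "ribbon", "clusters", "probes", "sample_interval", "seed",
}


def _tupled(obj):
    if isinstance(obj, dict):
        return {k: _tupled(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_tupled(v) for v in obj]
    return obj


def config_to_dict(config: SimulationConfig) -> dict:
    return _tupled(asdict(config))


def config_from_dict(data: dict) -> SimulationConfig:
    """Build a validated config from a plain dict; unknown keys are rejected."""
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(data) - _TOP_LEVEL_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    kwargs = dict(data)
    if "box_dims" in kwargs:
        kwargs["box_dims"] = tuple(kwargs["box_dims"])
    if "buffers" in kwargs:
        kwargs["buffers"] = [BufferSpec(**b) for b in kwargs["buffers"]]
    if "extrusion" in kwargs:
        ext = kwargs["extrusion"]
        kwargs["extrusion"] = ExtrusionSpec(
            bottom=SurfaceExtrusion(**ext.get("bottom", {})),
            other=SurfaceExtrusion(**ext.get("other", {})),
        )
    if "ribbon" in kwargs:
        rib = dict(kwargs["ribbon"])
        if rib.get("ridge_dims") is not None:
            rib["ridge_dims"] = tuple(rib["ridge_dims"])
        if rib.get("base_center") is not None:
            rib["base_center"] = tuple(rib["base_center"])
        kwargs["ribbon"] = RibbonGeometry(**rib)
    if "clusters" in kwargs:
        clu = dict(kwargs["clusters"])
        if clu.get("current_fractions") is not None:
            clu["current_fractions"] = tuple(clu["current_fractions"])
        if clu.get("cluster_positions") is not None:
            clu["cluster_positions"] = tuple(
                tuple(p) for p in clu["cluster_positions"]
            )
        kwargs["clusters"] = ChannelClusterLayout(**clu)
    if "probes" in kwargs:
        kwargs["probes"] = [
            Probe(p["name"], tuple(p["position"])) for p in kwargs["probes"]
        ]
    try:
        return SimulationConfig(**kwargs)
    except TypeError as exc:  # e.g. nested unknown keys
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path) -> SimulationConfig:
    """Load and validate a YAML (or JSON; YAML is a superset) config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data)


def dump_config(config: SimulationConfig, path: str | Path | None = None) -> str:
    """Serialize a config to YAML; write to ``path`` if given."""
    text = yaml.safe_dump(config_to_dict(config), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
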