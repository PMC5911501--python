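"""Structured-text (TOML) run configuration.

One file describes a complete simulation: the geometry (a built-in
parametric generator or a mesh file), material constants, the cardiac-cycle
waveform, solver/stabilization settings, the smoothing schedule and the
contact threshold.  All geometry lengths are millimeters; everything else
is SI.
"""

from __future__ import annotations

import hashlib
import tomllib
from dataclasses import dataclass, field

from .continuum import MaterialConstants
from .cycle import CycleConfig, PreStressConfig
from .errors import ConfigurationError
from .geometry import (
    BmhvParams,
    RootParams,
    generate_2d_valve_channel,
    generate_aortic_root,
    generate_bmhv,
)
from .smoothing import SmoothingConfig
from .solver import SolverConfig

_KINDS = ("channel2d", "root", "bmhv", "mesh_file")


def _build(cls, section: dict, label: str):
    valid = set(cls.__dataclass_fields__)
    unknown = set(section) - valid
    if unknown:
        raise ConfigurationError(f"unknown keys in [{label}]: {sorted(unknown)}")
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"invalid [{label}] section: {exc}") from exc


@dataclass
class RunConfig:
    """Merged configuration tree for one simulation run."""

    kind: str = "channel2d"
    duration: float | None = None
    seed: int = 0
    geometry: dict = field(default_factory=dict)
    materials: MaterialConstants = field(default_factory=MaterialConstants)
    cycle: CycleConfig = field(default_factory=CycleConfig)
    solver: SolverConfig = field(default_factory=lambda: SolverConfig(krylov="direct"))
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    prestress: PreStressConfig | None = None
    contact_enabled: bool = True
    contact_threshold: float | None = None
    contact_method: str = "geometric"
    output_directory: str = "out"
    store_every: int = 0
    config_hash: str = ""

    @classmethod
    def from_toml(cls, path: str) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = fh.read()
        try:
            data = tomllib.loads(raw.decode())
        except tomllib.TOMLDecodeError as exc:
            raise ConfigurationError(f"{path}: {exc}") from exc

        kind = data.get("kind", "channel2d")
        if kind not in _KINDS:
            raise ConfigurationError(
                f"unknown geometry kind {kind!r}; expected one of {_KINDS}"
            )
        contact = data.get("contact", {})
        output = data.get("output", {})
        cfg = cls(
            kind=kind,
            duration=data.get("duration"),
            seed=int(data.get("seed", 0)),
            geometry=dict(data.get("geometry", {})),
            materials=_build(MaterialConstants, data.get("material", {}), "material"),
            cycle=_build(CycleConfig, data.get("cycle", {}), "cycle"),
            solver=_build(SolverConfig, data.get("solver", {"krylov": "direct"}),
                          "solver"),
            smoothing=_build(SmoothingConfig, data.get("smoothing", {}), "smoothing"),
            prestress=(
                _build(PreStressConfig, data["prestress"], "prestress")
                if "prestress" in data else None
            ),
            contact_enabled=bool(contact.get("enabled", True)),
            contact_threshold=contact.get("threshold"),
            contact_method=contact.get("method", "geometric"),
            output_directory=output.get("directory", "out"),
            store_every=int(output.get("store_every", 0)),
            config_hash=hashlib.sha256(raw).hexdigest()[:16],
        )
        if cfg.contact_method not in ("geometric", "eikonal"):
            raise ConfigurationError(
                f"unknown contact method {cfg.contact_method!r}"
            )
        return cfg

    def build_mesh(self):
        g = dict(self.geometry)
        if self.kind == "channel2d":
            return generate_2d_valve_channel(
                g.pop("channel_length", 80.0),
                g.pop("channel_height", 20.0),
                g.pop("leaflet_length", 17.0),
                g.pop("leaflet_thickness", 1.5),
                g.pop("mesh_size", 2.0),
                **g,
            )
        if self.kind == "root":
            return generate_aortic_root(_build(RootParams, g, "geometry"))
        if self.kind == "bmhv":
            return generate_bmhv(_build(BmhvParams, g, "geometry"))
        if self.kind == "mesh_file":
            from .meshio_ import read_mesh

            if "mesh" not in g:
                raise ConfigurationError("[geometry] mesh = <path> required")
            return read_mesh(g["mesh"])
        raise ConfigurationError(f"unknown kind {self.kind!r}")

    def validate(self) -> None:
        """Build the geometry and check that all referenced tags exist."""
        mesh = self.build_mesh()
        for tag in ("inlet", "outlet", "wall"):
            if len(mesh.tagged_vertices(tag)) == 0:
                raise ConfigurationError(f"mesh lacks required facet tag {tag!r}")
        if self.contact_enabled and "closure" not in mesh.facet_tags:
            raise ConfigurationError(
                "contact enabled but the mesh has no closure surface"
            )
        mesh.validate()
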