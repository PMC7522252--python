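"""Run configuration: domain, substrate, traits, obstacles, boundary terms.

Configurations round-trip through plain dictionaries and YAML/JSON files so
runs are fully reproducible from a single text file plus a seed.  Units in
files: cm, day, kPa, degrees.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .growth import AxisSpec, GrowthTraits
from .obstacles import Obstacle
from .soil import VanGenuchtenSoil

__all__ = ["DomainConfig", "SimulationConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class DomainConfig:
    """Pseudo-2D growth domain and its structured mesh."""

    Lx: float = 10.0
    Lz: float = 10.0
    nx: int = 40
    nz: int = 40
    thickness: float = 0.2


@dataclass
class SimulationConfig:
    """Everything needed to reproduce one growth run (except the seed)."""

    domain: DomainConfig = field(default_factory=DomainConfig)
    soil: VanGenuchtenSoil = field(default_factory=VanGenuchtenSoil)
    obstacles: list = field(default_factory=list)
    traits: GrowthTraits = field(default_factory=GrowthTraits)
    collar_flux: float = 0.2          # cm3/day
    seed_pos: tuple = (5.0, 9.5)      # (x, z) cm
    horizon: float = 6.0              # day
    dt: float = 0.05                  # RSA step, day
    output_interval: float = 0.5      # day
    water_table_z: float = 0.0        # hydrostatic init datum
    bottom_head: float | None = None  # Dirichlet bottom head (cm) if set
    root_radius: float = 0.03         # cm
    K_x: float = 4.32e-2              # cm3/day per unit length
    L_r: float = 1.73e-4              # cm/day per unit length
    contact_threshold: float | None = None  # cm; default 1.5 * max element edge
    w_oi: float = 5.0
    kappa: float = 2.0

    def validate(self) -> None:
        if self.horizon < 0 or self.dt <= 0:
            raise ValueError("horizon must be >= 0 and dt > 0")
        x, z = self.seed_pos
        if not (0 <= x <= self.domain.Lx and 0 <= z <= self.domain.Lz):
            raise ValueError("seed position outside domain")
        times = [a.time for a in self.traits.axes]
        if times != sorted(times):
            raise ValueError("axis schedule must be sorted by time")

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "domain": dataclasses.asdict(self.domain),
            "soil": dataclasses.asdict(self.soil),
            "obstacles": [dataclasses.asdict(o) for o in self.obstacles],
            "traits": {
                **{k: v for k, v in dataclasses.asdict(self.traits).items()
                   if k != "axes"},
                "axes": [[a.time, a.angle] for a in self.traits.axes],
            },
        }
        for f in dataclasses.fields(self):
            if f.name not in ("domain", "soil", "obstacles", "traits"):
                d[f.name] = getattr(self, f.name)
        d["seed_pos"] = list(self.seed_pos)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        kw = {}
        if "domain" in d:
            kw["domain"] = DomainConfig(**d.pop("domain"))
        if "soil" in d:
            kw["soil"] = VanGenuchtenSoil(**d.pop("soil"))
        if "obstacles" in d:
            kw["obstacles"] = [
                Obstacle(**{**o, "center": tuple(o["center"])})
                for o in d.pop("obstacles")]
        if "traits" in d:
            t = dict(d.pop("traits"))
            axes = [AxisSpec(*a) for a in t.pop("axes", [[0.0, 0.0]])]
            for key in ("elongation_axis", "elongation_lateral"):
                if key in t:
                    t[key] = [tuple(row) for row in t[key]]
            kw["traits"] = GrowthTraits(axes=axes, **t)
        if "seed_pos" in d:
            kw["seed_pos"] = tuple(d.pop("seed_pos"))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kw.update(d)
        cfg = cls(**kw)
        cfg.validate()
        return cfg


def load_config(path) -> SimulationConfig:
    """Load a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return SimulationConfig.from_dict(data)


def save_config(cfg: SimulationConfig, path) -> None:
    path = Path(path)
    d = cfg.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
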