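"""Runtime configuration: every geometric threshold in one place.

All values that the analyses depend on but that have no single published
definition (bundle packing distance, perpendicularity window, disulfide
cutoff, domain window width, patch clustering parameters) are exposed
here and overridable from YAML.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

__all__ = ["Config", "load_config", "dump_default_config"]

SCHEMA_VERSION = 1


@dataclasses.dataclass
class Config:
    # secondary structure
    hbond_energy_cutoff: float = -0.5   # kcal/mol, Kabsch-Sander
    # bundle geometry
    axis_distance_max: float = 14.0     # A
    min_bundle_helix_len: int = 7       # residues
    perp_window: tuple = (60.0, 120.0)  # deg
    perp_centroid_dist: float = 12.0    # A
    # motifs
    sg_cutoff: float = 2.5              # A
    short_helix_max: int = 7            # residues
    hairpin_max_loop: int = 5           # residues
    # domains
    window_width: int = 15              # residues
    bend_definition: str = "principal"  # or "bundle_axis"
    # conservation / patches
    exposure_cutoff: float = 0.25
    link_distance: float = 10.0         # A
    conservation_quantile: float = 0.75
    # general
    seed: int = 0
    chain: str | None = None

    def __post_init__(self):
        for name in ("axis_distance_max", "sg_cutoff", "perp_centroid_dist",
                     "link_distance", "window_width", "short_helix_max",
                     "min_bundle_helix_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config threshold {name} must be positive")
        if self.bend_definition not in ("principal", "bundle_axis"):
            raise ValueError("bend_definition must be 'principal' or "
                             "'bundle_axis'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["perp_window"] = list(self.perp_window)
        d["schema_version"] = SCHEMA_VERSION
        return d


def load_config(path: str | Path | None) -> Config:
    if path is None:
        return Config()
    data = yaml.safe_load(Path(path).read_text()) or {}
    data.pop("schema_version", None)
    known = {f.name for f in dataclasses.fields(Config)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "perp_window" in data:
        data["perp_window"] = tuple(data["perp_window"])
    return Config(**data)


def dump_default_config() -> str:
    return yaml.safe_dump(Config().to_dict(), sort_keys=False)
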