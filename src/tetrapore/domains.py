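"""Named domain registry and analysis parameters.

The registry maps the standard RyR1 domain names (central domain CD,
C-terminal domain CTD, S2-S3 loop, EF-hand loops, pore region, ...) to
author-numbering residue intervals.  The central-block subdivisions
U_motif, S6N and S6C have no published boundaries and therefore carry no
defaults; analyses that need them require a user-supplied registry entry.

All distance cutoffs and numeric knobs live in :class:`AnalysisConfig`;
both objects load from a TOML file.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

__all__ = ["DomainDefinition", "DomainRegistry", "AnalysisConfig",
           "DEFAULT_VDW_RADII", "load_config"]

# HOLE-style simple van der Waals radius set (Angstrom)
DEFAULT_VDW_RADII: dict[str, float] = {
    "C": 1.85, "N": 1.75, "O": 1.65, "S": 2.00, "H": 1.00, "P": 2.10,
}


@dataclass(frozen=True)
class DomainDefinition:
    """A named set of inclusive author-numbering residue intervals."""

    name: str
    ranges: tuple[tuple[int, int], ...]
    scope: str = "per_protomer"  # or "assembly"

    def __post_init__(self) -> None:
        if not self.ranges:
            raise ValueError(f"domain {self.name}: no intervals")
        rngs = tuple((int(a), int(b)) for a, b in self.ranges)
        for a, b in rngs:
            if a > b:
                raise ValueError(f"domain {self.name}: interval {a} > {b}")
        ordered = sorted(rngs)
        for (a1, b1), (a2, b2) in zip(ordered, ordered[1:]):
            if a2 <= b1:
                raise ValueError(f"domain {self.name}: overlapping intervals")
        object.__setattr__(self, "ranges", rngs)
        if self.scope not in ("per_protomer", "assembly"):
            raise ValueError(f"domain {self.name}: bad scope {self.scope!r}")

    @property
    def n_residues(self) -> int:
        return sum(b - a + 1 for a, b in self.ranges)

    def contains(self, residue_number: int) -> bool:
        return any(a <= residue_number <= b for a, b in self.ranges)


def _dd(name: str, *ranges: tuple[int, int]) -> DomainDefinition:
    return DomainDefinition(name=name, ranges=tuple(ranges))


_DEFAULT_DOMAINS: dict[str, DomainDefinition] = {
    d.name: d for d in [
        _dd("CD", (3668, 4070)),
        _dd("CTD", (4957, 5037)),
        _dd("S2S3_loop", (4664, 4786)),
        _dd("EF_loops", (4081, 4090), (4116, 4123)),
        _dd("luminal_loop", (4860, 4878)),
        _dd("pore_helix", (4879, 4893)),
        _dd("pore_region", (4821, 5037)),
        _dd("helix_h", (3753, 3769)),
        _dd("S4_310", (4807, 4813)),
        _dd("S4_near_pi", (4814, 4819)),
        _dd("S5_pi", (4856, 4859)),
        _dd("S6_pi", (4921, 4928)),
        _dd("gate_residue", (4937, 4937)),
        _dd("constriction_check", (4933, 4933)),
        _dd("flexion_inner", (348, 348)),
        _dd("flexion_outer", (984, 984)),
    ]
}

# names accepted in config but deliberately without built-in boundaries
_NO_DEFAULT = ("U_motif", "S6N", "S6C")


class DomainRegistry:
    """Mapping of domain name -> :class:`DomainDefinition` with RyR1 defaults."""

    def __init__(self, extra: dict[str, DomainDefinition] | None = None) -> None:
        self._domains = dict(_DEFAULT_DOMAINS)
        if extra:
            self._domains.update(extra)

    def __contains__(self, name: str) -> bool:
        return name in self._domains

    def __getitem__(self, name: str) -> DomainDefinition:
        try:
            return self._domains[name]
        except KeyError:
            if name in _NO_DEFAULT:
                raise KeyError(
                    f"domain {name!r} has no built-in boundaries; supply it in "
                    "the registry configuration") from None
            raise KeyError(f"unknown domain name {name!r}") from None

    def get(self, name: str, default=None):
        return self._domains.get(name, default)

    def names(self) -> list[str]:
        return list(self._domains)

    def add(self, definition: DomainDefinition) -> None:
        self._domains[definition.name] = definition

    @classmethod
    def from_toml_dict(cls, data: dict) -> "DomainRegistry":
        extra = {}
        for name, spec in data.items():
            if isinstance(spec, dict):
                ranges = spec["ranges"]
                scope = spec.get("scope", "per_protomer")
            else:
                ranges = spec
                scope = "per_protomer"
            ranges = tuple((int(r[0]), int(r[1])) for r in ranges)
            extra[name] = DomainDefinition(name=name, ranges=ranges, scope=scope)
        return cls(extra=extra)


@dataclass(frozen=True)
class AnalysisConfig:
    """Distance cutoffs (Angstrom) and numeric parameters for all analyses."""

    salt_bridge_cutoff: float = 3.5
    coordination_cutoff: float = 2.8
    polar_contact_cutoff: float = 3.6
    ligand_contact_cutoff: float = 4.0
    lipid_contact_cutoff: float = 5.0
    disulfide_cutoff: float = 2.5
    hbond_distance_cutoff: float = 3.5
    hbond_angle_min: float = 120.0     # degrees, used only when H present
    sasa_probe: float = 1.4
    sasa_points: int = 960
    pore_step: float = 0.25
    pore_max_radius: float = 15.0
    rpt_window: int = 3                # residues-per-turn smoothing window
    vdw_radii: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_VDW_RADII))

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name in ("vdw_radii", "hbond_angle_min", "sasa_points", "rpt_window"):
                continue
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")
        if self.rpt_window < 1 or self.rpt_window % 2 == 0:
            raise ValueError("rpt_window must be odd and >= 1")
        if self.sasa_points < 1:
            raise ValueError("sasa_points must be >= 1")

    def vdw(self, element: str) -> float:
        try:
            return self.vdw_radii[element.capitalize() if len(element) > 1
                                  else element.upper()]
        except KeyError:
            raise KeyError(f"no van der Waals radius configured for element "
                           f"{element!r}") from None

    def with_(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)


def load_config(path: str | Path) -> tuple[DomainRegistry, AnalysisConfig]:
    """Load a TOML file with optional ``[domains]`` and ``[analysis]`` tables."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    registry = DomainRegistry.from_toml_dict(data.get("domains", {}))
    analysis = data.get("analysis", {})
    vdw = dict(DEFAULT_VDW_RADII)
    vdw.update(analysis.pop("vdw_radii", {}))
    config = AnalysisConfig(**analysis, vdw_radii=vdw)
    return registry, config
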