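"""Consolidated state report and closed/open/inactivated classification.

A :class:`StateReport` gathers, for one coordinate model, the geometric
hallmarks that distinguish the three gating states of the channel: the
Calpha gate diameter and minimal pore radius at the gate, the mean
flexion angle of the cytoplasmic shell, the presence of the configured
EF-hand/S2-S3-loop inter-subunit salt bridges, occupancy of configured
ion sites, and pi-helix presence in configured transmembrane ranges.

The classification rule is deliberately simple and configurable:

* open         iff gate Calpha diameter >= 14 A,
* inactivated  iff gate < 14 A and both salt bridges present and
                flexion <= -3.5 degrees,
* closed       iff gate < 14 A and the inactivation condition fails,
* indeterminate when a required measurement is unavailable.

The 14 A threshold splits the published closed-type (10.3-11.3 A) and
open-type (15.8-16.7 A) gate diameters.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .domains import AnalysisConfig, DomainRegistry
from .errors import TetraporeError
from .frame import assign_protomers, compute_channel_frame
from .interactions import coordination_shell, find_salt_bridges
from .helices import classify_helix, helix_segments, residues_per_turn
from .model import StructureModel, read_structure
from .motions import domain_motion, flexion_angle
from .pore import (compute_pore_profile, gate_diameter_calpha,
                   radius_at_landmark, write_profile)
from .superpose import rmsd_heatmap

__all__ = ["ClassificationRule", "StateReport", "analyze_state", "run_compare"]

DEFAULT_SALT_BRIDGE_PAIRS = ((4075, 4736), (4101, 4730))


@dataclass(frozen=True)
class ClassificationRule:
    open_gate_min: float = 14.0          # Calpha gate diameter, Angstrom
    inactivated_flexion_max: float = -3.5  # degrees

    def classify(self, gate_diameter: float | None,
                 both_bridges: bool | None,
                 flexion_mean: float | None) -> str:
        if gate_diameter is None:
            return "indeterminate"
        if gate_diameter >= self.open_gate_min:
            return "open"
        if both_bridges is None or flexion_mean is None:
            return "closed"
        if both_bridges and flexion_mean <= self.inactivated_flexion_max:
            return "inactivated"
        return "closed"


@dataclass
class StateReport:
    model_id: str
    gate_residue: int
    gate_ca_diameter: float | None = None
    min_pore_radius_at_gate: float | None = None
    flexion_mean: float | None = None
    flexion_per_protomer: tuple | None = None
    salt_bridges: dict = field(default_factory=dict)   # "4075-4736" -> bool
    ion_sites: dict = field(default_factory=dict)      # "CA" -> bool
    pi_segments: dict = field(default_factory=dict)    # "S6_pi" -> bool
    classification: str = "indeterminate"
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def _salt_bridge_flags(model: StructureModel, pairs, config) -> dict:
    records = find_salt_bridges(model, scope="inter_subunit", config=config)
    found = {(r.partner_a[2], r.partner_b[2]) for r in records}
    found |= {(b, a) for a, b in found}
    return {f"{a}-{b}": (a, b) in found for a, b in pairs}


def _pi_flags(model: StructureModel, registry, config, ranges) -> dict:
    out = {}
    ca = model.ca_mask
    for name in ranges:
        dom = registry[name]
        lo = min(a for a, _ in dom.ranges) - 6
        hi = max(b for _, b in dom.ranges) + 6
        present = False
        for k in range(model.symmetry_order):
            m = ca & (model.protomer == k) & \
                (model.res_number >= lo) & (model.res_number <= hi)
            idx = np.nonzero(m)[0]
            if len(idx) < 7:
                continue
            order = np.argsort(model.res_number[idx])
            trace = model.xyz[idx[order]]
            nums = model.res_number[idx[order]]
            if np.any(np.diff(nums) != 1):
                continue
            geo = classify_helix(residues_per_turn(trace, nums,
                                                   window=config.rpt_window))
            for label, a, b in helix_segments(geo):
                if label == "pi" and not (b < lo + 6 or a > hi - 6) \
                        and any(a <= rb and b >= ra for ra, rb in dom.ranges):
                    present = True
        out[name] = present
    return out


def analyze_state(model: StructureModel,
                  registry: DomainRegistry | None = None,
                  config: AnalysisConfig | None = None,
                  rule: ClassificationRule | None = None,
                  gate_residue: int = 4937,
                  salt_bridge_pairs=DEFAULT_SALT_BRIDGE_PAIRS,
                  ion_names: tuple[str, ...] = ("CA",),
                  pi_ranges: tuple[str, ...] = ("S6_pi",)) -> StateReport:
    """Measure every classification feature available in one model."""
    registry = registry or DomainRegistry()
    config = config or AnalysisConfig()
    rule = rule or ClassificationRule()
    if not (model.protomer >= 0).any():
        model = assign_protomers(model, registry=registry)
    report = StateReport(model_id=model.id, gate_residue=gate_residue)

    frame = None
    try:
        frame = compute_channel_frame(model, registry)
    except TetraporeError as exc:
        report.notes.append(f"frame: {exc}")

    if frame is not None:
        try:
            report.gate_ca_diameter = gate_diameter_calpha(model, gate_residue,
                                                           frame)
        except TetraporeError as exc:
            report.notes.append(f"gate diameter: {exc}")
        try:
            profile = compute_pore_profile(model, frame, registry=registry,
                                           config=config,
                                           landmarks=(gate_residue,))
            report.min_pore_radius_at_gate = radius_at_landmark(profile,
                                                                gate_residue)
        except TetraporeError as exc:
            report.notes.append(f"pore profile: {exc}")
        try:
            flex = flexion_angle(model, frame)
            report.flexion_mean = flex.mean
            report.flexion_per_protomer = flex.per_protomer
        except TetraporeError as exc:
            report.notes.append(f"flexion: {exc}")

    report.salt_bridges = _salt_bridge_flags(model, salt_bridge_pairs, config)
    for ion in ion_names:
        try:
            shells = coordination_shell(model, ion, config=config)
            report.ion_sites[ion] = any(len(s) > 0 for _, s in shells)
        except TetraporeError:
            report.ion_sites[ion] = False
    try:
        report.pi_segments = _pi_flags(model, registry, config, pi_ranges)
    except TetraporeError as exc:
        report.notes.append(f"pi segments: {exc}")

    both = None
    if report.salt_bridges:
        both = all(report.salt_bridges.values())
    report.classification = rule.classify(report.gate_ca_diameter, both,
                                          report.flexion_mean)
    return report


def run_compare(models: list,
                outdir: str | Path,
                registry: DomainRegistry | None = None,
                config: AnalysisConfig | None = None,
                rule: ClassificationRule | None = None,
                heatmap_domains: list[str] | None = None,
                motion_domain: str = "EF_loops",
                **state_kwargs) -> dict:
    """End-to-end comparison of a set of models.

    ``models`` holds file paths or :class:`StructureModel` objects.  The
    first model is the reference for pairwise heatmaps and rigid motions.
    Per-model failures are isolated and recorded; the returned dict has
    keys ``reports``, ``heatmaps``, ``motions``, ``failures``.
    """
    registry = registry or DomainRegistry()
    config = config or AnalysisConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    loaded: list[StructureModel] = []
    failures: dict[str, str] = {}
    for m in models:
        try:
            sm = m if isinstance(m, StructureModel) else read_structure(m)
            if not (sm.protomer >= 0).any():
                sm = assign_protomers(sm, registry=registry)
            loaded.append(sm)
        except Exception as exc:  # isolate per-model failures
            failures[str(m)] = str(exc)

    reports = []
    for sm in loaded:
        try:
            rep = analyze_state(sm, registry, config, rule, **state_kwargs)
            reports.append(rep)
            try:
                frame = compute_channel_frame(sm, registry)
                profile = compute_pore_profile(sm, frame, registry=registry,
                                               config=config)
                write_profile(profile, outdir / f"profile_{sm.id}.csv")
            except TetraporeError:
                pass
        except Exception as exc:
            failures[sm.id] = str(exc)

    heatmaps = {}
    motions = {}
    skipped: dict[str, str] = {}
    if len(loaded) >= 2:
        ref = loaded[0]
        for other in loaded[1:]:
            key = f"{ref.id}_vs_{other.id}"
            try:
                hm = rmsd_heatmap(ref, other, registry,
                                  domains=heatmap_domains, protomer=0)
                heatmaps[key] = hm
                hm.to_frame().to_csv(outdir / f"heatmap_{key}.csv", index=False)
            except TetraporeError as exc:
                skipped[f"heatmap:{key}"] = str(exc)
            try:
                motions[key] = domain_motion(ref, other,
                                             registry[motion_domain],
                                             registry=registry)
            except TetraporeError as exc:
                skipped[f"motion:{key}"] = str(exc)

    payload = {
        "software": {"name": "tetrapore", "version": __version__},
        "reports": [r.to_dict() for r in reports],
        "motions": {k: {"twist_deg": m.twist_deg, "swing_deg": m.swing_deg,
                        "swing_sign": m.swing_sign, "rmsd": m.rmsd,
                        "n_atoms": m.n_atoms} for k, m in motions.items()},
        "failures": failures,
        "skipped": skipped,
    }
    (outdir / "report.json").write_text(json.dumps(payload, indent=2,
                                                   sort_keys=True, default=str))
    (outdir / "run.log").write_text(
        f"tetrapore {__version__}\nmodels: {[getattr(m, 'id', m) for m in models]}\n"
        f"failures: {failures}\n")
    return {"reports": reports, "heatmaps": heatmaps, "motions": motions,
            "failures": failures, "skipped": skipped}
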