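"""Synthetic coordinate fixtures with analytically known properties.

Every analysis stage in the package is testable against these generators
without any downloaded structure: ideal helices of chosen twist/rise,
C4-symmetric pore fixtures with an exactly known constriction radius,
rigid-motion and flexion fixtures built by construction, and residue pairs
placed at controlled side-chain distances (full side chains taken from the
chemical component dictionary shipped with biotite).

All fixtures except the interaction fixtures are Calpha-only: every
measurement they feed (pore radius, RMSD, flexion, helix geometry) is
Calpha- or sphere-based.  The generators are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .domains import DEFAULT_VDW_RADII, DomainDefinition, DomainRegistry
from .errors import DegenerateGeometryError
from .frame import assign_protomers, compute_channel_frame, rotation_about_axis
from .model import AtomRecord, StructureModel

__all__ = ["HelixSpec", "PoreFixtureSpec", "build_ideal_helix",
           "build_c4_pore_fixture", "apply_rigid_motion",
           "build_flexion_fixture", "build_interaction_fixture",
           "build_conformation_fixture"]

_CHAINS = ("A", "B", "C", "D")


@dataclass(frozen=True)
class HelixSpec:
    """Ideal helix parameters.  Canonical values: alpha 100 deg / 1.5 A,
    3-10 120 deg / 2.0 A, pi 81.8 deg / 1.15 A."""

    n_residues: int = 20
    twist_per_residue: float = 100.0   # degrees
    rise_per_residue: float = 1.5      # Angstrom
    helix_radius: float = 2.3          # Angstrom (Calpha distance from axis)
    start_residue_number: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.twist_per_residue < 180.0):
            raise ValueError("twist_per_residue must be in (0, 180) degrees")
        if self.rise_per_residue <= 0:
            raise ValueError("rise_per_residue must be positive")
        if self.n_residues < 4:
            raise ValueError("need at least 4 residues")


@dataclass(frozen=True)
class PoreFixtureSpec:
    """C4 pore fixture: a constriction ring of known inscribed radius framed
    by wider vestibule rings."""

    gate_radius: float = 1.0          # analytic minimal pore radius, Angstrom
    ring_atom_count: int = 16         # atoms per ring (multiple of 4)
    ring_z: float = 0.0
    vestibule_radius: float = 5.0
    n_rings: int = 3                  # vestibule rings on each side of the gate
    atom_element: str = "O"
    ring_spacing: float = 1.0

    def __post_init__(self) -> None:
        if self.gate_radius <= 0:
            raise ValueError("gate_radius must be positive")
        if self.gate_radius >= self.vestibule_radius:
            raise ValueError("no constriction: gate_radius >= vestibule_radius")
        if self.ring_atom_count % 4 != 0 or self.ring_atom_count < 8:
            raise ValueError("ring_atom_count must be a multiple of 4, >= 8")
        if self.atom_element not in DEFAULT_VDW_RADII:
            raise ValueError(f"no vdW radius for element {self.atom_element!r}")


def build_ideal_helix(spec: HelixSpec, backbone: bool = False) -> StructureModel:
    """Calpha trace of an ideal helix about the z axis (single chain, ALA).

    With ``backbone=True`` pseudo N and O atoms are added in a purely
    geometric construction that realises the canonical i <- i+4 backbone
    hydrogen-bond pattern (O_i placed 2.95 A from N_{i+4}); this is a
    detector fixture, not a stereochemically built backbone.
    """
    n = spec.n_residues
    theta = np.radians(spec.twist_per_residue)
    ca = np.stack([
        spec.helix_radius * np.cos(theta * np.arange(n)),
        spec.helix_radius * np.sin(theta * np.arange(n)),
        spec.rise_per_residue * np.arange(n),
    ], axis=1)

    atoms: list[AtomRecord] = []
    serial = 1

    nitro = None
    if backbone:
        tangents = np.gradient(ca, axis=0)
        tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
        nitro = ca - 0.75 * tangents

    for k in range(n):
        resnum = spec.start_residue_number + k
        if backbone:
            atoms.append(AtomRecord(serial, "N", "N", "", resnum, "", "ALA", "A",
                                    -1, nitro[k]))
            serial += 1
        atoms.append(AtomRecord(serial, "CA", "C", "", resnum, "", "ALA", "A",
                                -1, ca[k]))
        serial += 1
        if backbone:
            if k + 4 < n:
                d = nitro[k + 4] - ca[k]
                o = nitro[k + 4] - 2.95 * d / np.linalg.norm(d)
            else:
                o = ca[k] + np.array([0.0, 0.0, -1.23])
            atoms.append(AtomRecord(serial, "O", "O", "", resnum, "", "ALA", "A",
                                    -1, o))
            serial += 1
    model = StructureModel.from_atoms(
        atoms, id=f"helix_twist{spec.twist_per_residue:g}_rise{spec.rise_per_residue:g}")
    return model


def build_c4_pore_fixture(spec: PoreFixtureSpec,
                          marker_radius: float | None = None,
                          gate_residue: int = 4937) -> StructureModel:
    """Tetramer whose maximal inscribed sphere at ``ring_z`` has exactly
    radius ``gate_radius``.

    Ring atom centers sit at (gate_radius + vdW) from the z axis.  Each
    chain also carries one Calpha marker per ring residue (at
    ``marker_radius`` from the axis, default the ring-center radius) so
    Calpha-based gate diameters can be asserted, and a cytoplasmic cap of
    Calpha atoms above the rings to orient the frame.
    """
    vdw = DEFAULT_VDW_RADII[spec.atom_element]
    gate_center_r = spec.gate_radius + vdw
    vest_center_r = spec.vestibule_radius + vdw
    if marker_radius is None:
        # default markers sit behind the lining atoms so they never shrink
        # the inscribed sphere below the analytic gate radius
        marker_radius = gate_center_r + 3.0
    m = spec.ring_atom_count // 4

    atoms: list[AtomRecord] = []
    serial = 1
    ring_js = range(-spec.n_rings, spec.n_rings + 1)
    for ci, chain in enumerate(_CHAINS):
        for j in ring_js:
            resnum = gate_residue + j
            radius = gate_center_r if j == 0 else vest_center_r
            z = spec.ring_z + j * spec.ring_spacing
            for i in range(m):
                phi = np.radians(ci * 90.0 + (i + 0.5) * 90.0 / m)
                pos = np.array([radius * np.cos(phi), radius * np.sin(phi), z])
                atoms.append(AtomRecord(serial, f"O{i+1}", spec.atom_element, "",
                                        resnum, "", "GLY", chain, -1, pos))
                serial += 1
            if j == 0:
                phi = np.radians(ci * 90.0 + 45.0)
                pos = np.array([marker_radius * np.cos(phi),
                                marker_radius * np.sin(phi), z])
                atoms.append(AtomRecord(serial, "CA", "C", "", resnum, "", "GLY",
                                        chain, -1, pos))
                serial += 1
        # cytoplasmic cap, outside the pore region so the axis orients +z
        z_top = spec.ring_z + (spec.n_rings + 1) * spec.ring_spacing + 15.0
        for r_i, resnum in enumerate((100, 101, 102)):
            phi = np.radians(ci * 90.0 + 20.0 * r_i)
            pos = np.array([12.0 * np.cos(phi), 12.0 * np.sin(phi),
                            z_top + 2.0 * r_i])
            atoms.append(AtomRecord(serial, "CA", "C", "", resnum, "", "GLY",
                                    chain, -1, pos))
            serial += 1
    model = StructureModel.from_atoms(atoms, id=f"pore_gate{spec.gate_radius:g}")
    return assign_protomers(model)


def apply_rigid_motion(model: StructureModel,
                       domain: DomainDefinition,
                       twist_deg: float = 0.0,
                       swing_deg: float = 0.0,
                       swing_axis_azimuth_deg: float = 0.0,
                       translation=(0.0, 0.0, 0.0),
                       registry: DomainRegistry | None = None) -> StructureModel:
    """Displace a domain by R_swing . R_twist about the channel frame, then
    translate; all other atoms untouched.  Ground-truth generator for the
    swing-twist recovery tests."""
    work = model if (model.protomer >= 0).any() else assign_protomers(model, registry=registry)
    frame = compute_channel_frame(work, registry)
    mask = np.zeros(work.n_atoms, bool)
    for a, b in domain.ranges:
        mask |= (work.res_number >= a) & (work.res_number <= b)
    if mask.sum() < 3:
        raise DegenerateGeometryError("domain selects fewer than 3 atoms")
    sv = np.linalg.svd(work.xyz[mask] - work.xyz[mask].mean(axis=0),
                       compute_uv=False)
    if sv[1] <= 1e-8 * max(sv[0], 1.0):
        raise DegenerateGeometryError("domain atoms are collinear")

    R_twist = rotation_about_axis(frame.axis_u, twist_deg)
    s_axis = (np.cos(np.radians(swing_axis_azimuth_deg)) * frame.e1 +
              np.sin(np.radians(swing_axis_azimuth_deg)) * frame.e2)
    R_swing = rotation_about_axis(s_axis, swing_deg)
    R = R_swing @ R_twist
    t = np.asarray(translation, float)

    out = work.copy()
    out.xyz[mask] = (out.xyz[mask] - frame.origin) @ R.T + frame.origin + t
    return out


def build_flexion_fixture(angle_deg: float,
                          inner_residue: int = 348,
                          outer_residue: int = 984) -> StructureModel:
    """C4 tetramer whose inner->outer marker diagonal makes exactly
    ``angle_deg`` with the plane perpendicular to the channel axis
    (negative = outer marker displaced toward the membrane/luminal side)."""
    if abs(angle_deg) >= 90.0:
        raise ValueError("flexion fixture angle must satisfy |angle| < 90")
    a = np.radians(angle_deg)
    L = 80.0
    r_inner = 40.0
    z_inner = 30.0
    atoms: list[AtomRecord] = []
    serial = 1
    for ci, chain in enumerate(_CHAINS):
        phi = np.radians(ci * 90.0)
        radial = np.array([np.cos(phi), np.sin(phi), 0.0])
        inner = r_inner * radial + np.array([0.0, 0.0, z_inner])
        outer = inner + L * np.cos(a) * radial + np.array([0.0, 0.0, L * np.sin(a)])
        for resnum, pos in ((inner_residue, inner), (outer_residue, outer)):
            atoms.append(AtomRecord(serial, "CA", "C", "", resnum, "", "GLY",
                                    chain, -1, pos))
            serial += 1
        # minimal pore region below the shell, to orient the frame
        for j, resnum in enumerate((4900, 4937, 4960)):
            phi_j = np.radians(ci * 90.0 + 10.0 * j)
            pos = np.array([6.0 * np.cos(phi_j), 6.0 * np.sin(phi_j), -5.0 + 2.5 * j])
            atoms.append(AtomRecord(serial, "CA", "C", "", resnum, "", "GLY",
                                    chain, -1, pos))
            serial += 1
    model = StructureModel.from_atoms(atoms, id=f"flexion_{angle_deg:+g}deg")
    return assign_protomers(model)


# ---------------------------------------------------------------------------
# Interaction fixtures (full side chains)
# ---------------------------------------------------------------------------

_BACKBONE = {"N", "CA", "C", "O", "OXT"}


def _template(res_name: str) -> tuple[list[str], list[str], np.ndarray]:
    """Heavy-atom names, elements and coordinates of an idealised residue."""
    import biotite.structure.info as info
    try:
        res = info.residue(res_name.upper())
    except KeyError as exc:
        raise ValueError(f"unknown residue name {res_name!r}") from exc
    if res is None:
        raise ValueError(f"unknown residue name {res_name!r}")
    keep = res.element != "H"
    return (list(res.atom_name[keep]), list(res.element[keep]),
            np.asarray(res.coord[keep], float))


def _align(v_from: np.ndarray, v_to: np.ndarray) -> np.ndarray:
    """Rotation taking unit vector v_from to v_to."""
    a = v_from / np.linalg.norm(v_from)
    b = v_to / np.linalg.norm(v_to)
    c = np.cross(a, b)
    d = float(a @ b)
    if np.linalg.norm(c) < 1e-12:
        if d > 0:
            return np.eye(3)
        # antiparallel: rotate 180 about any perpendicular
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a @ perp) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, perp)
        axis /= np.linalg.norm(axis)
        return rotation_about_axis(axis, 180.0)
    K = np.array([[0, -c[2], c[1]], [c[2], 0, -c[0]], [-c[1], c[0], 0]])
    return np.eye(3) + K + K @ K / (1.0 + d)


def _oriented(res_name: str, face: np.ndarray) -> tuple[list[str], list[str], np.ndarray]:
    """Residue template rotated so its side chain points along ``face``,
    positioned with Calpha at the origin."""
    names, elements, coords = _template(res_name)
    ca = coords[names.index("CA")]
    coords = coords - ca
    sc = np.array([c for nm, c in zip(names, coords) if nm not in _BACKBONE])
    if len(sc) == 0:
        raise ValueError(f"residue {res_name} has no side-chain heavy atoms")
    direction = sc.mean(axis=0)
    if np.linalg.norm(direction) < 1e-9:
        direction = np.array([1.0, 0.0, 0.0])
    R = _align(direction, face)
    return names, elements, coords @ R.T


def build_interaction_fixture(
        pairs: list[tuple[str, str, float, bool]]) -> StructureModel:
    """Place residue pairs at controlled minimal side-chain distances.

    Each entry is (residue_name_a, residue_name_b, min_heavy_atom_distance,
    same_protomer).  Side chains face each other and residue B is slid
    along the approach line until the minimal inter-side-chain heavy-atom
    distance equals the request to within 1e-4 A.  Inter-subunit pairs are
    split across chains A (protomer 0) and B (protomer 1).
    """
    atoms: list[AtomRecord] = []
    serial = 1
    for pi, (name_a, name_b, dist, same_protomer) in enumerate(pairs):
        if dist < 1.0:
            raise ValueError(f"requested distance {dist} below 1.0 A")
        base = np.array([0.0, 45.0 * pi, 0.0])
        names_a, elems_a, coords_a = _oriented(name_a, np.array([1.0, 0.0, 0.0]))
        names_b, elems_b, coords_b = _oriented(name_b, np.array([-1.0, 0.0, 0.0]))
        sc_a = np.array([c for nm, c in zip(names_a, coords_a)
                         if nm not in _BACKBONE])
        sc_b0 = np.array([c for nm, c in zip(names_b, coords_b)
                          if nm not in _BACKBONE])

        def gap(t: float) -> float:
            sc_b = sc_b0 + np.array([t, 0.0, 0.0])
            d = np.linalg.norm(sc_a[:, None, :] - sc_b[None, :, :], axis=2)
            return float(d.min()) - dist

        # outermost crossing: scan inward from a clearly separated placement
        t_hi = 60.0
        t_star = None
        for t in np.arange(t_hi - 0.25, -30.0, -0.25):
            if gap(t) <= 0.0:
                t_star = brentq(gap, t, t + 0.25, xtol=1e-6)
                break
        if t_star is None:
            raise ValueError(
                f"could not realise distance {dist} A for {name_a}-{name_b}")
        offset_b = np.array([t_star, 0.0, 0.0])

        chain_b = "A" if same_protomer else "B"
        prot_b = 0 if same_protomer else 1
        res_a = 10 + 2 * pi
        res_b = 11 + 2 * pi
        for nm, el, c in zip(names_a, elems_a, coords_a):
            atoms.append(AtomRecord(serial, nm, el, "", res_a, "",
                                    name_a.upper(), "A", 0, c + base))
            serial += 1
        for nm, el, c in zip(names_b, elems_b, coords_b):
            atoms.append(AtomRecord(serial, nm, el, "", res_b, "",
                                    name_b.upper(), chain_b, prot_b,
                                    c + base + offset_b))
            serial += 1
    return StructureModel.from_atoms(atoms, id="interaction_fixture")


# ---------------------------------------------------------------------------
# Composite conformation-state fixtures
# ---------------------------------------------------------------------------

def _helix_trace(start_res: int, end_res: int, pi_range: tuple[int, int] | None,
                 origin: np.ndarray, azimuth_deg: float) -> list[tuple[int, np.ndarray]]:
    """Calpha trace with alpha twist (100 deg) except an optional pi
    segment (81.8 deg); the local helix axis runs along z at ``origin``."""
    n = end_res - start_res + 1
    twists = np.full(n, 100.0)
    if pi_range is not None:
        for i, res in enumerate(range(start_res, end_res + 1)):
            if pi_range[0] <= res <= pi_range[1]:
                twists[i] = 81.8
    phases = np.radians(azimuth_deg + np.concatenate([[0.0], np.cumsum(twists[:-1])]))
    out = []
    for i, res in enumerate(range(start_res, end_res + 1)):
        pos = origin + np.array([2.3 * np.cos(phases[i]),
                                 2.3 * np.sin(phases[i]), 1.5 * i])
        out.append((res, pos))
    return out


def build_conformation_fixture(gate_ca_diameter: float = 10.7,
                               flexion_deg: float = -2.2,
                               salt_bridges: bool = False,
                               ca_ion: bool = False,
                               s6_pi: bool = False,
                               bridge_distance: float = 3.3) -> StructureModel:
    """Minimal C4 channel mimic carrying the classification hallmarks.

    Composes, per protomer: flexion anchor markers (348/984), a gate
    Calpha ring of the requested diagonal diameter with an oxygen lining
    ring, optionally the two EF-hand/S2-S3-loop inter-subunit salt-bridge
    pairs (Glu4075-Arg4736, Lys4101-Asp4730) at ``bridge_distance``,
    optionally a Ca ion coordinated by Glu3893/Glu3967/Thr5001 side
    chains, and optionally an S6-like helix trace with a pi segment at
    residues 4921-4928.  One asymmetric unit is built and replicated by
    exact 90-degree rotations, so the fixture is exactly C4-symmetric.
    """
    a = np.radians(flexion_deg)
    L, r_inner, z_inner = 80.0, 40.0, 30.0
    gate_r = gate_ca_diameter / 2.0
    lining_r = max(gate_r - 1.0, 1.0)

    # asymmetric unit: (name, element, resnum, resname, chain_offset, pos, het)
    unit: list[tuple] = []

    def add(name, element, resnum, resname, pos, offset=0, hetero=False):
        unit.append((name, element, resnum, resname, offset,
                     np.asarray(pos, float), hetero))

    def add_residue(resname, resnum, tip_point, approach_dir, tip_gap,
                    offset=0):
        """Full-side-chain residue with its side-chain tip ``tip_gap``
        before ``tip_point`` along ``approach_dir``."""
        names, elems, coords = _oriented(resname, approach_dir)
        sc = np.array([c for nm, c in zip(names, coords) if nm not in _BACKBONE])
        tip = sc[np.argmax(sc @ approach_dir)]
        shift = tip_point - tip_gap * approach_dir - tip
        for nm, el, c in zip(names, elems, coords):
            add(nm, el, resnum, resname, c + shift, offset=offset)

    # flexion anchors
    radial = np.array([1.0, 0.0, 0.0])
    inner = r_inner * radial + np.array([0.0, 0.0, z_inner])
    outer = inner + L * np.cos(a) * radial + np.array([0.0, 0.0, L * np.sin(a)])
    add("CA", "C", 348, "GLY", inner)
    add("CA", "C", 984, "GLY", outer)

    # gate Calpha marker and oxygen lining rings
    add("CA", "C", 4937, "GLY",
        [gate_r * np.cos(np.pi / 4), gate_r * np.sin(np.pi / 4), 0.0])
    for j, resnum in ((-1, 4936), (0, 4935), (1, 4938)):
        radius = lining_r + 1.65 if j == 0 else lining_r + 4.0
        for i in range(4):
            ang = np.radians((i + 0.5) * 22.5)
            add(f"O{i+1}", "O", resnum, "GLY",
                [radius * np.cos(ang), radius * np.sin(ang), 1.5 * j])

    if s6_pi:
        # S6-like trace ending before the gate-ring residues (4935-4938)
        hx_origin = np.array([8.0 * np.cos(np.pi / 3),
                              8.0 * np.sin(np.pi / 3), -22.0])
        for res, pos in _helix_trace(4908, 4932, (4921, 4928), hx_origin, 0.0):
            add("CA", "C", res, "ALA", pos)

    if salt_bridges:
        # EF-hand side on this protomer, S2-S3-loop side on the next one,
        # meeting at the inter-subunit interface (azimuth +45 deg)
        mid_phi = np.pi / 4
        for pair_i, (res_a, name_a, res_b, name_b) in enumerate(
                ((4075, "GLU", 4736, "ARG"), (4101, "LYS", 4730, "ASP"))):
            center = np.array([30.0 * np.cos(mid_phi),
                               30.0 * np.sin(mid_phi), 12.0 + 14.0 * pair_i])
            tangent = np.array([-np.sin(mid_phi), np.cos(mid_phi), 0.0])
            add_residue(name_a, res_a, center, tangent, bridge_distance / 2.0)
            add_residue(name_b, res_b, center, -tangent, bridge_distance / 2.0,
                        offset=1)

    if ca_ion:
        ion_pos = np.array([22.0 * np.cos(np.pi / 8),
                            22.0 * np.sin(np.pi / 8), 18.0])
        for li, (resnum, resname) in enumerate(
                ((3893, "GLU"), (3967, "GLU"), (5001, "THR"))):
            ang = np.radians(120.0 * li)
            direction = np.array([np.cos(ang), np.sin(ang), 0.0])
            add_residue(resname, resnum, ion_pos, -direction, 2.5)
        add("CA", "Ca", 5101, "CA", ion_pos, hetero=True)

    atoms: list[AtomRecord] = []
    serial = 0
    for k in range(4):
        R = rotation_about_axis(np.array([0.0, 0.0, 1.0]), 90.0 * k)
        for name, element, resnum, resname, offset, pos, hetero in unit:
            serial += 1
            atoms.append(AtomRecord(serial, name, element, "", resnum, "",
                                    resname, _CHAINS[(k + offset) % 4], -1,
                                    R @ pos, is_hetero=hetero))
    model = StructureModel.from_atoms(
        atoms, id=f"state_gate{gate_ca_diameter:g}_flex{flexion_deg:+g}")
    return assign_protomers(model)
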