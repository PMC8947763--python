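"""C4 protomer assignment and channel reference frame.

The tetramer's symmetry axis defines the "vertical" of every signed
measurement in the package: the axis unit vector points from the luminal
side (pore region) toward the cytoplasmic assembly, in-plane rotations are
positive counterclockwise when viewed from the cytoplasmic side, and the
flexion "horizontal plane" is the plane perpendicular to it.

The axis is found from the least-squares rotation that maps each protomer
onto the next (a single Kabsch fit over the concatenated correspondences
P0->P1, P1->P2, P2->P3, P3->P0); for a C4-symmetric structure this
rotation is exactly the 90-degree symmetry operation and its axis the
symmetry axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .domains import DomainRegistry
from .errors import DegenerateGeometryError, SymmetryError
from .model import StructureModel
from .superpose import kabsch_fit

__all__ = ["ChannelFrame", "assign_protomers", "compute_channel_frame",
           "rotation_about_axis", "c4_rotation_residual"]


@dataclass(frozen=True)
class ChannelFrame:
    """Channel symmetry axis, origin, and cyclic protomer order.

    ``axis_u`` is a unit vector pointing luminal -> cytoplasmic.  Rotating
    protomer ``protomer_cycle[k]`` by +90 degrees (right-hand rule about
    ``axis_u``) superposes it onto ``protomer_cycle[k+1]``.  ``e1``/``e2``
    complete a right-handed orthonormal basis and give azimuths a
    deterministic zero.
    """

    origin: np.ndarray
    axis_u: np.ndarray
    protomer_cycle: tuple[int, int, int, int]
    e1: np.ndarray
    e2: np.ndarray
    c4_residual: float = 0.0

    def __post_init__(self) -> None:
        u = np.asarray(self.axis_u, float)
        if abs(np.linalg.norm(u) - 1.0) > 1e-9:
            raise ValueError("axis_u must be a unit vector")
        object.__setattr__(self, "axis_u", u)
        object.__setattr__(self, "origin", np.asarray(self.origin, float))
        object.__setattr__(self, "e1", np.asarray(self.e1, float))
        object.__setattr__(self, "e2", np.asarray(self.e2, float))

    def azimuth_deg(self, point: np.ndarray) -> float:
        """Azimuth of a point about the axis, degrees in (-180, 180]."""
        v = np.asarray(point, float) - self.origin
        return float(np.degrees(np.arctan2(v @ self.e2, v @ self.e1)))


def rotation_about_axis(axis_u: np.ndarray, angle_deg: float) -> np.ndarray:
    """Right-hand rotation matrix by ``angle_deg`` about a unit axis."""
    u = np.asarray(axis_u, float)
    u = u / np.linalg.norm(u)
    a = np.radians(angle_deg)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def _perpendicular_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(u @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - (ref @ u) * u
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2


def _provisional_axis(model: StructureModel, chains: list[str]) -> np.ndarray:
    """Unoriented axis estimate: normal of the best-fit plane through the
    chain Calpha centroids (they form a square perpendicular to the axis)."""
    cents = []
    ca = model.ca_mask
    for c in chains:
        m = ca & model.chain_mask(c)
        if not m.any():
            m = model.chain_mask(c) & ~model.is_hetero
        if not m.any():
            continue
        cents.append(model.xyz[m].mean(axis=0))
    cents = np.asarray(cents)
    if len(cents) < 3:
        raise DegenerateGeometryError("need >= 3 chain centroids for axis estimate")
    centered = cents - cents.mean(axis=0)
    _, sv, Vt = np.linalg.svd(centered)
    if sv[1] <= 1e-8 * max(sv[0], 1.0):
        raise DegenerateGeometryError("chain centroids are collinear")
    return Vt[2] / np.linalg.norm(Vt[2])


def _orient_axis(model: StructureModel, axis: np.ndarray,
                 registry: DomainRegistry | None) -> np.ndarray:
    """Flip the axis so it points luminal -> cytoplasmic.

    Rule: from the pore-region Calpha centroid toward the centroid of all
    remaining Calpha (the cytoplasmic assembly holds most of the mass).
    When no pore-region residues exist the +z hemisphere is kept, which
    suits synthetic fixtures built about z.
    """
    registry = registry or DomainRegistry()
    pore = registry["pore_region"]
    ca = model.ca_mask
    in_pore = np.zeros(model.n_atoms, bool)
    for a, b in pore.ranges:
        in_pore |= (model.res_number >= a) & (model.res_number <= b)
    pore_ca = ca & in_pore
    rest_ca = ca & ~in_pore
    if pore_ca.any() and rest_ca.any():
        direction = model.xyz[rest_ca].mean(axis=0) - model.xyz[pore_ca].mean(axis=0)
        if direction @ axis < 0:
            axis = -axis
    else:
        for comp in (2, 1, 0):
            if abs(axis[comp]) > 1e-9:
                if axis[comp] < 0:
                    axis = -axis
                break
    return axis


def assign_protomers(model: StructureModel,
                     frame_hint: ChannelFrame | None = None,
                     registry: DomainRegistry | None = None) -> StructureModel:
    """Assign protomer indices 0-3 to chains, cyclic counterclockwise as
    viewed from the cytoplasmic side; protomer 0 is the first protein chain
    in file order.  Ligand chains are indexed with the protein chain they
    share an identifier with, else left unassigned (-1)."""
    chains = model.chains()
    order = model.symmetry_order
    if len(chains) == 0:
        raise SymmetryError("no protein chains in model")
    if len(chains) % order != 0:
        raise SymmetryError(
            f"{len(chains)} protein chains not divisible by symmetry order {order}")
    if frame_hint is not None:
        axis = frame_hint.axis_u
    else:
        axis = _provisional_axis(model, chains)
        axis = _orient_axis(model, axis, registry)
    e1, e2 = _perpendicular_basis(axis)

    ca = model.ca_mask
    center = model.xyz[ca].mean(axis=0) if ca.any() else model.xyz.mean(axis=0)
    az = {}
    for c in chains:
        m = ca & model.chain_mask(c)
        if not m.any():
            m = model.chain_mask(c) & ~model.is_hetero
        v = model.xyz[m].mean(axis=0) - center
        az[c] = np.degrees(np.arctan2(v @ e2, v @ e1))

    per_protomer = len(chains) // order
    az0 = az[chains[0]]
    chain_protomer: dict[str, int] = {}
    if per_protomer == 1:
        # counterclockwise about +axis = increasing azimuth
        for c in chains:
            rel = (az[c] - az0) % 360.0
            k = int(np.round(rel / 90.0)) % order
            if abs(rel - 90.0 * np.round(rel / 90.0)) > 30.0:
                raise SymmetryError(
                    f"chain {c}: azimuth {rel:.1f} deg not near a multiple of 90")
            if k in chain_protomer.values() and chain_protomer.get(c) != k:
                pass
            chain_protomer[c] = k
        if sorted(chain_protomer.values()) != list(range(order)):
            raise SymmetryError("chains do not occupy distinct 90-degree sectors")
    else:
        # several chains per protomer: bin into quadrants anchored on chain 0
        for c in chains:
            rel = (az[c] - az0 + 45.0) % 360.0
            chain_protomer[c] = int(rel // 90.0) % order

    out = model.copy()
    for c, k in chain_protomer.items():
        out.protomer[out.chain_id == c] = k
    # carry ligand/water chains that reuse a protein chain id
    return out


def compute_channel_frame(model: StructureModel,
                          registry: DomainRegistry | None = None) -> ChannelFrame:
    """Symmetry axis, origin and cyclic protomer order of the tetramer.

    Requires protomers assigned.  The origin is the pore-region Calpha
    centroid (whole-assembly centroid when the model has no pore-region
    residues, as in generic fixtures).
    """
    registry = registry or DomainRegistry()
    if not (model.protomer >= 0).any():
        raise SymmetryError("protomers not assigned; call assign_protomers first")
    order = model.symmetry_order

    # correspondences between consecutive protomers over common Calpha keys
    ca = model.ca_mask
    maps = []
    for k in range(order):
        d = {}
        idx = np.nonzero(ca & (model.protomer == k))[0]
        for i in idx:
            d[(int(model.res_number[i]), str(model.icode[i]), str(model.name[i]))] = \
                model.xyz[i]
        maps.append(d)
    common = set(maps[0])
    for d in maps[1:]:
        common &= set(d)
    common = sorted(common)
    if len(common) < 3:
        raise SymmetryError("fewer than 3 Calpha atoms shared by all protomers")
    P = [np.array([maps[k][key] for key in common]) for k in range(order)]

    X = np.concatenate([P[k] for k in range(order)])
    Y = np.concatenate([P[(k + 1) % order] for k in range(order)])
    fit = kabsch_fit(X, Y)
    R, t = fit.rotation, fit.translation

    # rotation axis of R (eigenvector for eigenvalue +1)
    w, V = np.linalg.eig(R)
    axis = np.real(V[:, np.argmin(np.abs(w - 1.0))])
    axis /= np.linalg.norm(axis)
    axis = _orient_axis(model, axis, registry)

    # origin: point on the axis; least-squares fixed point of the screw
    # restricted to the plane perpendicular to the axis
    A = np.eye(3) - R
    c = np.linalg.lstsq(A + np.outer(axis, axis), t, rcond=None)[0]

    pore = registry["pore_region"]
    in_pore = np.zeros(model.n_atoms, bool)
    for a, b in pore.ranges:
        in_pore |= (model.res_number >= a) & (model.res_number <= b)
    pore_ca = ca & in_pore
    if pore_ca.any():
        origin_raw = model.xyz[pore_ca].mean(axis=0)
    else:
        origin_raw = model.xyz[ca].mean(axis=0)
    # place the origin on the symmetry axis at the height of that centroid
    origin = c + ((origin_raw - c) @ axis) * axis

    e1, e2 = _perpendicular_basis(axis)

    # does +90 about axis_u map protomer k onto k+1, or onto k-1?
    R90 = rotation_about_axis(axis, 90.0)
    fwd = np.sqrt(np.mean(np.sum(
        ((P[0] - origin) @ R90.T + origin - P[1]) ** 2, axis=1)))
    bwd = np.sqrt(np.mean(np.sum(
        ((P[0] - origin) @ R90.T + origin - P[order - 1]) ** 2, axis=1)))
    cycle = (0, 1, 2, 3) if fwd <= bwd else (0, 3, 2, 1)

    frame = ChannelFrame(origin=origin, axis_u=axis, protomer_cycle=cycle,
                         e1=e1, e2=e2)
    residual = c4_rotation_residual(model, frame)
    return ChannelFrame(origin=origin, axis_u=axis, protomer_cycle=cycle,
                        e1=e1, e2=e2, c4_residual=residual)


def c4_rotation_residual(model: StructureModel, frame: ChannelFrame) -> float:
    """RMSD between each protomer rotated by +90 degrees and its successor."""
    ca = model.ca_mask
    order = model.symmetry_order
    maps = []
    for k in range(order):
        d = {}
        idx = np.nonzero(ca & (model.protomer == k))[0]
        for i in idx:
            d[(int(model.res_number[i]), str(model.icode[i]), str(model.name[i]))] = \
                model.xyz[i]
        maps.append(d)
    common = sorted(set.intersection(*[set(d) for d in maps]))
    if not common:
        raise SymmetryError("no shared Calpha atoms across protomers")
    R90 = rotation_about_axis(frame.axis_u, 90.0)
    sq = 0.0
    n = 0
    cyc = frame.protomer_cycle
    for j in range(order):
        src = np.array([maps[cyc[j]][key] for key in common])
        dst = np.array([maps[cyc[(j + 1) % order]][key] for key in common])
        rotated = (src - frame.origin) @ R90.T + frame.origin
        sq += float(((rotated - dst) ** 2).sum())
        n += len(common)
    return float(np.sqrt(sq / n))
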