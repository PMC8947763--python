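"""Rigid-motion decomposition and the cytoplasmic-shell flexion angle.

Inter-state domain motions are reported as an in-plane component (twist
about the channel axis, positive counterclockwise viewed from the
cytoplasmic side) and an out-of-plane component (swing about an axis
perpendicular to the channel axis), obtained from the quaternion
swing-twist decomposition R = R_swing . R_twist.  The decomposition is
unique for any proper rotation; the degenerate case of a 180-degree
rotation about a perpendicular axis is resolved by zero twist.

The flexion angle quantifies the tilt of the cytoplasmic shell: per
protomer, the angle between the intra-subunit diagonal from an inner
anchor residue to an outer (peripheral) anchor residue and the plane
perpendicular to the channel axis.  Negative values mean the peripheral
anchor is bent toward the membrane, the convention under which channel
opening makes the angle more negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .domains import DomainDefinition, DomainRegistry
from .errors import TetraporeError
from .frame import ChannelFrame, compute_channel_frame
from .model import StructureModel
from .superpose import kabsch_fit, shared_calpha

__all__ = ["RigidMotion", "FlexionResult", "swing_twist_decompose",
           "domain_motion", "flexion_angle"]


@dataclass(frozen=True)
class RigidMotion:
    """Swing-twist decomposition of a domain's inter-state motion."""

    twist_deg: float            # about axis_u, CCW from cytoplasmic side > 0
    swing_deg: float            # >= 0, about an axis perpendicular to axis_u
    swing_axis_azimuth_deg: float
    swing_sign: int             # +1 when the centroid moves cytoplasmic-ward
    translation: np.ndarray     # centroid displacement, Angstrom
    rmsd: float                 # post-fit domain RMSD
    n_atoms: int
    source_id: str = ""
    target_id: str = ""


@dataclass(frozen=True)
class FlexionResult:
    per_protomer: tuple[float, float, float, float]
    mean: float
    inner_residue: int
    outer_residue: int
    axis_u: np.ndarray


def _quat_from_matrix(R: np.ndarray) -> np.ndarray:
    """Unit quaternion (w, x, y, z) of a proper rotation matrix."""
    from scipy.spatial.transform import Rotation
    x, y, z, w = Rotation.from_matrix(R).as_quat()
    return np.array([w, x, y, z])


def swing_twist_decompose(R: np.ndarray, axis: np.ndarray
                          ) -> tuple[float, float, float]:
    """Decompose R = R_swing . R_twist about a unit axis.

    Returns (twist_deg, swing_deg, swing_axis_azimuth_deg); twist is signed
    in (-180, 180], swing in [0, 180].  The azimuth of the swing axis is
    measured in a deterministic perpendicular basis of ``axis``.
    """
    R = np.asarray(R, float)
    if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8) \
            or np.linalg.det(R) < 0:
        raise ValueError("R must be a proper rotation matrix")
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    q = _quat_from_matrix(R)
    w, v = q[0], q[1:]
    proj = float(v @ a)
    norm = np.hypot(w, proj)
    if norm < 1e-12:
        # 180-degree rotation about an axis perpendicular to `axis`
        twist = 0.0
        q_t = np.array([1.0, 0.0, 0.0, 0.0])
    else:
        q_t = np.array([w, *(proj * a)]) / norm
        twist = float(np.degrees(2.0 * np.arctan2(proj, w)))
    # q_s = q * conj(q_t)
    wt, vt = q_t[0], q_t[1:]
    w_s = w * wt + float(v @ vt)
    v_s = -w * vt + wt * v + np.cross(v, -vt)
    swing = float(np.degrees(2.0 * np.arctan2(np.linalg.norm(v_s), w_s)))
    if swing > 180.0:
        swing = 360.0 - swing
    if twist <= -180.0:
        twist += 360.0
    elif twist > 180.0:
        twist -= 360.0
    # azimuth of swing axis in the perpendicular basis
    from .frame import _perpendicular_basis
    e1, e2 = _perpendicular_basis(a)
    if np.linalg.norm(v_s) > 1e-12:
        s_axis = v_s / np.linalg.norm(v_s)
        azimuth = float(np.degrees(np.arctan2(s_axis @ e2, s_axis @ e1)))
    else:
        azimuth = 0.0
    return twist, swing, azimuth


def recompose(twist_deg: float, swing_deg: float, azimuth_deg: float,
              axis: np.ndarray) -> np.ndarray:
    """Inverse of :func:`swing_twist_decompose` (used by the tests)."""
    from .frame import _perpendicular_basis, rotation_about_axis
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    e1, e2 = _perpendicular_basis(a)
    s_axis = np.cos(np.radians(azimuth_deg)) * e1 + \
        np.sin(np.radians(azimuth_deg)) * e2
    return rotation_about_axis(s_axis, swing_deg) @ rotation_about_axis(a, twist_deg)


def domain_motion(A: StructureModel, B: StructureModel,
                  domain: DomainDefinition,
                  frame: ChannelFrame | None = None,
                  frame_selection: DomainDefinition | None = None,
                  registry: DomainRegistry | None = None) -> RigidMotion:
    """Rigid motion of a domain between states A and B.

    B is first placed in A's frame by superposing ``frame_selection``
    (default: all shared Calpha); the Kabsch fit of the domain A -> B then
    gives the rotation, decomposed swing-twist about A's channel axis.
    """
    if frame is None:
        frame = compute_channel_frame(A, registry)
    FA, FB, _ = shared_calpha(A, B, frame_selection, None)
    global_fit = kabsch_fit(FB, FA)
    XA, XB, _ = shared_calpha(A, B, domain, None)
    XB = global_fit.apply(XB)
    fit = kabsch_fit(XA, XB)
    twist, swing, azim = swing_twist_decompose(fit.rotation, frame.axis_u)
    centroid_shift = XB.mean(axis=0) - XA.mean(axis=0)
    axial = float(centroid_shift @ frame.axis_u)
    sign = 1 if axial >= 0 else -1
    post = fit.apply(XA)
    rmsd = float(np.sqrt(((post - XB) ** 2).sum() / len(XA)))
    return RigidMotion(twist_deg=twist, swing_deg=swing,
                       swing_axis_azimuth_deg=azim, swing_sign=sign,
                       translation=centroid_shift, rmsd=rmsd, n_atoms=len(XA),
                       source_id=A.id, target_id=B.id)


def flexion_angle(model: StructureModel,
                  frame: ChannelFrame | None = None,
                  inner: int = 348, outer: int = 984,
                  registry: DomainRegistry | None = None) -> FlexionResult:
    """Signed tilt of the cytoplasmic shell, per protomer and averaged.

    angle_k = arcsin( d_hat . axis_u ) with d = Calpha(outer) - Calpha(inner)
    of protomer k; negative = peripheral anchor displaced membrane-ward.
    """
    if frame is None:
        frame = compute_channel_frame(model, registry)
    u = frame.axis_u
    angles = []
    ca = model.ca_mask
    for k in range(model.symmetry_order):
        vals = {}
        for res in (inner, outer):
            m = ca & (model.protomer == k) & (model.res_number == res)
            if not m.any():
                raise TetraporeError(
                    f"protomer {k}: no Calpha for anchor residue {res}")
            vals[res] = model.xyz[m].mean(axis=0)
        d = vals[outer] - vals[inner]
        d = d / np.linalg.norm(d)
        angles.append(float(np.degrees(np.arcsin(np.clip(d @ u, -1.0, 1.0)))))
    return FlexionResult(per_protomer=tuple(angles),
                         mean=float(np.mean(angles)),
                         inner_residue=inner, outer_residue=outer, axis_u=u)
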