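"""Least-squares rigid superposition and multi-regime domain RMSD.

Conformational differences between two states of the tetramer are
decomposed per domain under three alignment regimes:

* ``prealigned``  -- the domain itself is Kabsch-fitted pairwise before the
  RMSD is taken; measures internal (conformational) change only.
* ``unaligned``   -- the two models are first placed in a common frame by
  superposing a frame selection (default: every shared Calpha of the whole
  assembly); the domain RMSD then includes rigid repositioning.
* ``cd_aligned``  -- the protomer is superposed through an anchor domain
  (default: the central domain CD); the domain RMSD then measures motion
  relative to that anchor.

``unaligned - prealigned`` estimates the rigid shift of the domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .domains import AnalysisConfig, DomainDefinition, DomainRegistry
from .errors import DegenerateGeometryError
from .model import StructureModel

__all__ = ["SuperpositionResult", "RmsdHeatmap", "kabsch_fit",
           "rmsd_prealigned", "rmsd_in_frame", "rmsd_cd_aligned", "rmsd_heatmap"]


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal proper-rotation superposition of paired coordinate sets."""

    rotation: np.ndarray      # 3x3, det +1; maps X onto Y
    translation: np.ndarray   # 3-vector
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_fit(X: np.ndarray, Y: np.ndarray) -> SuperpositionResult:
    """Proper rotation R and translation t minimising RMSD(R X + t, Y).

    ``X`` and ``Y`` are paired (n, 3) arrays, n >= 3, non-collinear.
    Reflections are excluded by the determinant correction.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.shape != Y.shape:
        raise ValueError(f"paired sets differ in shape: {X.shape} vs {Y.shape}")
    if X.ndim != 2 or X.shape[1] != 3 or X.shape[0] < 3:
        raise ValueError("need at least 3 paired 3-D points")
    xc = X.mean(axis=0)
    yc = Y.mean(axis=0)
    Xc = X - xc
    Yc = Y - yc
    sv = np.linalg.svd(Xc, compute_uv=False)
    if sv[1] <= 1e-8 * max(sv[0], 1.0):
        raise DegenerateGeometryError("collinear point set: rotation not unique")
    H = Xc.T @ Yc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    diff = Xc @ R.T - Yc
    rmsd = float(np.sqrt((diff ** 2).sum() / len(X)))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_atoms=len(X))


# ---------------------------------------------------------------------------
# Shared-Calpha extraction
# ---------------------------------------------------------------------------

def _ca_index(model: StructureModel, ranges=None, protomer: int | None = None):
    """Map (protomer, residue number, icode) -> xyz for Calpha atoms."""
    mask = model.ca_mask
    if protomer is not None:
        mask = mask & (model.protomer == protomer)
    if ranges is not None:
        in_r = np.zeros(model.n_atoms, dtype=bool)
        for a, b in ranges:
            in_r |= (model.res_number >= a) & (model.res_number <= b)
        mask = mask & in_r
    idx = np.nonzero(mask)[0]
    out = {}
    for i in idx:
        key = (int(model.protomer[i]), int(model.res_number[i]), str(model.icode[i]))
        out.setdefault(key, model.xyz[i])
    return out


def shared_calpha(A: StructureModel, B: StructureModel,
                  domain: DomainDefinition | None = None,
                  protomer: int | None = None) -> tuple[np.ndarray, np.ndarray, list]:
    """Paired Calpha coordinates for residues resolved in both models."""
    ranges = domain.ranges if domain is not None else None
    da = _ca_index(A, ranges, protomer)
    db = _ca_index(B, ranges, protomer)
    keys = sorted(set(da) & set(db))
    if len(keys) < 3:
        raise DegenerateGeometryError(
            f"fewer than 3 shared Calpha atoms "
            f"(domain={getattr(domain, 'name', None)}, protomer={protomer})")
    XA = np.array([da[k] for k in keys])
    XB = np.array([db[k] for k in keys])
    return XA, XB, keys


def _plain_rmsd(X: np.ndarray, Y: np.ndarray) -> float:
    return float(np.sqrt(((X - Y) ** 2).sum() / len(X)))


# ---------------------------------------------------------------------------
# The three regimes
# ---------------------------------------------------------------------------

def rmsd_prealigned(A: StructureModel, B: StructureModel,
                    domain: DomainDefinition,
                    protomer: int | None = None) -> float:
    """Calpha RMSD after Kabsch-fitting the domain itself (pairwise)."""
    XA, XB, _ = shared_calpha(A, B, domain, protomer)
    return kabsch_fit(XA, XB).rmsd


def rmsd_in_frame(A: StructureModel, B: StructureModel,
                  domain: DomainDefinition,
                  frame_selection: DomainDefinition | None = None,
                  protomer: int | None = None) -> float:
    """'Unaligned' regime: common frame from ``frame_selection`` (default all
    shared Calpha of the assembly), then the domain RMSD without further fit."""
    FA, FB, _ = shared_calpha(A, B, frame_selection, None)
    fit = kabsch_fit(FB, FA)          # B -> A frame
    XA, XB, _ = shared_calpha(A, B, domain, protomer)
    return _plain_rmsd(XA, fit.apply(XB))


def rmsd_cd_aligned(A: StructureModel, B: StructureModel,
                    domain: DomainDefinition,
                    anchor: DomainDefinition,
                    protomer: int | None = 0) -> float:
    """Superpose the protomer through an anchor domain (CD by default
    upstream), then the unfitted Calpha RMSD of the domain."""
    FA, FB, _ = shared_calpha(A, B, anchor, protomer)
    fit = kabsch_fit(FB, FA)
    XA, XB, _ = shared_calpha(A, B, domain, protomer)
    return _plain_rmsd(XA, fit.apply(XB))


@dataclass
class RmsdHeatmap:
    """Per-domain RMSD under the three regimes plus the derived shift."""

    domains: list[str]
    prealigned: dict[str, float]
    unaligned: dict[str, float]
    cd_aligned: dict[str, float]
    repositioning: dict[str, float]
    shared_counts: dict[str, int]
    low_coverage: list[str] = field(default_factory=list)
    missing: list[str] = field(default_factory=list)
    frame_selection: str = "all_shared_calpha"

    def to_frame(self):
        import pandas as pd
        rows = []
        for d in self.domains:
            rows.append({
                "domain": d,
                "prealigned": self.prealigned.get(d, np.nan),
                "unaligned": self.unaligned.get(d, np.nan),
                "cd_aligned": self.cd_aligned.get(d, np.nan),
                "repositioning": self.repositioning.get(d, np.nan),
                "n_shared": self.shared_counts.get(d, 0),
            })
        return pd.DataFrame(rows)


def rmsd_heatmap(A: StructureModel, B: StructureModel,
                 registry: DomainRegistry,
                 domains: list[str] | None = None,
                 anchor: str = "CD",
                 frame_selection: DomainDefinition | None = None,
                 protomer: int | None = 0,
                 config: AnalysisConfig | None = None) -> RmsdHeatmap:
    """All three regimes for a list of registry domains.

    Domains lacking shared residues are recorded as missing rather than
    raising; domains where fewer than half of the defined residues are
    shared between the two models are flagged as low coverage.
    """
    if domains is None:
        domains = ["CD", "CTD", "EF_loops", "S2S3_loop", "pore_region"]
    result = RmsdHeatmap(domains=list(domains), prealigned={}, unaligned={},
                         cd_aligned={}, repositioning={}, shared_counts={},
                         frame_selection=(frame_selection.name if frame_selection
                                          else "all_shared_calpha"))
    anchor_def = registry[anchor]
    for name in domains:
        dom = registry[name]
        try:
            XA, XB, keys = shared_calpha(A, B, dom, protomer)
        except DegenerateGeometryError:
            result.missing.append(name)
            continue
        result.shared_counts[name] = len(keys)
        n_defined = dom.n_residues if protomer is not None else 4 * dom.n_residues
        if len(keys) < 0.5 * n_defined:
            result.low_coverage.append(name)
        pre = kabsch_fit(XA, XB).rmsd
        una = rmsd_in_frame(A, B, dom, frame_selection, protomer)
        cda = rmsd_cd_aligned(A, B, dom, anchor_def, protomer)
        result.prealigned[name] = pre
        result.unaligned[name] = una
        result.cd_aligned[name] = cda
        result.repositioning[name] = max(una - pre, 0.0)
    return result
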