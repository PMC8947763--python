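"""Solvent-accessible surface area by deterministic point sampling.

Shrake-Rupley style: each atom's solvent sphere (vdW radius + probe) is
covered with a fixed Fibonacci point set and the accessible fraction is
the share of points not buried inside any neighbour's solvent sphere.
The point set is deterministic, so areas are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .domains import AnalysisConfig
from .model import StructureModel

__all__ = ["SasaResult", "compute_sasa", "crevice_coverage"]


@dataclass
class SasaResult:
    per_atom: np.ndarray      # A^2, aligned with the model's atom order
    probe: float
    n_points: int

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())

    def total_of(self, mask: np.ndarray) -> float:
        return float(self.per_atom[mask].sum())


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n)
    golden = (1 + 5 ** 0.5) / 2
    theta = 2 * np.pi * k / golden
    z = 1 - 2 * (k + 0.5) / n
    s = np.sqrt(1 - z ** 2)
    return np.stack([s * np.cos(theta), s * np.sin(theta), z], axis=1)


def compute_sasa(model: StructureModel,
                 probe: float | None = None,
                 n_points: int | None = None,
                 config: AnalysisConfig | None = None) -> SasaResult:
    """Per-atom solvent-accessible area over all heavy atoms of the model.

    Raises KeyError for elements without a configured van der Waals radius.
    """
    config = config or AnalysisConfig()
    probe = probe if probe is not None else config.sasa_probe
    n_points = n_points if n_points is not None else config.sasa_points

    heavy = model.element != "H"
    idx = np.nonzero(heavy)[0]
    radii = np.array([config.vdw(model.element[i]) for i in idx]) + probe
    xyz = model.xyz[idx]
    sphere = _fibonacci_sphere(n_points)

    areas = np.zeros(model.n_atoms)
    if len(idx) == 0:
        return SasaResult(per_atom=areas, probe=probe, n_points=n_points)
    tree = cKDTree(xyz)
    rmax = radii.max()
    for a in range(len(idx)):
        pts = xyz[a] + radii[a] * sphere
        neigh = [b for b in tree.query_ball_point(xyz[a], radii[a] + rmax)
                 if b != a]
        accessible = np.ones(n_points, bool)
        for b in neigh:
            d = np.linalg.norm(pts - xyz[b], axis=1)
            # points exactly on a neighbour's surface (coincident/tangent
            # spheres) are kept by the lower-index atom only
            if b < a:
                accessible &= d > radii[b] + 1e-9
            else:
                accessible &= d >= radii[b] - 1e-9
            if not accessible.any():
                break
        frac = accessible.mean()
        areas[idx[a]] = frac * 4.0 * np.pi * radii[a] ** 2
    return SasaResult(per_atom=areas, probe=probe, n_points=n_points)


def crevice_coverage(model: StructureModel,
                     crevice_mask: np.ndarray,
                     lipid_mask: np.ndarray,
                     config: AnalysisConfig | None = None
                     ) -> tuple[float, float]:
    """Surface area of a crevice and the share of it buried by lipids.

    ``crevice_area``: SASA of the crevice atoms with the lipids absent.
    ``covered_area``: that area minus the same atoms' SASA with lipids
    present, i.e. the area the lipids occlude.
    """
    config = config or AnalysisConfig()
    crevice_mask = np.asarray(crevice_mask, bool)
    lipid_mask = np.asarray(lipid_mask, bool)
    if not crevice_mask.any() or crevice_mask[lipid_mask].any():
        if not crevice_mask.any():
            raise ValueError("crevice selection is empty")
        raise ValueError("crevice and lipid selections overlap")

    without = model.subset(~lipid_mask)
    res_no = compute_sasa(without, config=config)
    crev_in_without = crevice_mask[~lipid_mask]
    crevice_area = res_no.total_of(crev_in_without)

    res_with = compute_sasa(model, config=config)
    with_lipids = res_with.total_of(crevice_mask)
    covered = max(crevice_area - with_lipids, 0.0)
    return crevice_area, covered
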