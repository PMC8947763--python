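"""Shared fixtures: registries, configs and small C4 tetramer builders."""

from __future__ import annotations

import numpy as np
import pytest

from tetrapore import (AnalysisConfig, AtomRecord, DomainRegistry,
                       StructureModel, assign_protomers)
from tetrapore.frame import rotation_about_axis

# residue slabs used by the miniature tetramer; chosen inside the default
# registry domains so registry-driven analyses resolve them
MINI_RANGES = {
    "anchor_inner": (348, 348),
    "anchor_outer": (984, 984),
    "CD": (3668, 3697),
    "EF_loops": (4081, 4090),
    "S2S3_loop": (4664, 4683),
    "pore_region": (4821, 4850),
    "CTD": (4957, 4971),
}


@pytest.fixture
def registry() -> DomainRegistry:
    return DomainRegistry()


@pytest.fixture
def config() -> AnalysisConfig:
    return AnalysisConfig()


def make_ca_chain(start: int, end: int, chain: str = "A", seed: int = 0,
                  offset=(0.0, 0.0, 0.0)) -> StructureModel:
    """Single-chain Calpha random walk with one residue per number."""
    rng = np.random.default_rng(seed)
    n = end - start + 1
    steps = rng.normal(scale=1.2, size=(n, 3)) + np.array([0.5, 0.2, 0.3])
    coords = np.cumsum(steps, axis=0) + np.asarray(offset, float)
    atoms = [AtomRecord(i + 1, "CA", "C", "", start + i, "", "ALA", chain, -1,
                        coords[i]) for i in range(n)]
    return StructureModel.from_atoms(atoms, id=f"chain_{chain}")


def build_mini_tetramer(seed: int = 0) -> StructureModel:
    """Exactly C4-symmetric Calpha tetramer covering the registry domains.

    One protomer is drawn as seeded random clusters placed off-axis (the
    pore-region slab low, the cytoplasmic anchors high, so the frame
    orients +z), then replicated by 90-degree rotations.
    """
    rng = np.random.default_rng(seed)
    placements = {
        "anchor_inner": (np.array([40.0, 0.0, 30.0]), 0.1),
        "anchor_outer": (np.array([120.0, 0.0, 26.0]), 0.1),
        "CD": (np.array([35.0, 10.0, 22.0]), 3.0),
        "EF_loops": (np.array([28.0, 18.0, 14.0]), 2.0),
        "S2S3_loop": (np.array([24.0, -12.0, 8.0]), 2.5),
        "pore_region": (np.array([8.0, 3.0, -6.0]), 2.5),
        "CTD": (np.array([18.0, 6.0, 4.0]), 2.0),
    }
    unit = []
    for name, (lo, hi) in MINI_RANGES.items():
        center, spread = placements[name]
        for res in range(lo, hi + 1):
            unit.append((res, center + rng.normal(scale=spread, size=3)))
    atoms = []
    serial = 0
    for k, chain in enumerate("ABCD"):
        R = rotation_about_axis(np.array([0.0, 0.0, 1.0]), 90.0 * k)
        for res, pos in unit:
            serial += 1
            atoms.append(AtomRecord(serial, "CA", "C", "", res, "", "ALA",
                                    chain, -1, R @ pos))
    model = StructureModel.from_atoms(atoms, id=f"mini_{seed}")
    return assign_protomers(model)


@pytest.fixture
def mini_tetramer() -> StructureModel:
    return build_mini_tetramer(seed=0)
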