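"""Per-residue helical parameters from Calpha traces.

For each window of four consecutive Calpha atoms, the rigid screw
transform mapping (CA_i, CA_i+1, CA_i+2) onto (CA_i+1, CA_i+2, CA_i+3) is
fitted by Kabsch superposition; its rotation angle is the local twist per
residue and the translation component along the screw axis the local
rise.  On an ideal helix this fit is exact for any twist, rise and
radius.  Residues per turn (360/twist) are smoothed with a centered
moving window and classified into 3-10, alpha and pi ranges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError
from .superpose import kabsch_fit

__all__ = ["HelixGeometry", "screw_twist_profile", "residues_per_turn",
           "classify_helix", "helix_segments"]

# residues-per-turn class boundaries; canonical values are 3.0 (3-10),
# 3.6 (alpha) and 4.4 (pi), the thresholds bracket them
DEFAULT_THRESHOLDS = {"three_ten_max": 3.35, "alpha_max": 4.0}


@dataclass
class HelixGeometry:
    residue_numbers: np.ndarray      # residues carrying a window value
    twist_deg: np.ndarray            # per-residue local twist
    rise: np.ndarray                 # per-residue local rise, Angstrom
    residues_per_turn: np.ndarray    # smoothed 360/twist
    rpt_raw: np.ndarray              # unsmoothed 360/twist
    labels: list[str] | None = None  # three_ten | alpha | pi | irregular

    @property
    def n(self) -> int:
        return len(self.residue_numbers)


def screw_twist_profile(trace: np.ndarray,
                        residue_numbers: np.ndarray | None = None
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Local (twist_deg, rise) for each 4-Calpha window of a trace.

    The value is assigned to the window's central bond, labelled by the
    residue number of the window's second Calpha.  Collinear windows yield
    NaN (downstream label: irregular).
    """
    trace = np.asarray(trace, float)
    if trace.ndim != 2 or trace.shape[1] != 3 or len(trace) < 4:
        raise ValueError("need an (n, 3) Calpha trace with n >= 4")
    n = len(trace)
    if residue_numbers is None:
        residue_numbers = np.arange(1, n + 1)
    twists = np.full(n - 3, np.nan)
    rises = np.full(n - 3, np.nan)
    for i in range(n - 3):
        X = trace[i:i + 3]
        Y = trace[i + 1:i + 4]
        try:
            fit = kabsch_fit(X, Y)
        except DegenerateGeometryError:
            continue
        R, t = fit.rotation, fit.translation
        cos_a = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
        angle = np.degrees(np.arccos(cos_a))
        if angle < 1e-9:
            continue
        # rotation axis from the antisymmetric part (angle < 180 here)
        axis = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0],
                         R[1, 0] - R[0, 1]])
        nrm = np.linalg.norm(axis)
        if nrm < 1e-12:
            continue
        axis /= nrm
        twists[i] = angle
        rises[i] = abs(float(t @ axis))
    centers = np.asarray(residue_numbers)[1:n - 2]
    return centers, twists, rises


def residues_per_turn(trace: np.ndarray,
                      residue_numbers: np.ndarray | None = None,
                      window: int = 3) -> HelixGeometry:
    """Residues per turn per residue, smoothed with a centered moving
    average of ``window`` residues (ends truncated to shorter windows)."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    centers, twists, rises = screw_twist_profile(trace, residue_numbers)
    rpt = 360.0 / twists
    half = window // 2
    smoothed = np.full_like(rpt, np.nan)
    for i in range(len(rpt)):
        lo = max(0, i - half)
        hi = min(len(rpt), i + half + 1)
        vals = rpt[lo:hi]
        vals = vals[np.isfinite(vals)]
        if len(vals):
            smoothed[i] = vals.mean()
    return HelixGeometry(residue_numbers=centers, twist_deg=twists,
                         rise=rises, residues_per_turn=smoothed, rpt_raw=rpt)


def classify_helix(geometry: HelixGeometry,
                   thresholds: dict[str, float] | None = None,
                   min_segment: int = 3) -> HelixGeometry:
    """Label each residue three_ten / alpha / pi / irregular by its
    smoothed residues-per-turn value."""
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    labels = []
    for v in geometry.residues_per_turn:
        if not np.isfinite(v):
            labels.append("irregular")
        elif v < th["three_ten_max"]:
            labels.append("three_ten")
        elif v < th["alpha_max"]:
            labels.append("alpha")
        else:
            labels.append("pi")
    geometry.labels = labels
    return geometry


def helix_segments(geometry: HelixGeometry,
                   min_length: int = 3) -> list[tuple[str, int, int]]:
    """Contiguous runs of one label, as (label, first_residue,
    last_residue); runs shorter than ``min_length`` are suppressed."""
    if geometry.labels is None:
        raise ValueError("classify_helix must run first")
    segments = []
    start = 0
    labels = geometry.labels
    nums = geometry.residue_numbers
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            if i - start >= min_length:
                segments.append((labels[start], int(nums[start]),
                                 int(nums[i - 1])))
            start = i
    return segments
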