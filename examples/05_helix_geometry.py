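"""Residues per turn and pi-helix detection along a composite helix.

An S6-like trace is built alpha-helical (3.6 residues/turn) with a pi
segment (4.4 residues/turn) in the middle, mimicking the pi bulge the
pore-lining helix develops; the classifier must recover the segment
boundaries.
"""

import numpy as np

from tetrapore import classify_helix, residues_per_turn
from tetrapore.helices import helix_segments
from tetrapore.synthetic import HelixSpec, build_ideal_helix

alpha1 = build_ideal_helix(HelixSpec(n_residues=10, twist_per_residue=100.0,
                                     rise_per_residue=1.5)).xyz
pi_seg = build_ideal_helix(HelixSpec(n_residues=8, twist_per_residue=81.8,
                                     rise_per_residue=1.15)).xyz
alpha2 = build_ideal_helix(HelixSpec(n_residues=10, twist_per_residue=100.0,
                                     rise_per_residue=1.5)).xyz
pi_seg = pi_seg + (alpha1[-1] - pi_seg[0]) + np.array([0.0, 0.0, 1.5])
alpha2 = alpha2 + (pi_seg[-1] - alpha2[0]) + np.array([0.0, 0.0, 1.15])
trace = np.vstack([alpha1, pi_seg, alpha2])

geo = classify_helix(residues_per_turn(trace, window=3))
print("residue  rpt    label")
for res, rpt, label in zip(geo.residue_numbers, geo.residues_per_turn,
                           geo.labels):
    print(f"{res:7d}  {rpt:5.2f}  {label}")
print("segments:", helix_segments(geo))
# 3.6 residues/turn = canonical alpha; >= 4.0 flags the pi bulge whose
# i <- i+5 hydrogen bonding makes the pore-lining helix locally flexible.
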