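# tetrapore

Geometric conformational analysis of homotetrameric ion-channel
structures from atomic coordinates.

Cryo-EM structures of C4-symmetric channels such as the ryanodine
receptor (RyR1) are distinguished into gating states — closed, open, and
Ca²⁺-inactivated — by a small set of geometric measurements: the radius
profile of the ion permeation pathway, the Cα diameter at the
hydrophobic gate, the tilt ("flexion") of the cytoplasmic shell,
inter-subunit salt bridges and ion coordination shells, and local
transmembrane-helix geometry (π- and 3₁₀-segments).  `tetrapore`
implements these measurements as a tested, reusable library for anyone
comparing coordinate models of tetrameric channels, together with a
synthetic-fixture module that generates structures whose ground truth is
known analytically, so every stage of the pipeline is verifiable without
downloading any deposited model.

## What it computes

* **Pore profile** — at each axial step z along the channel symmetry
  axis, the inscribed-sphere radius
  `r(z) = max_c min_i (|c − x_i| − r_vdW,i)` over the pore-lining atoms,
  maximised by a deterministic multi-start Nelder–Mead with the center
  constrained to the plane at z; plus the gate diameter as the mean of
  the two diagonal Cα–Cα distances at a gate residue (Ile4937 in RyR1
  numbering).
* **Channel frame** — the C4 symmetry axis from a single Kabsch fit of
  the protomer cycle P₀→P₁→P₂→P₃→P₀, oriented luminal→cytoplasmic;
  all signed angles refer to this frame.
* **Domain RMSD in three regimes** — per domain, Cα RMSD pre-aligned
  (Kabsch on the domain itself), unaligned (common frame from all shared
  Cα), and anchor-aligned (protomer superposed through the central
  domain); `unaligned − prealigned` isolates rigid repositioning.
* **Rigid-motion decomposition** — quaternion swing–twist split
  `R = R_swing·R_twist` of a domain's inter-state rotation into an
  in-plane twist about the channel axis (positive counterclockwise seen
  from the cytoplasmic side) and an out-of-plane swing.
* **Flexion angle** — per protomer, `asin(d̂·û)` for the diagonal d from
  an inner anchor (residue 348) to a peripheral anchor (residue 984);
  negative = periphery bent toward the membrane.
* **Interactions** — salt bridges (3.5 Å side-chain cutoff), hydrogen
  bonds, disulfides (2.5 Å), ion coordination shells (2.8 Å), ligand and
  lipid contact shells (4 / 5 Å), and Shrake–Rupley solvent-accessible
  surface areas with deterministic point sets.
* **Helix geometry** — per-residue twist and rise from exact screw fits
  of 4-Cα windows, residues per turn with a 3-residue moving average,
  and 3₁₀/α/π classification.
* **State report** — the consolidated per-model feature table and a
  configurable closed/open/inactivated classification rule.

## Worked example

A tetramer whose gate ring is built to enclose a sphere of exactly
1.0 Å — the closed-state gate radius — measured back by the profiler
(`examples/01_pore_profile.py`):

```
profile: 25 samples, step 0.25 A
minimal pore radius: 1.000 A  (built as 1.000)
radius at the Ile4937 gate landmark: 1.000 A
Calpha gate diameter (mean of diagonals): 11.30 A
```

A radius of ~1 Å means a dehydrated Ca²⁺ ion barely fits: the pore is
closed.  The full state comparison (`examples/06_state_comparison.py`)
builds three mimics with the hallmark values of the three states and
classifies them:

```
state_gate10.4_flex-2.2  => classification: closed
state_gate15.8_flex-5.1  => classification: open
state_gate10.7_flex-4.6  => classification: inactivated
```

The inactivated mimic is recognised by a closed gate (10.7 Å < 14 Å)
*plus* both inter-subunit EF-hand/S2–S3-loop salt bridges
(Glu4075–Arg4736, Lys4101–Asp4730 within 3.5 Å) *plus* a strongly
downward shell (flexion −4.6° ≤ −3.5°).

The `tetrapore` command exposes the same analyses from the shell
(`tetrapore profile|flexion|heatmap|motion|interactions|helixgeo|sasa|synth|compare`).

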