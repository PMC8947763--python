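# Methods

This note documents the measurement definitions, the numerical choices
behind them, what the synthetic fixtures do and do not emulate, and the
known limitations.  Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate model and addressing

Structures are held as a struct-of-arrays container parsed with gemmi
from PDB or mmCIF.  Author residue numbering is the only addressing
scheme — the literature on RyR1 cites author numbers (Ile4937, Glu4075,
…) and the deposited models use them — and label/entity numbering is
ignored.  Alternate locations are collapsed to the highest-occupancy
conformer, ties broken by alt-loc identifier order.  The deposited
models carry no hydrogens, so all defaults operate on heavy atoms; when
hydrogens are present the hydrogen-bond detector additionally applies a
D–H···A angle test.  PDB output checks every fixed-width field (serial
≤ 99999, residue number within 4 characters, coordinates within 8.3
format) and raises on overflow instead of emitting a malformed record.

## Channel frame

All signed quantities need a common vertical.  The C4 axis is obtained
from one Kabsch fit mapping the concatenated protomer correspondences
(P₀→P₁, P₁→P₂, P₂→P₃, P₃→P₀) onto each other; for an exactly symmetric
assembly the fitted rotation is the 90° symmetry operation and its
rotation axis the symmetry axis, and for near-symmetric inputs it is
the least-squares compromise.  The axis point is the least-squares
fixed point of that rotation restricted to the perpendicular plane.
Orientation follows the mass distribution: the unit axis û points from
the pore-region Cα centroid (residues 4821–5037) toward the centroid of
the remaining Cα, because the cytoplasmic assembly carries most of the
mass in these channels; fixtures without pore-region residues fall back
to the +z hemisphere.  Protomer indices run counterclockwise viewed
from the cytoplasmic side, i.e. a +90° right-hand rotation about û maps
protomer k onto k+1; protomer 0 is the first protein chain in file
order, which makes assignments reproducible while leaving the cycle
invariant under chain reshuffling.  The residual RMSD of the 90°
mapping is recorded on the frame (`c4_residual`) as a symmetry
diagnostic.

## Pore profile

The profile follows the inscribed-sphere definition: at axial position
z the pore radius is `max_c f(c)` with
`f(c) = min_i (|c − x_i| − r_vdW,i)`, the center c constrained to the
plane at z.  Differences from the classic simulated-annealing
implementation, chosen for exact reproducibility:

* deterministic multi-start downhill simplex per plane (seeds: previous
  plane's optimum plus four lateral offsets of one step) instead of
  Monte Carlo annealing;
* the sphere center is confined to each z plane (no free axial drift);
* a hard plane-to-plane continuity constraint (lateral center movement
  < 2 steps) enforcing a connected pathway;
* radii are clamped at `pore_max_radius` (15 Å default), and a profile
  whose first plane is unbounded laterally raises an enclosure error.

The axial step defaults to 0.25 Å.  Van der Waals radii default to the
simple set C 1.85, N 1.75, O 1.65, S 2.00, H 1.00, P 2.10 Å
(configurable).  Waters and ligands are excluded from the pore
selection by default.  Landmark radii (e.g. at the Ile4937 gate) are
linearly interpolated between the flanking samples of the mean Cα
height of the landmark residue.  The gate "diameter" is defined as the
mean of the two diagonal Cα–Cα distances (protomer pairs 0–2 and 1–3 of
the cycle); the published figures show diagonal protomers but print no
formula, so this symmetric definition is adopted and documented.

Correctness is established against a brute-force oracle: dense 2-D grid
maximisation of f on the gate plane of randomized fixtures (0.01 Å
grid), with agreement required within 0.05 Å.

## Superposition and RMSD regimes

`kabsch_fit` is the standard SVD solution with determinant correction
(reflections excluded); collinear point sets are rejected.  Three
per-domain Cα RMSD regimes are computed between two states:

* **prealigned** — the domain itself fitted pairwise; internal change;
* **unaligned** — both models placed in a common frame first; the
  default frame selection is every Cα shared by the two models, a
  deliberate, recorded choice since published maps rarely state their
  frame, and it is configurable (e.g. a TMD-only frame);
* **cd_aligned** — the protomer superposed through an anchor domain
  (the central domain CD by default), exposing motion relative to that
  anchor.

Residues must be resolved in both models to enter any RMSD (shared-set
intersection); shared counts are reported and domains with less than
half their residues shared are flagged.  `unaligned − prealigned ≥ 0`
estimates rigid repositioning.

## Swing–twist decomposition and flexion

A domain's inter-state rotation (Kabsch, after the global frame
superposition) is split as `R = R_swing·R_twist` by the quaternion
swing–twist construction: the twist quaternion is the normalised
projection of the rotation quaternion onto the axis, the swing the
remainder, which rotates about an axis exactly perpendicular to the
channel axis.  The decomposition is unique; the degenerate 180°-
perpendicular case resolves to zero twist.  Twist is signed positive
counterclockwise viewed from the cytoplasmic side; swing is reported
with a separate sign taken from the axial component of the domain
centroid displacement (+1 = cytoplasmic-ward, "upward"), since an
out-of-plane sense is otherwise descriptive.

The flexion angle of the cytoplasmic shell is, per protomer,
`asin(d̂·û)` where d runs from the Cα of an inner anchor (residue 348,
N-terminal domain) to a peripheral anchor (residue 984, P1 domain), and
the "horizontal plane" is exactly the plane perpendicular to the
computed channel axis.  Negative = periphery displaced toward the
membrane; this keeps the customary signs (closed ≈ +1…+2° with the
FKBP12 subunit bound, around −2° without it, open ≈ −5°).  The mean of
the four protomers is reported alongside the per-protomer values.

## Interactions and surface areas

All detectors are geometric, one record per residue pair at the minimal
heavy-atom distance:

* salt bridges: Asp/Glu carboxylate O versus Lys NZ / Arg NE,NH1,NH2
  within 3.5 Å; His is excluded from the cation set by default because
  its protonation at pH ≈ 7.4 is unknown (flag to include);
* hydrogen bonds: donor/acceptor heavy-atom typing from a standard
  residue chemistry table, 3.5 Å cutoff; backbone–backbone pairs of
  sequence neighbours are excluded and helical offsets are annotated
  (i+4 α, i+5 π); with explicit hydrogens a 120° minimum D–H···A angle
  applies.  This distance-plus-typing criterion is simpler than
  dedicated H-bond prediction software and is stated as such;
* disulfides: Cys SG–SG ≤ 2.5 Å;
* coordination shells: protein heavy atoms within 2.8 Å of each
  selected ion, ties preserved;
* contact shells: unique residues within 4 Å (ligands) or 5 Å (lipids),
  annotated with the registry domain containing them.

SASA uses Shrake–Rupley point sampling with a deterministic Fibonacci
sphere (960 points default, probe 1.4 Å); points landing exactly on a
neighbour's surface are credited to the lower-index atom so coincident
atoms are counted once.  Crevice coverage is operationalised as
ΔSASA: the crevice's area computed with the lipids absent, minus the
same atoms' area with lipids present.  Published coverage areas were
produced by an unstated method, so ours is reported, not asserted
against them.

## Helix geometry

For each window of four consecutive Cα atoms the rigid transform
mapping (CAᵢ…CAᵢ₊₂) onto (CAᵢ₊₁…CAᵢ₊₃) is Kabsch-fitted; its rotation
angle is the local twist per residue, the translation component along
the rotation axis the rise.  This screw fit is exact on ideal helices
for any twist, rise and radius (verified to 1e-6°), which is why it
replaces bisector-based constructions used by older helix-analysis
tools.  Residues per turn = 360/twist, smoothed by a centered 3-residue
moving average (window configurable; ends truncate).  Classification
thresholds rpt < 3.35 → 3₁₀, < 4.0 → α, ≥ 4.0 → π bracket the canonical
3.0/3.6/4.4 values and are configurable; reported segments must span at
least 3 residues to suppress single-residue flicker.  The smoothing is
applied to the rpt values (not to the twist window) — one of two
readings of a "3-residue moving window", chosen and exposed.

## Synthetic fixtures: what they emulate

The generator module produces the study conditions used throughout the
tests and the acceptance script:

* pore fixtures whose gate ring encloses an inscribed sphere of exactly
  the requested radius (closed-state value 1.0 Å), with Cα markers for
  diameter checks (closed-type diameters 10.4–10.7 Å, open 15.8 Å);
* flexion fixtures at the state-typical angles (−2.2° closed without
  FKBP12, −4.6° inactivated, −5.1° open; subclass values −4.4°, −5.6°);
* rigid-motion fixtures displaced by known twist/swing (e.g. 3.4°/6.8°,
  the activation-step magnitudes);
* ideal helices at canonical α (100°/1.5 Å), 3₁₀ (120°/2.0 Å) and π
  (81.8°/1.15 Å) geometry;
* residue pairs at controlled side-chain distances straddling the
  published cutoffs, with side chains taken from the chemical component
  dictionary shipped with biotite;
* composite "conformation" mimics combining gate, flexion, salt-bridge,
  ion-site and π-segment hallmarks, built as one asymmetric unit
  replicated by exact 90° rotations (hence exactly C4).

These fixtures are minimal geometric constructions: they carry no
realistic protein density, packing, side-chain conformers or
experimental noise.  Passing tests therefore demonstrate that the
*measurements* are correct (the estimator recovers known geometry),
not that any particular biological structure has particular values; the
deposited-model regression covers the latter and requires the published
coordinate files under `data/deposited/` (they cannot be redistributed
inside this repository, and the two tests that need them fail with an
explanatory message when the files are absent).

## Classification rule

open ⇔ gate Cα diameter ≥ 14 Å; inactivated ⇔ gate < 14 Å and both
configured inter-subunit salt bridges present and mean flexion ≤ −3.5°;
closed ⇔ gate < 14 Å otherwise; indeterminate when the gate cannot be
measured.  The 14 Å threshold splits the published closed-type
(10.3–11.3 Å) from open-type (15.8–16.7 Å) diameters and is
configurable, as is the flexion threshold (−3.5° separates the −2.2°
closed consensus from the −4.2…−4.6° inactivated datasets).  Hallmarks
not reducible to single-model geometry (nucleotide occupancy, lipids in
the TMD crevice) are reported as detector outputs but do not enter the
rule.

## Numerical choices and degenerate inputs

Kabsch rejects collinear sets (second singular value ≤ 1e-8 of the
first).  The swing–twist quaternion projection guards the w≈0, v·a≈0
degeneracy.  Pore optimisation uses Nelder–Mead with xatol 1e-4 Å.
Interaction detectors use KD-trees but are tested for exact agreement
with brute-force all-pairs scans.  Problem sizes in the test-suite and
acceptance script (tetramers of 10²–10³ atoms, 20 randomized pore
fixtures, 10³ random rotations) were chosen so the whole suite runs on
one CPU in a few minutes while still exercising every code path; all
tolerances are stated per test.

## Known limitations

* Single-conformer analysis only: no ensembles, no B-factor weighting.
* No sequence alignment — numbering is assumed consistent between the
  two models being compared (true within one deposition series).
* The hydrogen-bond criterion without hydrogens is distance+typing
  only; dedicated prediction tools apply stricter geometry.
* The "unaligned" RMSD regime depends on the declared common-frame
  selection; absolute unaligned values from other software are only
  comparable when the same frame is used.
* In-plane/out-of-plane rotation magnitudes depend on the decomposition
  convention and the domain boundary definition; published values from
  unspecified conventions are reproduced only qualitatively.
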