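"""Geometric interaction detection: salt bridges, hydrogen bonds,
disulfides, ion coordination shells and ligand contact shells.

All detectors are purely geometric, operate on heavy atoms (the deposited
models carry no hydrogens) and use the distance cutoffs from
:class:`tetrapore.domains.AnalysisConfig` — 3.5 A side-chain distance for
salt bridges, 2.8 A for ion coordination, 4 A for ligand contacts and 5 A
for lipid contacts.  When hydrogens are present, hydrogen bonds are
additionally filtered by the donor-H...acceptor angle.

Histidine is excluded from salt-bridge cations by default since its
protonation state at physiological pH is unknown.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .domains import AnalysisConfig, DomainRegistry
from .errors import EmptySelectionError
from .model import StructureModel

__all__ = ["InteractionRecord", "ContactResidue", "find_salt_bridges",
           "find_hydrogen_bonds", "find_disulfides", "coordination_shell",
           "contact_shell"]

Partner = tuple[int, str, int, str, str]  # protomer, chain, resnum, resname, atom


@dataclass(frozen=True)
class InteractionRecord:
    kind: str                  # salt_bridge | hbond | disulfide | coordination | contact
    partner_a: Partner
    partner_b: Partner
    distance: float
    inter_subunit: bool
    annotation: str = ""

    def residue_pair(self) -> tuple[tuple, tuple]:
        a = self.partner_a[:4]
        b = self.partner_b[:4]
        return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class ContactResidue:
    protomer: int
    chain: str
    residue_number: int
    residue_name: str
    min_distance: float
    domain: str = ""


# -- chemistry tables (heavy atoms) -----------------------------------------

ANION_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
CATION_ATOMS = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2")}
HIS_CATION_ATOMS = {"HIS": ("ND1", "NE2")}

SIDECHAIN_DONORS = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",), "CYS": ("SG",),
    "ASN": ("ND2",), "GLN": ("NE2",), "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2"), "TRP": ("NE1",),
}
SIDECHAIN_ACCEPTORS = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "ASN": ("OD1",), "GLN": ("OE1",), "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"), "HIS": ("ND1", "NE2"), "MET": ("SD",),
}


def _partner(model: StructureModel, i: int) -> Partner:
    return (int(model.protomer[i]), str(model.chain_id[i]),
            int(model.res_number[i]), str(model.res_name[i]),
            str(model.name[i]))


def _atoms_matching(model: StructureModel, table: dict[str, tuple[str, ...]]
                    ) -> np.ndarray:
    mask = np.zeros(model.n_atoms, bool)
    for res, names in table.items():
        mask |= (model.res_name == res) & np.isin(model.name, list(names))
    return np.nonzero(mask & ~model.is_hetero)[0]


def _scope_ok(model: StructureModel, i: int, j: int, scope: str) -> bool:
    inter = (model.protomer[i] != model.protomer[j]) or \
        (model.chain_id[i] != model.chain_id[j])
    if scope == "inter_subunit":
        return bool(inter)
    if scope == "intra":
        return not inter
    return True


def _pair_records(model: StructureModel, idx_a: np.ndarray, idx_b: np.ndarray,
                  cutoff: float, kind: str, scope: str = "all",
                  exclude_same_residue: bool = True) -> list[InteractionRecord]:
    """One record per residue pair at the minimal heavy-atom distance."""
    if len(idx_a) == 0 or len(idx_b) == 0:
        return []
    tree_b = cKDTree(model.xyz[idx_b])
    pairs: dict[tuple, tuple[float, int, int]] = {}
    neighbor_lists = tree_b.query_ball_point(model.xyz[idx_a], cutoff)
    for ai, neigh in zip(idx_a, neighbor_lists):
        for nb in neigh:
            bj = idx_b[nb]
            if ai == bj:
                continue
            res_a = (int(model.protomer[ai]), str(model.chain_id[ai]),
                     int(model.res_number[ai]), str(model.icode[ai]))
            res_b = (int(model.protomer[bj]), str(model.chain_id[bj]),
                     int(model.res_number[bj]), str(model.icode[bj]))
            if exclude_same_residue and res_a == res_b:
                continue
            if not _scope_ok(model, ai, bj, scope):
                continue
            key = (res_a, res_b) if res_a <= res_b else (res_b, res_a)
            d = float(np.linalg.norm(model.xyz[ai] - model.xyz[bj]))
            if d <= cutoff and (key not in pairs or d < pairs[key][0]):
                pairs[key] = (d, ai, bj)
    records = []
    for d, ai, bj in pairs.values():
        pa, pb = _partner(model, ai), _partner(model, bj)
        if (pa[0], pa[2]) > (pb[0], pb[2]):
            pa, pb = pb, pa
        inter = pa[0] != pb[0] or pa[1] != pb[1]
        records.append(InteractionRecord(kind=kind, partner_a=pa, partner_b=pb,
                                         distance=d, inter_subunit=inter))
    records.sort(key=lambda r: (r.partner_a, r.partner_b))
    return records


# ---------------------------------------------------------------------------


def find_salt_bridges(model: StructureModel, cutoff: float | None = None,
                      scope: str = "all", include_his: bool = False,
                      config: AnalysisConfig | None = None
                      ) -> list[InteractionRecord]:
    """Asp/Glu carboxylate O within ``cutoff`` of Lys/Arg (optionally His)
    side-chain N; one record per residue pair at the minimal distance."""
    config = config or AnalysisConfig()
    cutoff = cutoff if cutoff is not None else config.salt_bridge_cutoff
    cations = dict(CATION_ATOMS)
    if include_his:
        cations.update(HIS_CATION_ATOMS)
    idx_an = _atoms_matching(model, ANION_ATOMS)
    idx_cat = _atoms_matching(model, cations)
    return _pair_records(model, idx_an, idx_cat, cutoff, "salt_bridge", scope)


def find_disulfides(model: StructureModel, cutoff: float | None = None,
                    config: AnalysisConfig | None = None
                    ) -> list[InteractionRecord]:
    """Cys SG-SG pairs within the disulfide cutoff (default 2.5 A)."""
    config = config or AnalysisConfig()
    cutoff = cutoff if cutoff is not None else config.disulfide_cutoff
    idx = _atoms_matching(model, {"CYS": ("SG",)})
    recs = _pair_records(model, idx, idx, cutoff, "disulfide")
    return recs


def find_hydrogen_bonds(model: StructureModel,
                        config: AnalysisConfig | None = None,
                        scope: str = "all") -> list[InteractionRecord]:
    """Donor-acceptor heavy-atom pairs within the hydrogen-bond cutoff.

    Backbone N is a donor (except proline), backbone O an acceptor;
    side-chain typing follows a standard residue chemistry table.
    Backbone-backbone pairs between sequence neighbours (|i-j| < 2) are
    excluded.  Backbone pairs are annotated with their helical offset
    ("i+4" canonical alpha, "i+5" pi-helix bonding).  If explicit
    hydrogens exist on a donor, the D-H...A angle must exceed
    ``hbond_angle_min``.
    """
    config = config or AnalysisConfig()
    cutoff = config.hbond_distance_cutoff

    backbone_n = np.nonzero((model.name == "N") & ~model.is_hetero &
                            (model.res_name != "PRO"))[0]
    backbone_o = np.nonzero(np.isin(model.name, ["O", "OXT"]) &
                            ~model.is_hetero)[0]
    sc_don = _atoms_matching(model, SIDECHAIN_DONORS)
    sc_acc = _atoms_matching(model, SIDECHAIN_ACCEPTORS)
    donors = np.concatenate([backbone_n, sc_don])
    acceptors = np.concatenate([backbone_o, sc_acc])
    if len(donors) == 0 or len(acceptors) == 0:
        return []
    is_bb_don = np.zeros(model.n_atoms, bool)
    is_bb_don[backbone_n] = True
    is_bb_acc = np.zeros(model.n_atoms, bool)
    is_bb_acc[backbone_o] = True

    hydrogens = np.nonzero(model.element == "H")[0]
    h_tree = cKDTree(model.xyz[hydrogens]) if len(hydrogens) else None

    tree = cKDTree(model.xyz[acceptors])
    pairs: dict[tuple, tuple[float, int, int]] = {}
    for di, neigh in zip(donors, tree.query_ball_point(model.xyz[donors], cutoff)):
        for nb in neigh:
            aj = acceptors[nb]
            res_d = (str(model.chain_id[di]), int(model.res_number[di]),
                     str(model.icode[di]))
            res_a = (str(model.chain_id[aj]), int(model.res_number[aj]),
                     str(model.icode[aj]))
            if res_d == res_a:
                continue
            if is_bb_don[di] and is_bb_acc[aj] and res_d[0] == res_a[0] \
                    and abs(res_d[1] - res_a[1]) < 2:
                continue
            if not _scope_ok(model, di, aj, scope):
                continue
            d = float(np.linalg.norm(model.xyz[di] - model.xyz[aj]))
            if d > cutoff:
                continue
            if h_tree is not None:
                # require a covalent H on the donor with a good angle
                hs = h_tree.query_ball_point(model.xyz[di], 1.3)
                if hs:
                    ok = False
                    for h in hs:
                        hv = model.xyz[hydrogens[h]]
                        v1 = model.xyz[di] - hv
                        v2 = model.xyz[aj] - hv
                        cosang = (v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                        ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                        if ang >= config.hbond_angle_min:
                            ok = True
                            break
                    if not ok:
                        continue
            key = (di, aj)
            pairs[key] = (d, di, aj)

    # per donor/acceptor residue pair keep the minimal-distance contact
    best: dict[tuple, tuple[float, int, int]] = {}
    for d, di, aj in pairs.values():
        rk = ((int(model.protomer[di]), str(model.chain_id[di]),
               int(model.res_number[di]), str(model.name[di])),
              (int(model.protomer[aj]), str(model.chain_id[aj]),
               int(model.res_number[aj]), str(model.name[aj])))
        if rk not in best or d < best[rk][0]:
            best[rk] = (d, di, aj)
    records = []
    for d, di, aj in best.values():
        annot = ""
        if is_bb_don[di] and is_bb_acc[aj] and \
                model.chain_id[di] == model.chain_id[aj]:
            delta = int(model.res_number[di]) - int(model.res_number[aj])
            if delta in (3, 4, 5):
                annot = f"i+{delta}"
        pa, pb = _partner(model, di), _partner(model, aj)
        inter = pa[0] != pb[0] or pa[1] != pb[1]
        records.append(InteractionRecord(kind="hbond", partner_a=pa,
                                         partner_b=pb, distance=d,
                                         inter_subunit=inter, annotation=annot))
    records.sort(key=lambda r: (r.partner_a, r.partner_b))
    return records


def _resolve_ligand_mask(model: StructureModel, ligand) -> np.ndarray:
    if isinstance(ligand, np.ndarray):
        return ligand.astype(bool)
    names = [ligand] if isinstance(ligand, str) else list(ligand)
    return model.is_hetero & np.isin(model.res_name, names)


def coordination_shell(model: StructureModel, ion_selection,
                       cutoff: float | None = None,
                       config: AnalysisConfig | None = None
                       ) -> list[tuple[Partner, list[InteractionRecord]]]:
    """Protein heavy atoms within the coordination cutoff of each ion.

    ``ion_selection`` is a hetero residue name (e.g. "CA"), a list of
    names, or a boolean atom mask.  Returns one (ion, shell) entry per ion
    atom, the shell sorted by distance with ties preserved in atom order.
    """
    config = config or AnalysisConfig()
    cutoff = cutoff if cutoff is not None else config.coordination_cutoff
    ion_mask = _resolve_ligand_mask(model, ion_selection)
    ions = np.nonzero(ion_mask)[0]
    if len(ions) == 0:
        raise EmptySelectionError("ion selection matched no atoms")
    protein = np.nonzero(~model.is_hetero & (model.element != "H"))[0]
    tree = cKDTree(model.xyz[protein])
    out = []
    for ion in ions:
        shell = []
        for nb in tree.query_ball_point(model.xyz[ion], cutoff):
            pj = protein[nb]
            d = float(np.linalg.norm(model.xyz[ion] - model.xyz[pj]))
            pa, pb = _partner(model, ion), _partner(model, pj)
            shell.append(InteractionRecord(kind="coordination", partner_a=pa,
                                           partner_b=pb, distance=d,
                                           inter_subunit=False))
        shell.sort(key=lambda r: (round(r.distance, 9), r.partner_b))
        out.append((_partner(model, ion), shell))
    return out


def contact_shell(model: StructureModel, ligand_selection,
                  cutoff: float,
                  registry: DomainRegistry | None = None
                  ) -> list[ContactResidue]:
    """Unique protein residues with any heavy atom within ``cutoff`` of the
    ligand selection, annotated with the registry domain containing them."""
    lig_mask = _resolve_ligand_mask(model, ligand_selection)
    lig = np.nonzero(lig_mask)[0]
    if len(lig) == 0:
        raise EmptySelectionError("ligand selection matched no atoms")
    protein = np.nonzero(~model.is_hetero & (model.element != "H"))[0]
    tree = cKDTree(model.xyz[lig])
    best: dict[tuple, float] = {}
    meta: dict[tuple, tuple] = {}
    dists, _ = tree.query(model.xyz[protein], k=1)
    for pj, d in zip(protein, dists):
        if d > cutoff:
            continue
        key = (int(model.protomer[pj]), str(model.chain_id[pj]),
               int(model.res_number[pj]), str(model.icode[pj]))
        if key not in best or d < best[key]:
            best[key] = float(d)
            meta[key] = (str(model.res_name[pj]),)
    out = []
    for key in sorted(best):
        prot, chain, resnum, _ = key
        domain = ""
        if registry is not None:
            for name in registry.names():
                if registry[name].contains(resnum):
                    domain = name
                    break
        out.append(ContactResidue(protomer=prot, chain=chain,
                                  residue_number=resnum,
                                  residue_name=meta[key][0],
                                  min_distance=best[key], domain=domain))
    return out
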