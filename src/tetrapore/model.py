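"""Atomic coordinate container and PDB/mmCIF input/output.

The in-memory representation is a struct-of-arrays :class:`StructureModel`
(one numpy array per atom attribute), which keeps whole-structure geometric
operations vectorised.  Residues are addressed exclusively by *author*
numbering, the scheme used in deposited coordinate files and in the
structural literature on ryanodine receptors (e.g. the Ile4937 gate).

Parsing and mmCIF serialisation are delegated to :mod:`gemmi`; the PDB
writer is implemented here so that fixed-width field overflow can be
detected explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .errors import (
    EmptyModelError,
    EmptySelectionError,
    FieldOverflowError,
    ParseError,
)

__all__ = [
    "AtomRecord",
    "StructureModel",
    "Selection",
    "read_structure",
    "write_structure",
    "select_atoms",
]


@dataclass(frozen=True)
class AtomRecord:
    """A single atom, as a plain record (used at API boundaries)."""

    serial: int
    name: str
    element: str
    alt_loc: str
    residue_number: int
    insertion_code: str
    residue_name: str
    chain_id: str
    protomer_index: int  # 0..3, or -1 when unassigned
    position: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")
        if not self.element:
            raise ValueError(f"atom {self.name}: empty element symbol")


class StructureModel:
    """Hierarchical atomic model stored as parallel numpy arrays.

    Atom order is preserved from the source.  ``protomer`` holds the C4
    subunit index (0-3) or -1 before :func:`tetrapore.frame.assign_protomers`
    has run.
    """

    def __init__(
        self,
        *,
        serial: np.ndarray,
        name: np.ndarray,
        element: np.ndarray,
        alt_loc: np.ndarray,
        res_number: np.ndarray,
        icode: np.ndarray,
        res_name: np.ndarray,
        chain_id: np.ndarray,
        protomer: np.ndarray,
        xyz: np.ndarray,
        occupancy: np.ndarray,
        b_factor: np.ndarray,
        is_hetero: np.ndarray,
        id: str = "",
        symmetry_order: int = 4,
        warnings: list[str] | None = None,
    ) -> None:
        n = len(serial)
        self.serial = np.asarray(serial, dtype=np.int64)
        self.name = np.asarray(name, dtype="U6")
        self.element = np.asarray(element, dtype="U2")
        self.alt_loc = np.asarray(alt_loc, dtype="U1")
        self.res_number = np.asarray(res_number, dtype=np.int64)
        self.icode = np.asarray(icode, dtype="U1")
        self.res_name = np.asarray(res_name, dtype="U5")
        self.chain_id = np.asarray(chain_id, dtype="U4")
        self.protomer = np.asarray(protomer, dtype=np.int64)
        self.xyz = np.ascontiguousarray(xyz, dtype=np.float64).reshape(n, 3)
        self.occupancy = np.asarray(occupancy, dtype=np.float64)
        self.b_factor = np.asarray(b_factor, dtype=np.float64)
        self.is_hetero = np.asarray(is_hetero, dtype=bool)
        self.id = id
        self.symmetry_order = int(symmetry_order)
        self.warnings: list[str] = list(warnings or [])
        for arr in (self.name, self.element, self.alt_loc, self.res_number,
                    self.icode, self.res_name, self.chain_id, self.protomer,
                    self.occupancy, self.b_factor, self.is_hetero):
            if len(arr) != n:
                raise ValueError("attribute arrays have inconsistent lengths")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite coordinates in model")

    # -- construction -------------------------------------------------

    @classmethod
    def from_atoms(cls, atoms: Iterable[AtomRecord], *, id: str = "",
                   symmetry_order: int = 4) -> "StructureModel":
        records = list(atoms)
        if not records:
            return cls.empty(id=id, symmetry_order=symmetry_order)
        return cls(
            serial=np.array([a.serial for a in records]),
            name=np.array([a.name for a in records]),
            element=np.array([a.element for a in records]),
            alt_loc=np.array([a.alt_loc for a in records]),
            res_number=np.array([a.residue_number for a in records]),
            icode=np.array([a.insertion_code for a in records]),
            res_name=np.array([a.residue_name for a in records]),
            chain_id=np.array([a.chain_id for a in records]),
            protomer=np.array([a.protomer_index for a in records]),
            xyz=np.array([a.position for a in records], dtype=float),
            occupancy=np.array([a.occupancy for a in records]),
            b_factor=np.array([a.b_factor for a in records]),
            is_hetero=np.array([a.is_hetero for a in records]),
            id=id,
            symmetry_order=symmetry_order,
        )

    @classmethod
    def empty(cls, *, id: str = "", symmetry_order: int = 4) -> "StructureModel":
        z = np.zeros(0)
        return cls(serial=z, name=z.astype("U6"), element=z.astype("U2"),
                   alt_loc=z.astype("U1"), res_number=z, icode=z.astype("U1"),
                   res_name=z.astype("U5"), chain_id=z.astype("U4"), protomer=z,
                   xyz=np.zeros((0, 3)), occupancy=z, b_factor=z,
                   is_hetero=z.astype(bool), id=id, symmetry_order=symmetry_order)

    # -- basic properties ----------------------------------------------

    def __len__(self) -> int:
        return len(self.serial)

    @property
    def n_atoms(self) -> int:
        return len(self.serial)

    def __iter__(self):
        for i in range(len(self)):
            yield self.atom(i)

    def atom(self, i: int) -> AtomRecord:
        return AtomRecord(
            serial=int(self.serial[i]), name=str(self.name[i]),
            element=str(self.element[i]), alt_loc=str(self.alt_loc[i]),
            residue_number=int(self.res_number[i]),
            insertion_code=str(self.icode[i]), residue_name=str(self.res_name[i]),
            chain_id=str(self.chain_id[i]), protomer_index=int(self.protomer[i]),
            position=self.xyz[i].copy(), occupancy=float(self.occupancy[i]),
            b_factor=float(self.b_factor[i]), is_hetero=bool(self.is_hetero[i]),
        )

    def copy(self) -> "StructureModel":
        return StructureModel(
            serial=self.serial.copy(), name=self.name.copy(),
            element=self.element.copy(), alt_loc=self.alt_loc.copy(),
            res_number=self.res_number.copy(), icode=self.icode.copy(),
            res_name=self.res_name.copy(), chain_id=self.chain_id.copy(),
            protomer=self.protomer.copy(), xyz=self.xyz.copy(),
            occupancy=self.occupancy.copy(), b_factor=self.b_factor.copy(),
            is_hetero=self.is_hetero.copy(), id=self.id,
            symmetry_order=self.symmetry_order, warnings=list(self.warnings),
        )

    def subset(self, mask: np.ndarray) -> "StructureModel":
        """New model containing the atoms selected by a boolean mask or index array."""
        idx = np.asarray(mask)
        return StructureModel(
            serial=self.serial[idx], name=self.name[idx], element=self.element[idx],
            alt_loc=self.alt_loc[idx], res_number=self.res_number[idx],
            icode=self.icode[idx], res_name=self.res_name[idx],
            chain_id=self.chain_id[idx], protomer=self.protomer[idx],
            xyz=self.xyz[idx], occupancy=self.occupancy[idx],
            b_factor=self.b_factor[idx], is_hetero=self.is_hetero[idx],
            id=self.id, symmetry_order=self.symmetry_order,
        )

    # -- convenience masks ---------------------------------------------

    @property
    def ca_mask(self) -> np.ndarray:
        return (self.name == "CA") & ~self.is_hetero

    @property
    def protein_mask(self) -> np.ndarray:
        return ~self.is_hetero

    def chains(self) -> list[str]:
        """Chain identifiers of protein chains, in order of first appearance."""
        seen: dict[str, None] = {}
        for cid, het in zip(self.chain_id, self.is_hetero):
            if not het and cid not in seen:
                seen[cid] = None
        return list(seen)

    def chain_mask(self, chain: str) -> np.ndarray:
        return self.chain_id == chain

    def residue_keys(self) -> set[tuple[str, int, str]]:
        return set(zip(self.chain_id.tolist(), self.res_number.tolist(),
                       self.icode.tolist()))

    def validate_unique_atoms(self) -> None:
        keys = list(zip(self.chain_id.tolist(), self.res_number.tolist(),
                        self.icode.tolist(), self.name.tolist(),
                        self.alt_loc.tolist()))
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (chain, residue, icode, atom, alt_loc) keys")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    mask: np.ndarray | None = None) -> "StructureModel":
        """Copy with ``x -> R x + t`` applied to all atoms (or to a mask)."""
        out = self.copy()
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        if mask is None:
            out.xyz = out.xyz @ R.T + t
        else:
            out.xyz[mask] = out.xyz[mask] @ R.T + t
        return out


@dataclass
class Selection:
    """Result of :func:`select_atoms`: the matched atoms plus bookkeeping.

    ``missing_residues`` lists (chain_id, residue_number) pairs that fall in
    the requested ranges but are not resolved in the model.
    """

    model: StructureModel
    missing_residues: list[tuple[str, int]] = field(default_factory=list)

    @property
    def xyz(self) -> np.ndarray:
        return self.model.xyz

    @property
    def n_atoms(self) -> int:
        return self.model.n_atoms

    @property
    def n_missing(self) -> int:
        return len(self.missing_residues)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

_FORMAT_BY_SUFFIX = {
    ".pdb": "pdb", ".ent": "pdb", ".cif": "mmcif", ".mmcif": "mmcif",
}


def _detect_format(path: Path, format_hint: str | None) -> str:
    if format_hint is not None:
        fmt = format_hint.lower()
        if fmt not in ("pdb", "mmcif"):
            raise ValueError(f"unknown format hint {format_hint!r}")
        return fmt
    fmt = _FORMAT_BY_SUFFIX.get(path.suffix.lower())
    if fmt is None:
        raise ParseError(f"cannot detect format from extension of {path}")
    return fmt


def read_structure(path: str | Path, format_hint: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Alternate locations are collapsed to the highest-occupancy conformer
    (ties broken by alt_loc identifier order); author residue numbering is
    preserved; waters and ligands are kept with ``is_hetero`` set.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    fmt = _detect_format(path, format_hint)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"failed to parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyModelError(f"{path}: no models in file")
    gmodel = st[0]

    serials, names, elements, altlocs = [], [], [], []
    resnums, icodes, resnames, chainids = [], [], [], []
    xyz, occs, bs, het = [], [], [], []
    warnings: list[str] = []
    n_collapsed = 0
    for chain in gmodel:
        for res in chain:
            is_het = res.het_flag == "H"
            # collapse alt-locs: highest occupancy wins, ties by alt_loc order
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = best.get(atom.name)
                if prev is None:
                    best[atom.name] = atom
                else:
                    n_collapsed += 1
                    if (atom.occ, _neg_ord(atom.altloc)) > (prev.occ, _neg_ord(prev.altloc)):
                        best[atom.name] = atom
            for atom in best.values():
                serials.append(atom.serial)
                names.append(atom.name)
                elements.append(atom.element.name if atom.element.name else
                                _guess_element(atom.name))
                altlocs.append(atom.altloc if atom.altloc else "")
                resnums.append(res.seqid.num)
                icodes.append(res.seqid.icode.strip())
                resnames.append(res.name)
                chainids.append(chain.name)
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
                occs.append(min(max(atom.occ, 0.0), 1.0))
                bs.append(atom.b_iso)
                het.append(is_het)
    if not serials:
        raise EmptyModelError(f"{path}: model contains no atoms")
    if n_collapsed:
        warnings.append(f"collapsed {n_collapsed} alternate-location atoms "
                        "to highest occupancy")
    model = StructureModel(
        serial=np.array(serials), name=np.array(names), element=np.array(elements),
        alt_loc=np.array(altlocs), res_number=np.array(resnums),
        icode=np.array(icodes), res_name=np.array(resnames),
        chain_id=np.array(chainids), protomer=np.full(len(serials), -1),
        xyz=np.array(xyz), occupancy=np.array(occs), b_factor=np.array(bs),
        is_hetero=np.array(het), id=st.name or path.stem, warnings=warnings,
    )
    return model


def _neg_ord(altloc: str) -> int:
    # tie-break: earlier alt_loc identifier wins, so invert the ordering
    return -ord(altloc) if altloc else 0


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "BR", "NA", "MG",
                                                       "ZN", "CA", "FE", "MN"):
        return stripped[:2].capitalize()
    return stripped[:1].upper() if stripped else "X"


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_structure(model: StructureModel, path: str | Path,
                    format: str | None = None) -> None:
    """Write a model as PDB (fixed-width v3.3) or mmCIF.

    PDB output checks every fixed-width field and raises
    :class:`FieldOverflowError` rather than emit a malformed record;
    mmCIF has no field-width limits.
    """
    path = Path(path)
    if model.n_atoms == 0:
        raise EmptyModelError("refusing to write an empty model")
    fmt = _detect_format(path, format)
    if fmt == "pdb":
        _write_pdb(model, path)
    else:
        _write_mmcif(model, path)


def _write_pdb(model: StructureModel, path: Path) -> None:
    lines = []
    serial = 0
    order = _file_order(model)
    for i in order:
        serial += 1
        if serial > 99999:
            raise FieldOverflowError("more than 99999 atoms: PDB serial overflow")
        resnum = int(model.res_number[i])
        if not (-999 <= resnum <= 9999):
            raise FieldOverflowError(
                f"residue number {resnum} does not fit the 4-character PDB field")
        chain = str(model.chain_id[i])
        if len(chain) > 1:
            raise FieldOverflowError(f"chain id {chain!r} longer than 1 character")
        x, y, z = model.xyz[i]
        for v in (x, y, z):
            if not (-999.999 <= v <= 9999.999):
                raise FieldOverflowError(f"coordinate {v:.3f} overflows PDB field")
        name = str(model.name[i])
        # PDB atom-name column convention: element right-justified in 14-15
        padded = f" {name:<3s}" if len(name) < 4 and len(str(model.element[i])) < 2 \
            else f"{name:<4s}"
        record = "HETATM" if model.is_hetero[i] else "ATOM  "
        lines.append(
            f"{record}{serial:5d} {padded[:4]}{str(model.alt_loc[i]) or ' ':1s}"
            f"{str(model.res_name[i]):>3s} {chain:1s}{resnum:4d}"
            f"{str(model.icode[i]) or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{model.occupancy[i]:6.2f}"
            f"{model.b_factor[i]:6.2f}          {str(model.element[i]):>2s}  "
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def _write_mmcif(model: StructureModel, path: Path) -> None:
    st = _to_gemmi(model)
    doc = st.make_mmcif_document()
    doc.write_file(str(path))


def _file_order(model: StructureModel) -> np.ndarray:
    """Stable atom order for output: group by chain (first appearance), then
    residue number/insertion code, preserving intra-residue order."""
    chain_rank = {c: r for r, c in enumerate(dict.fromkeys(model.chain_id.tolist()))}
    ranks = np.array([chain_rank[c] for c in model.chain_id])
    return np.lexsort((np.arange(model.n_atoms), model.res_number, ranks))


def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.id or "model"
    gm = gemmi.Model("1")
    order = _file_order(model)
    cur_chain = None
    cur_res_key = None
    chain_obj = None
    res_obj = None
    for i in order:
        cid = str(model.chain_id[i])
        if cid != cur_chain:
            chain_obj = gemmi.Chain(cid)
            gm.add_chain(chain_obj)
            chain_obj = gm[-1]
            cur_chain = cid
            cur_res_key = None
        res_key = (int(model.res_number[i]), str(model.icode[i]), str(model.res_name[i]))
        if res_key != cur_res_key:
            res = gemmi.Residue()
            res.seqid = gemmi.SeqId(int(model.res_number[i]), str(model.icode[i]) or " ")
            res.name = str(model.res_name[i])
            res.het_flag = "H" if model.is_hetero[i] else "A"
            chain_obj.add_residue(res)
            res_obj = chain_obj[-1]
            cur_res_key = res_key
        atom = gemmi.Atom()
        atom.name = str(model.name[i])
        atom.element = gemmi.Element(str(model.element[i]))
        atom.altloc = str(model.alt_loc[i]) or "\0"
        atom.pos = gemmi.Position(*model.xyz[i])
        atom.occ = float(model.occupancy[i])
        atom.b_iso = float(model.b_factor[i])
        atom.serial = int(model.serial[i])
        res_obj.add_atom(atom)
    st.add_model(gm)
    st.setup_entities()
    return st


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def select_atoms(
    model: StructureModel,
    domain: "object | Sequence[tuple[int, int]]",
    atom_names: set[str] | None = None,
    protomer: int | None = None,
    include_hetero: bool = False,
) -> Selection:
    """Select atoms by author-numbering residue ranges.

    ``domain`` is a :class:`tetrapore.domains.DomainDefinition` or a raw list
    of inclusive ``(start, end)`` intervals.  Atoms are returned ordered by
    (protomer, residue number, atom name).  Residues in the requested ranges
    missing from the model are skipped but reported in the result.
    """
    ranges = getattr(domain, "ranges", domain)
    ranges = [(int(a), int(b)) for a, b in ranges]
    for a, b in ranges:
        if a > b:
            raise ValueError(f"invalid range {a}-{b}")

    in_range = np.zeros(model.n_atoms, dtype=bool)
    for a, b in ranges:
        in_range |= (model.res_number >= a) & (model.res_number <= b)
    mask = in_range
    if not include_hetero:
        mask = mask & ~model.is_hetero
    if atom_names is not None:
        mask = mask & np.isin(model.name, list(atom_names))
    if protomer is not None:
        mask = mask & (model.protomer == protomer)

    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        raise EmptySelectionError(
            f"selection {ranges} (atoms={atom_names}, protomer={protomer}) "
            "matched no atoms")
    # order: (protomer, residue number, atom name), stable w.r.t. input
    sub_prot = model.protomer[idx]
    sub_res = model.res_number[idx]
    sub_name = model.name[idx]
    order = np.lexsort((idx, sub_name, sub_res, sub_prot))
    idx = idx[order]

    # missing-residue report, per chain covered by the (possibly filtered) scope
    missing: list[tuple[str, int]] = []
    scope = ~model.is_hetero if not include_hetero else np.ones(model.n_atoms, bool)
    if protomer is not None:
        scope = scope & (model.protomer == protomer)
    for cid in dict.fromkeys(model.chain_id[scope].tolist()):
        chain_res = set(model.res_number[scope & (model.chain_id == cid)].tolist())
        for a, b in ranges:
            if chain_res and (min(chain_res) <= b and max(chain_res) >= a):
                for r in range(a, b + 1):
                    if r not in chain_res:
                        missing.append((cid, r))
    return Selection(model=model.subset(idx), missing_residues=missing)
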