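"""Interaction detectors against brute-force all-pairs distance scans."""

import numpy as np
import pytest

from tetrapore import (AtomRecord, StructureModel, contact_shell,
                       coordination_shell, find_disulfides,
                       find_hydrogen_bonds, find_salt_bridges)
from tetrapore.errors import EmptySelectionError
from tetrapore.frame import rotation_about_axis
from tetrapore.synthetic import (HelixSpec, build_conformation_fixture,
                                 build_ideal_helix, build_interaction_fixture)

# independent oracle tables (kept local on purpose)
ORACLE_ANIONS = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
ORACLE_CATIONS = {("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2")}


def brute_force_salt_bridges(model, cutoff=3.5):
    """All-pairs scan; one (residue pair, min distance) per bridge."""
    found = {}
    n = model.n_atoms
    for i in range(n):
        if (model.res_name[i], model.name[i]) not in ORACLE_ANIONS:
            continue
        for j in range(n):
            if (model.res_name[j], model.name[j]) not in ORACLE_CATIONS:
                continue
            d = float(np.linalg.norm(model.xyz[i] - model.xyz[j]))
            if d <= cutoff:
                key = tuple(sorted([(str(model.chain_id[i]), int(model.res_number[i])),
                                    (str(model.chain_id[j]), int(model.res_number[j]))]))
                if key not in found or d < found[key]:
                    found[key] = d
    return found


class TestSaltBridges:
    def test_pair_inside_cutoff_detected(self):
        model = build_interaction_fixture([("GLU", "ARG", 3.4, False)])
        assert len(find_salt_bridges(model)) == 1

    def test_pair_outside_cutoff_excluded(self):
        model = build_interaction_fixture([("GLU", "ARG", 3.6, False)])
        assert len(find_salt_bridges(model, cutoff=3.5)) == 0

    def test_matches_brute_force_scan(self):
        model = build_interaction_fixture([
            ("GLU", "ARG", 3.4, False), ("LYS", "ASP", 3.2, True),
            ("GLU", "LYS", 3.49, False), ("ASP", "ARG", 3.51, False)])
        records = find_salt_bridges(model)
        oracle = brute_force_salt_bridges(model)
        got = {tuple(sorted([(r.partner_a[1], r.partner_a[2]),
                             (r.partner_b[1], r.partner_b[2])])): r.distance
               for r in records}
        assert set(got) == set(oracle)
        for k in got:
            assert got[k] == pytest.approx(oracle[k], abs=1e-9)

    def test_scope_filtering(self):
        model = build_interaction_fixture([
            ("GLU", "ARG", 3.4, False), ("LYS", "ASP", 3.2, True)])
        inter = find_salt_bridges(model, scope="inter_subunit")
        intra = find_salt_bridges(model, scope="intra")
        assert len(inter) == 1 and inter[0].inter_subunit
        assert len(intra) == 1 and not intra[0].inter_subunit

    def test_c4_multiplicity_on_symmetric_fixture(self):
        model = build_conformation_fixture(salt_bridges=True)
        records = find_salt_bridges(model, scope="inter_subunit")
        by_pair = {}
        for r in records:
            key = tuple(sorted((r.partner_a[2], r.partner_b[2])))
            by_pair.setdefault(key, []).append(r)
        assert set(by_pair) == {(4075, 4736), (4101, 4730)}
        assert all(len(v) == 4 for v in by_pair.values())

    def test_invariance_under_global_rotation(self):
        model = build_conformation_fixture(salt_bridges=True)
        R = rotation_about_axis(np.array([1.0, 2.0, 2.0]) / 3.0, 77.0)
        moved = model.transformed(R, np.array([3.0, 3.0, 3.0]))
        a = {(r.residue_pair(), round(r.distance, 6))
             for r in find_salt_bridges(model)}
        b = {(r.residue_pair(), round(r.distance, 6))
             for r in find_salt_bridges(moved)}
        assert a == b


class TestDisulfides:
    def test_canonical_bond_detected(self):
        model = build_interaction_fixture([("CYS", "CYS", 2.05, True)])
        recs = find_disulfides(model)
        assert len(recs) == 1
        assert recs[0].distance == pytest.approx(2.05, abs=0.01)

    def test_beyond_cutoff_not_detected(self):
        model = build_interaction_fixture([("CYS", "CYS", 2.6, True)])
        assert len(find_disulfides(model)) == 0


class TestHydrogenBonds:
    def test_alpha_helix_backbone_shows_i_plus_4_pattern(self):
        model = build_ideal_helix(HelixSpec(n_residues=14), backbone=True)
        recs = find_hydrogen_bonds(model)
        i4 = {(r.partner_b[2], r.partner_a[2]) for r in recs
              if r.annotation == "i+4"}
        # every acceptor O_k should bond the donor N_{k+4}
        assert {(k, k + 4) for k in range(1, 10)} <= i4

    def test_distance_cutoff_exclusive(self):
        # donor-acceptor pair at 3.6 A is beyond the 3.5 A cutoff
        atoms = [
            AtomRecord(1, "OG", "O", "", 1, "", "SER", "A", 0, np.zeros(3)),
            AtomRecord(2, "NZ", "N", "", 5, "", "LYS", "A", 0,
                       np.array([3.6, 0.0, 0.0]))]
        model = StructureModel.from_atoms(atoms)
        assert len(find_hydrogen_bonds(model)) == 0
        atoms[1] = AtomRecord(2, "NZ", "N", "", 5, "", "LYS", "A", 0,
                              np.array([3.4, 0.0, 0.0]))
        assert len(find_hydrogen_bonds(StructureModel.from_atoms(atoms))) == 1


class TestCoordination:
    def _ion_model(self, distances):
        atoms = [AtomRecord(1, "CA", "Ca", "", 100, "", "CA", "I", -1,
                            np.zeros(3), is_hetero=True)]
        for i, d in enumerate(distances):
            ang = 2 * np.pi * i / max(len(distances), 1)
            atoms.append(AtomRecord(2 + i, "OE1", "O", "", 10 + i, "", "GLU",
                                    "A", 0,
                                    np.array([d * np.cos(ang),
                                              d * np.sin(ang), 0.0])))
        return StructureModel.from_atoms(atoms)

    def test_in_and_out_of_cutoff(self):
        shells = coordination_shell(self._ion_model([2.7, 2.9]), "CA")
        assert len(shells) == 1
        _, shell = shells[0]
        assert [r.partner_b[2] for r in shell] == [10]

    def test_equidistant_tie_preserved(self):
        _, shell = coordination_shell(self._ion_model([2.5, 2.5]), "CA")[0]
        assert len(shell) == 2
        assert shell[0].distance == pytest.approx(shell[1].distance, abs=1e-12)

    def test_empty_ion_selection_raises(self):
        model = build_interaction_fixture([("GLU", "ARG", 3.4, False)])
        with pytest.raises(EmptySelectionError):
            coordination_shell(model, "ZN")

    def test_conformation_fixture_site_occupied(self):
        model = build_conformation_fixture(ca_ion=True)
        shells = coordination_shell(model, "CA")
        assert len(shells) == 4             # one ion per protomer
        for _, shell in shells:
            resnums = {r.partner_b[2] for r in shell}
            assert {3893, 3967, 5001} <= resnums
            assert all(r.distance <= 2.8 for r in shell)


class TestContactShell:
    def test_single_atom_near_one_residue(self):
        atoms = [AtomRecord(1, "C1", "C", "", 900, "", "LIG", "L", -1,
                            np.zeros(3), is_hetero=True),
                 AtomRecord(2, "CA", "C", "", 10, "", "GLY", "A", 0,
                            np.array([3.9, 0.0, 0.0])),
                 AtomRecord(3, "CA", "C", "", 11, "", "GLY", "A", 0,
                            np.array([4.2, 0.0, 0.0]))]
        model = StructureModel.from_atoms(atoms)
        shell = contact_shell(model, "LIG", cutoff=4.0)
        assert [c.residue_number for c in shell] == [10]
        assert shell[0].min_distance == pytest.approx(3.9, abs=1e-9)

    def test_constructed_21_residue_lipid_pocket(self):
        # 21 residues placed within 5 A of a lipid tail, 9 decoys beyond
        rng = np.random.default_rng(12)
        atoms = [AtomRecord(1, "C1", "C", "", 900, "", "POV", "L", -1,
                            np.zeros(3), is_hetero=True),
                 AtomRecord(2, "C2", "C", "", 900, "", "POV", "L", -1,
                            np.array([0.0, 0.0, 4.0]), is_hetero=True)]
        serial = 3
        for i in range(21):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pos = direction * rng.uniform(2.0, 4.9)
            atoms.append(AtomRecord(serial, "CA", "C", "", 100 + i, "", "LEU",
                                    "A", 0, pos))
            serial += 1
        for i in range(9):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pos = direction * rng.uniform(9.5, 15.0)
            atoms.append(AtomRecord(serial, "CA", "C", "", 200 + i, "", "ALA",
                                    "A", 0, pos))
            serial += 1
        model = StructureModel.from_atoms(atoms)
        shell = contact_shell(model, "POV", cutoff=5.0)
        assert len(shell) == 21
        assert all(c.min_distance <= 5.0 for c in shell)
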