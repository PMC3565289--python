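"""Structure I/O and perception: PDB round trips, bonds, ligand, site."""

import numpy as np
import pytest

from mqsar.errors import (EmptyInputError, NoLigandError,
                          ParameterMissingError, PreconditionError)
from mqsar.structio import (MolecularSystem, binding_site,
                            count_rotatable_bonds, detect_ligand,
                            perceive_bonds, read_charge_table, read_pdb,
                            write_charge_table, write_pdb)

from conftest import chain_molecule


def _two_atom_system(element_a, element_b, distance):
    return chain_molecule([element_a, element_b], spacing=distance)


class TestPdbRoundTrip:
    def test_single_atom_file(self, tmp_path):
        path = tmp_path / "one.pdb"
        path.write_text(
            "ATOM      1  CA  ALA A   1      11.104  13.207   2.100"
            "  1.00  0.00           C\n")
        traj = read_pdb(path)
        assert traj.n_frames == 1
        assert traj.topology.n_atoms == 1
        np.testing.assert_allclose(traj.coords[0, 0],
                                   [11.104, 13.207, 2.100])

    def test_multi_model_counts(self, tmp_path, toy_pocket):
        system, _, _ = toy_pocket
        path = tmp_path / "traj.pdb"
        from mqsar.structio import Trajectory
        coords = np.stack([system.coords, system.coords + 0.1,
                           system.coords + 0.2])
        write_pdb(Trajectory(system, coords, np.arange(3.0)), path)
        traj = read_pdb(path)
        assert traj.n_frames == 3
        assert traj.topology.n_atoms == system.n_atoms

    def test_round_trip_preserves_identity_and_coords(self, tmp_path,
                                                      toy_pocket):
        system, _, manifest = toy_pocket
        path = tmp_path / "pocket.pdb"
        write_pdb(system, path)
        back = read_pdb(path).topology
        assert back.n_atoms == system.n_atoms == manifest.counts["atoms"]
        assert back.names == system.names
        assert back.residue_names == system.residue_names
        assert list(back.residue_seqs) == list(system.residue_seqs)
        np.testing.assert_allclose(back.coords, system.coords, atol=5e-4)

    def test_charges_via_sidecar_and_occupancy(self, tmp_path, toy_pocket):
        system, _, _ = toy_pocket
        pdb, csv = tmp_path / "s.pdb", tmp_path / "q.csv"
        write_pdb(system, pdb, charges_in_occupancy=True)
        write_charge_table(system, csv)
        by_occ = read_pdb(pdb, charges="occupancy").topology
        by_csv = read_pdb(pdb, charges=csv).topology
        np.testing.assert_allclose(by_occ.charges, system.charges, atol=5e-3)
        np.testing.assert_allclose(by_csv.charges, system.charges)
        assert read_charge_table(csv)[1] == pytest.approx(system.charges[0])

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(EmptyInputError):
            read_pdb(path)


class TestPerceiveBonds:
    @pytest.mark.parametrize("pair, distance, bonded", [
        (("C", "C"), 1.54, True),    # within 0.77+0.77+0.45
        (("C", "C"), 3.00, False),   # beyond any covalent threshold
        (("O", "H"), 0.96, True),    # hydroxyl
        (("H", "H"), 0.70, False),   # H-H never bonded
    ])
    def test_distance_rule(self, pair, distance, bonded):
        system = _two_atom_system(*pair, distance)
        assert ((0, 1) in system.bonds) is bonded

    def test_symmetric_and_reorder_invariant(self, toy_pocket):
        system, _, _ = toy_pocket
        reordered = system.subset(np.arange(system.n_atoms)[::-1])
        perceive_bonds(reordered)
        n = system.n_atoms
        remapped = {tuple(sorted((n - 1 - i, n - 1 - j)))
                    for i, j in system.bonds}
        assert remapped == reordered.bonds

    def test_unknown_element_reported(self):
        system = chain_molecule(["C", "C"])
        system.elements[1] = "XX"
        with pytest.raises(ParameterMissingError, match="XX"):
            perceive_bonds(system)


class TestDetectLigand:
    def test_picks_largest_hetero_component(self):
        elements = ["C"] * 20 + ["C"] * 8
        n = 28
        coords = np.zeros((n, 3))
        coords[:20, 0] = np.arange(20) * 1.5
        coords[20:, 0] = np.arange(8) * 1.5
        coords[20:, 1] = 30.0  # separate component
        system = MolecularSystem(
            serials=np.arange(1, n + 1), names=["C"] * n, elements=["C"] * n,
            residue_names=["LG1"] * 20 + ["LG2"] * 8,
            chain_ids=["L"] * n, residue_seqs=[1] * 20 + [2] * 8,
            insertion_codes=[""] * n, coords=coords, is_hetero=[True] * n)
        perceive_bonds(system)
        assert detect_ligand(system).atom_indices == tuple(range(20))

    def test_waters_and_ions_excluded(self, toy_pocket):
        system, ligand, _ = toy_pocket
        assert detect_ligand(system).atom_indices == ligand.atom_indices

    def test_apo_structure_raises(self):
        system = chain_molecule(["C", "C", "C"], hetero=False,
                                resname="ALA", chain="A")
        with pytest.raises(NoLigandError):
            detect_ligand(system)


class TestBindingSite:
    def _pocket_with_residue_at(self, distance):
        n = 4
        coords = np.array([[0.0, 0, 0], [1.5, 0, 0],
                           [distance, 0, 0], [distance + 1.5, 0, 0]])
        system = MolecularSystem(
            serials=np.arange(1, n + 1), names=["C"] * n, elements=["C"] * n,
            residue_names=["LIG", "LIG", "GLY", "GLY"],
            chain_ids=["L", "L", "A", "A"], residue_seqs=[1, 1, 2, 2],
            insertion_codes=[""] * n, coords=coords,
            is_hetero=[True, True, False, False])
        perceive_bonds(system)
        from mqsar.structio import LigandSelection
        return system, LigandSelection((0, 1))

    @pytest.mark.parametrize("nearest, included", [(7.9 + 1.5, True),
                                                   (8.1 + 1.5, False)])
    def test_cutoff_threshold(self, nearest, included):
        system, ligand = self._pocket_with_residue_at(nearest)
        site = binding_site(system, ligand, cutoff=8.0)
        assert (("A", 2, "", "GLY") in site) is included

    def test_matches_brute_force_scan(self):
        system, ligand, _ = __import__("mqsar.synthetic", fromlist=["x"]) \
            .make_toy_pocket(n_residues=30, seed=7)
        site = set(binding_site(system, ligand, cutoff=8.0))
        lig = set(ligand.atom_indices)
        expected = set()
        for key, idx in system.residues():
            if key[3] == "LIG":
                continue
            dmin = min(np.linalg.norm(system.coords[i] - system.coords[j])
                       for i in idx for j in lig)
            if dmin <= 8.0:
                expected.add(key)
        assert site == expected

    def test_monotone_in_cutoff(self, toy_pocket):
        system, ligand, _ = toy_pocket
        previous = set()
        for cutoff in (3.0, 5.0, 8.0, 12.0):
            current = set(binding_site(system, ligand, cutoff))
            assert previous <= current
            previous = current


class TestRotatableBonds:
    def test_ethane_has_none(self):
        assert count_rotatable_bonds(chain_molecule(["C", "C"])) == 0

    def test_cyclohexane_ring_bonds_excluded(self):
        angles = np.radians(np.arange(0, 360, 60))
        coords = 1.54 * np.column_stack(
            [np.cos(angles), np.sin(angles), np.zeros(6)])
        ring = MolecularSystem(
            serials=np.arange(1, 7), names=["C"] * 6, elements=["C"] * 6,
            residue_names=["LIG"] * 6, chain_ids=["L"] * 6,
            residue_seqs=[1] * 6, insertion_codes=[""] * 6, coords=coords,
            is_hetero=[True] * 6)
        perceive_bonds(ring)
        assert len(ring.bonds) == 6
        assert count_rotatable_bonds(ring) == 0

    def test_pentane_has_two(self):
        assert count_rotatable_bonds(
            chain_molecule(["C"] * 5, spacing=1.54)) == 2

    def test_amide_cn_excluded(self):
        # N-methylacetamide: the only non-terminal single bond is amide C-N
        coords = np.array([
            [0.0, 0.0, 0.0],       # methyl C
            [1.52, 0.0, 0.0],      # carbonyl C
            [2.135, 1.065, 0.0],   # carbonyl O
            [2.185, -1.152, 0.0],  # amide N
            [3.635, -1.152, 0.0],  # N-methyl C
        ])
        mol = MolecularSystem(
            serials=np.arange(1, 6), names=["C1", "C2", "O", "N", "C3"],
            elements=["C", "C", "O", "N", "C"], residue_names=["LIG"] * 5,
            chain_ids=["L"] * 5, residue_seqs=[1] * 5,
            insertion_codes=[""] * 5, coords=coords, is_hetero=[True] * 5)
        perceive_bonds(mol)
        assert (1, 3) in mol.bonds
        assert count_rotatable_bonds(mol) == 0


def test_empty_ligand_selection_rejected():
    from mqsar.structio import LigandSelection
    with pytest.raises(PreconditionError):
        LigandSelection(())
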