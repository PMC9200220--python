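import numpy as np
import pytest
from rdkit import Chem

from vscreen import chem_features as cf
from vscreen import pocket_extract as pe
from vscreen import synthetic_data as sd
from vscreen.errors import ConfigError, PDBParseError, VScreenError

MINI_PDB = """\
ATOM      1  N   GLY A   1      -1.458   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       0.551   1.417   0.000  1.00  0.00           C
HETATM    4  C1  XYZ A  90      20.000  20.000  20.000  1.00  0.00           C
END
"""


class TestParseStructure:
    def test_atoms_and_het_groups(self):
        s = pe.parse_structure(MINI_PDB)
        assert len(s.atoms) == 3
        assert list(s.het_groups) == [("XYZ", "A", 90)]

    def test_water_only_gives_zero_het_groups(self):
        text = "HETATM    1  O   HOH A 100       0.000   0.000   0.000  1.00  0.00           O\n"
        s = pe.parse_structure(text)
        assert s.het_groups == {}
        assert s.atoms == []

    def test_empty_file_raises(self):
        with pytest.raises(PDBParseError):
            pe.parse_structure("REMARK nothing here\nEND\n")

    def test_malformed_record_reports_line_number(self):
        text = MINI_PDB.replace("-1.458", "xx.xxx")
        with pytest.raises(PDBParseError) as err:
            pe.parse_structure(text)
        assert err.value.line_number == 1

    def test_toy_complex_matches_generator_metadata(self):
        text, meta = sd.generate_toy_complex(n_residues=6, n_near=3, seed=11)
        s = pe.parse_structure(text)
        assert len(s.atoms) == meta["n_protein_atoms"]
        assert list(s.het_groups) == [meta["ligand_id"]]
        assert len(s.residues()) == 6

    def test_altloc_keeps_highest_occupancy(self):
        text = (
            "ATOM      1  CA AGLY A   1       0.000   0.000   0.000  0.40  0.00           C\n"
            "ATOM      2  CA BGLY A   1       5.000   0.000   0.000  0.60  0.00           C\n"
        )
        s = pe.parse_structure(text)
        assert len(s.atoms) == 1
        assert s.atoms[0].x == 5.0

    def test_altloc_tie_broken_by_letter(self):
        text = (
            "ATOM      1  CA BGLY A   1       5.000   0.000   0.000  0.50  0.00           C\n"
            "ATOM      2  CA AGLY A   1       0.000   0.000   0.000  0.50  0.00           C\n"
        )
        s = pe.parse_structure(text)
        assert s.atoms[0].altloc == "A"

    def test_first_model_only(self):
        text = (
            "MODEL        1\n"
            + MINI_PDB.replace("END\n", "")
            + "ENDMDL\nMODEL        2\n"
            + MINI_PDB.replace("END\n", "")
            + "ENDMDL\nEND\n"
        )
        s = pe.parse_structure(text)
        assert len(s.atoms) == 3


class TestExtractPocket:
    def test_coincident_atom_included_any_radius(self):
        text = (
            "ATOM      1  CA  GLY A   1       1.000   2.000   3.000  1.00  0.00           C\n"
            "HETATM    2  C1  LIG A  90       1.000   2.000   3.000  1.00  0.00           C\n"
        )
        s = pe.parse_structure(text)
        pocket = pe.extract_pocket(s, ("LIG", "A", 90), pe.PocketConfig(radius=0.001))
        assert len(pocket.residues) == 1

    def test_planted_distances_at_cutoff(self):
        text, meta = sd.generate_toy_complex(
            n_residues=3, n_near=2, radius=10.0, seed=0, distances=[5.0, 9.9, 10.1]
        )
        s = pe.parse_structure(text)
        pocket = pe.extract_pocket(s, meta["ligand_id"], pe.PocketConfig(radius=10.0))
        assert [r[1] for r in pocket.residues] == [1, 2]

    def test_brute_force_distance_oracle(self):
        text, meta = sd.generate_toy_complex(n_residues=8, n_near=4, radius=10.0, seed=5)
        s = pe.parse_structure(text)
        lig = s.het_groups[meta["ligand_id"]]
        lig_xyz = np.array([[a.x, a.y, a.z] for a in lig])
        expected = []
        for key, atoms in sorted(s.residues().items()):
            xyz = np.array([[a.x, a.y, a.z] for a in atoms])
            dmin = min(
                float(np.linalg.norm(p - q)) for p in xyz for q in lig_xyz
            )
            if dmin <= 10.0:
                expected.append(key)
        pocket = pe.extract_pocket(s, meta["ligand_id"], pe.PocketConfig(radius=10.0))
        assert pocket.residues == expected
        assert [r[1] for r in pocket.residues] == meta["near_residues"]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_monotone_in_radius(self, seed):
        text, meta = sd.generate_toy_complex(n_residues=10, n_near=5, seed=seed)
        s = pe.parse_structure(text)
        small = pe.extract_pocket(s, meta["ligand_id"], pe.PocketConfig(radius=6.0))
        big = pe.extract_pocket(s, meta["ligand_id"], pe.PocketConfig(radius=14.0))
        assert set(small.residues) <= set(big.residues)

    def test_unknown_ligand_raises_key_error(self):
        s = pe.parse_structure(MINI_PDB)
        with pytest.raises(KeyError):
            pe.extract_pocket(s, ("NOP", "A", 1))

    def test_empty_pocket_is_not_an_error(self):
        s = pe.parse_structure(MINI_PDB)
        pocket = pe.extract_pocket(s, ("XYZ", "A", 90), pe.PocketConfig(radius=1.0))
        assert len(pocket) == 0


class TestPocketToMolecule:
    def test_glycine_bond_template(self):
        # oracle: glycine heavy atoms bond as N-CA, CA-C, C=O
        text, meta = sd.generate_toy_complex(n_residues=1, n_near=1, seed=0)
        s = pe.parse_structure(text)
        pocket = pe.extract_pocket(s, meta["ligand_id"])
        mol = pe.pocket_to_molecule(pocket)
        names = [a.name for a in pocket.atoms]
        bonds = {
            tuple(sorted((names[b.GetBeginAtomIdx()], names[b.GetEndAtomIdx()])))
            for b in mol.GetBonds()
        }
        assert bonds == {("CA", "N"), ("C", "CA"), ("C", "O")}

    def test_distant_residues_two_components(self):
        text, _ = sd.generate_toy_complex(
            n_residues=2, n_near=2, radius=60.0, seed=1, distances=[5.0, 55.0]
        )
        s = pe.parse_structure(text)
        pocket = pe.extract_pocket(s, ("LIG", "A", 900), pe.PocketConfig(radius=60.0))
        mol = pe.pocket_to_molecule(pocket)
        assert len(Chem.GetMolFrags(mol)) == 2

    def test_deterministic_sentences(self):
        text, meta = sd.generate_toy_complex(n_residues=4, n_near=2, seed=2)
        s = pe.parse_structure(text)
        pocket = pe.extract_pocket(s, meta["ligand_id"])
        s1 = cf.mol_to_sentence(pe.pocket_to_molecule(pocket))
        s2 = cf.mol_to_sentence(pe.pocket_to_molecule(pocket))
        assert s1.tokens == s2.tokens

    def test_unrecognized_element_raises(self):
        atom = pe.AtomRecord(1, "XX", "", "UNK", "A", 1, "", 0, 0, 0, 1.0, "QQ", False)
        pocket = pe.PocketStructure(residues=[("A", 1, "")], atoms=[atom])
        with pytest.raises(VScreenError, match="QQ"):
            pe.pocket_to_molecule(pocket)


class TestFeaturizePocket:
    def test_vector_length_300(self):
        text, meta = sd.generate_toy_complex(n_residues=3, n_near=2, seed=3)
        s = pe.parse_structure(text)
        pocket = pe.extract_pocket(s, meta["ligand_id"])
        table = cf.EmbeddingTable(dim=300, vectors={})
        fv = pe.featurize_pocket(pocket, table)
        assert fv.values.shape == (300,)

    def test_empty_table_zero_unk_gives_zero(self):
        text, meta = sd.generate_toy_complex(n_residues=2, n_near=1, seed=4)
        s = pe.parse_structure(text)
        pocket = pe.extract_pocket(s, meta["ligand_id"])
        fv = pe.featurize_pocket(pocket, cf.EmbeddingTable(dim=8, vectors={}))
        assert np.array_equal(fv.values, np.zeros(8))

    def test_disjoint_pocket_union_additivity(self):
        text, meta = sd.generate_toy_complex(n_residues=4, n_near=4, radius=40.0, seed=6,
                                             distances=[5.0, 8.0, 30.0, 35.0])
        s = pe.parse_structure(text)
        cfg_all = pe.PocketConfig(radius=40.0)
        pocket_all = pe.extract_pocket(s, meta["ligand_id"], cfg_all)
        near = pe.extract_pocket(s, meta["ligand_id"], pe.PocketConfig(radius=10.0))
        far_keys = set(pocket_all.residues) - set(near.residues)
        far = pe.PocketStructure(
            residues=sorted(far_keys),
            atoms=[a for a in pocket_all.atoms if a.residue_key in far_keys],
        )
        rng = np.random.default_rng(0)
        tokens = set()
        for p in (pocket_all, near, far):
            tokens |= set(cf.mol_to_sentence(pe.pocket_to_molecule(p)).tokens)
        table = cf.EmbeddingTable(
            dim=16, vectors={t: rng.standard_normal(16) for t in tokens}
        )
        v_all = pe.featurize_pocket(pocket_all, table).values
        v_near = pe.featurize_pocket(near, table).values
        v_far = pe.featurize_pocket(far, table).values
        np.testing.assert_allclose(v_all, v_near + v_far, atol=1e-10)
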