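import numpy as np
import pytest

from fodm.structure_io import (PdbParseError, SelectionError, UnitSelector,
                               effective_atoms, extract_sequence,
                               read_structure)

from conftest import atom_line


class TestReadStructure:
    def test_minimal_two_residue_file(self, two_residue_pdb):
        atoms = read_structure(two_residue_pdb)
        assert len(atoms) == 3
        assert {a.residue_number for a in atoms} == {1, 2}
        assert atoms[0].element == "C"

    def test_empty_text_raises(self):
        with pytest.raises(PdbParseError):
            read_structure("")

    def test_garbled_text_names_first_line(self):
        with pytest.raises(PdbParseError, match="GARBAGE"):
            read_structure("GARBAGE LINE\nMORE GARBAGE\n")

    def test_hetatm_only_is_no_polymer(self, make_pdb):
        text = make_pdb([
            atom_line(1, "O", "HOH", "A", 1, 0.0, 0.0, 0.0, record="HETATM"),
            atom_line(2, "C1", "LIG", "A", 2, 1.0, 0.0, 0.0, record="HETATM"),
        ])
        with pytest.raises(PdbParseError, match="no polymer atoms"):
            read_structure(text)

    def test_hetatm_and_waters_excluded(self, make_pdb):
        text = make_pdb([
            atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0),
            atom_line(2, "CA", "GLY", "A", 2, 3.0, 0.0, 0.0),
            atom_line(3, "O", "HOH", "A", 100, 9.0, 0.0, 0.0, record="HETATM"),
        ])
        atoms = read_structure(text)
        assert len(atoms) == 2
        assert all(a.residue_name != "HOH" for a in atoms)

    def test_multi_model_keeps_first(self):
        body = [
            "MODEL        1",
            atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0),
            atom_line(2, "CA", "GLY", "A", 2, 3.0, 0.0, 0.0),
            "ENDMDL",
            "MODEL        2",
            atom_line(1, "CA", "ALA", "A", 1, 9.0, 9.0, 9.0),
            atom_line(2, "CA", "GLY", "A", 2, 12.0, 9.0, 9.0),
            "ENDMDL",
            "END",
        ]
        atoms = read_structure("\n".join(body) + "\n")
        assert len(atoms) == 2
        assert np.allclose(atoms[0].position, [0.0, 0.0, 0.0])

    def test_altloc_highest_occupancy_wins(self, make_pdb):
        text = make_pdb([
            atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, occ=0.3, altloc="A"),
            atom_line(2, "CA", "ALA", "A", 1, 5.0, 0.0, 0.0, occ=0.7, altloc="B"),
            atom_line(3, "CA", "GLY", "A", 2, 3.0, 0.0, 0.0),
        ])
        atoms = read_structure(text)
        ala = [a for a in atoms if a.residue_name == "ALA"]
        assert len(ala) == 1
        assert np.allclose(ala[0].position, [5.0, 0.0, 0.0])

    def test_hydrogens_dropped(self, make_pdb):
        text = make_pdb([
            atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0),
            atom_line(2, "H", "ALA", "A", 1, 1.0, 0.0, 0.0),
            atom_line(3, "CA", "GLY", "A", 2, 3.0, 0.0, 0.0),
        ])
        atoms = read_structure(text)
        assert all(a.element != "H" for a in atoms)
        assert len(atoms) == 2


class TestEffectiveAtoms:
    def test_centroid_is_heavy_atom_mean(self, two_residue_pdb):
        atoms = read_structure(two_residue_pdb)
        eas = effective_atoms(atoms, UnitSelector("A"))
        # ALA has atoms at (0,0,0) and (2,0,0) -> centroid (1,0,0)
        assert np.allclose(eas.residues[0].centroid, [1.0, 0.0, 0.0])
        assert np.allclose(eas.residues[1].centroid, [5.0, 0.0, 0.0])

    def test_glycine_four_atom_hand_average(self, make_pdb):
        # hand average of N, CA, C, O positions
        positions = [(1.0, 2.0, 3.0), (2.0, 3.0, 1.0), (4.0, 0.0, 2.0), (1.0, 1.0, 2.0)]
        expected = np.mean(positions, axis=0)  # (2, 1.5, 2)
        text = make_pdb(
            [atom_line(i + 1, nm, "GLY", "A", 1, *p)
             for i, (nm, p) in enumerate(zip(["N", "CA", "C", "O"], positions))]
            + [atom_line(5, "CA", "ALA", "A", 2, 10.0, 0.0, 0.0)])
        eas = effective_atoms(read_structure(text), UnitSelector("A"))
        assert np.allclose(eas.residues[0].centroid, expected)
        assert np.allclose(expected, [2.0, 1.5, 2.0])

    def test_permutation_invariant_over_atom_order(self, make_pdb):
        lines = [
            atom_line(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0),
            atom_line(2, "CA", "ALA", "A", 1, 2.0, 1.0, 0.0),
            atom_line(3, "CA", "GLY", "A", 2, 5.0, 0.0, 0.0),
        ]
        a1 = read_structure(make_pdb(lines))
        a2 = list(reversed(a1))
        e1 = effective_atoms(a1, UnitSelector("A"))
        e2 = effective_atoms(a2, UnitSelector("A"))
        assert np.allclose(e1.coords, e2.coords)

    def test_centroid_inside_convex_hull_bounds(self, make_pdb):
        lines = [
            atom_line(1, "N", "ALA", "A", 1, -1.0, -2.0, 0.5),
            atom_line(2, "CA", "ALA", "A", 1, 2.0, 1.0, -0.5),
            atom_line(3, "CB", "ALA", "A", 1, 0.0, 4.0, 1.5),
            atom_line(4, "CA", "GLY", "A", 2, 9.0, 0.0, 0.0),
        ]
        eas = effective_atoms(read_structure(make_pdb(lines)), UnitSelector("A"))
        c = eas.residues[0].centroid
        assert (-1.0 <= c[0] <= 2.0) and (-2.0 <= c[1] <= 4.0) and (-0.5 <= c[2] <= 1.5)

    def test_range_selection_inclusive(self, make_pdb):
        lines = [atom_line(i, "CA", "GLY", "A", i, float(3 * i), 0.0, 0.0)
                 for i in range(1, 6)]
        eas = effective_atoms(read_structure(make_pdb(lines)),
                              UnitSelector.parse("A:2-4"))
        assert len(eas) == 3
        assert eas.residues[0].residue_id == "A:2"
        assert eas.residues[-1].residue_id == "A:4"

    def test_range_outside_chain_errors(self, two_residue_pdb):
        atoms = read_structure(two_residue_pdb)
        with pytest.raises(SelectionError):
            effective_atoms(atoms, UnitSelector("A", (100, 200)))

    def test_wrong_chain_errors(self, two_residue_pdb):
        atoms = read_structure(two_residue_pdb)
        with pytest.raises(SelectionError):
            effective_atoms(atoms, UnitSelector("B"))


class TestSequence:
    def test_letters_and_length(self, make_pdb):
        lines = [
            atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0),
            atom_line(2, "CA", "VAL", "A", 2, 3.0, 0.0, 0.0),
            atom_line(3, "CA", "LEU", "A", 3, 6.0, 0.0, 0.0),
        ]
        eas = effective_atoms(read_structure(make_pdb(lines)), UnitSelector("A"))
        assert extract_sequence(eas) == "AVL"
        assert len(extract_sequence(eas)) == len(eas)

    def test_nonstandard_residue_is_x_unless_mapped(self, make_pdb):
        lines = [
            atom_line(1, "CA", "MSE", "A", 1, 0.0, 0.0, 0.0),
            atom_line(2, "CA", "ALA", "A", 2, 3.0, 0.0, 0.0),
        ]
        atoms = read_structure(make_pdb(lines))
        assert extract_sequence(effective_atoms(atoms, UnitSelector("A"))) == "XA"
        mapped = effective_atoms(atoms, UnitSelector("A"),
                                 nonstandard_letters={"MSE": "M"})
        assert extract_sequence(mapped) == "MA"


class TestSelectorParsing:
    @pytest.mark.parametrize("text,chain,rng", [
        ("A", "A", None),
        ("B:10-20", "B", (10, 20)),
    ])
    def test_parse(self, text, chain, rng):
        sel = UnitSelector.parse(text)
        assert sel.chain_id == chain and sel.residue_range == rng

    @pytest.mark.parametrize("bad", ["", "A:x-y", ":1-5", "A:9-3"])
    def test_bad_selectors(self, bad):
        with pytest.raises(ValueError):
            UnitSelector.parse(bad)
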