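"""PDB input/output, selection language, COM and the T->U mutation."""

import numpy as np
import pytest

from baseflip import (DuplexSpec, build_duplex, center_of_mass,
                      mutate_thymine_to_uracil, read_pdb, select_atoms,
                      write_pdb)
from baseflip.errors import (AtomLookupError, EmptySetError, FormatError,
                             MutationError, SelectionError, TrajectoryError)
from conftest import PEPTIDE_PDB, TOY_PDB, random_rigid_transform


class TestReadPDB:
    def test_hand_written_columns(self, toy_pdb):
        st = read_pdb(toy_pdb)
        assert st.n_models == 1 and st.n_atoms == 3
        np.testing.assert_allclose(st.coords[0, 0],
                                   [11.104, 6.134, -6.504], atol=1e-6)
        assert [a.name for a in st.atoms] == ["N", "CA", "C"]
        assert st.atoms[1].element == "C"
        assert st.atoms[0].residue_name == "ALA"

    def test_multi_model(self, tmp_path):
        body = TOY_PDB.replace("HEADER    TOY\n", "").replace("END\n", "")
        text = f"MODEL        1\n{body}ENDMDL\nMODEL        2\n{body}ENDMDL\nEND\n"
        p = tmp_path / "two.pdb"
        p.write_text(text)
        st = read_pdb(p)
        assert st.n_models == 2
        np.testing.assert_allclose(st.coords[0], st.coords[1])

    def test_inconsistent_models_raise(self, tmp_path):
        body = TOY_PDB.replace("HEADER    TOY\n", "").replace("END\n", "")
        short = "".join(body.splitlines(keepends=True)[:2])
        text = f"MODEL        1\n{body}ENDMDL\nMODEL        2\n{short}ENDMDL\n"
        p = tmp_path / "bad.pdb"
        p.write_text(text)
        with pytest.raises(TrajectoryError):
            read_pdb(p)
        with pytest.warns(UserWarning):
            st = read_pdb(p, strict_models=False)
        assert st.n_models == 1

    def test_zero_atoms(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("HEADER    NOTHING\nEND\n")
        with pytest.raises(FormatError):
            read_pdb(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FormatError):
            read_pdb(tmp_path / "nope.pdb")


class TestWritePDB:
    def test_round_trip_toy(self, toy_pdb, tmp_path):
        st = read_pdb(toy_pdb)
        out = tmp_path / "out.pdb"
        write_pdb(st, out)
        back = read_pdb(out)
        np.testing.assert_allclose(back.coords, st.coords, atol=1e-3)
        assert [a.name for a in back.atoms] == [a.name for a in st.atoms]
        assert [a.residue_number for a in back.atoms] \
            == [a.residue_number for a in st.atoms]

    def test_duplex_rereads_34_residues(self, duplex, tmp_path):
        out = tmp_path / "duplex.pdb"
        write_pdb(duplex, out)
        # independent residue count straight off the text
        ids = {(line[21], line[22:26]) for line in out.read_text().splitlines()
               if line.startswith("ATOM")}
        assert len(ids) == 34
        assert len(read_pdb(out).residues()) == 34

    def test_multi_model_blocks(self, toy_pdb, tmp_path):
        st = read_pdb(toy_pdb)
        from baseflip import Structure
        st2 = Structure(st.atoms, np.repeat(st.coords, 2, axis=0))
        out = tmp_path / "two.pdb"
        write_pdb(st2, out)
        assert out.read_text().count("MODEL") >= 2
        assert read_pdb(out).n_models == 2


class TestSelection:
    def test_chain_and_calpha(self, peptide_pdb):
        st = read_pdb(peptide_pdb)
        sel = select_atoms(st, "chain A and calpha")
        assert len(sel) == 2
        assert sel.atom_names == ["CA", "CA"]

    def test_uracil_base_atoms(self, duplex):
        sel = select_atoms(duplex, "chain A and resid 12 and base")
        heavy = {n for n in sel.atom_names if not n.startswith("H")}
        assert heavy == {"N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"}
        hyd = {n for n in sel.atom_names if n.startswith("H")}
        assert hyd == {"H3", "H5", "H6"}

    def test_phosphate_count_17mer_strand(self, duplex):
        sel = select_atoms(duplex, "chain A and phosphate and element P")
        # independent count: every residue except the 5'-terminal one has P
        n_p = sum(1 for a in duplex.atoms
                  if a.chain_id == "A" and a.name == "P")
        assert len(sel) == n_p == 16

    def test_idempotent_and_conjunctive(self, duplex):
        a = select_atoms(duplex, "chain A and base")
        b = select_atoms(duplex, "chain A")
        c = select_atoms(duplex, "base")
        np.testing.assert_array_equal(
            a.indices, np.intersect1d(b.indices, c.indices))

    def test_or_and_not(self, duplex):
        both = select_atoms(duplex, "chain A or chain B")
        assert len(both) == duplex.n_atoms
        noh = select_atoms(duplex, "not hydrogen")
        assert all(not n.startswith("H") for n in noh.atom_names)

    def test_empty_result_is_not_an_error(self, duplex):
        assert len(select_atoms(duplex, "chain Z")) == 0

    def test_unknown_field(self, duplex):
        with pytest.raises(SelectionError):
            select_atoms(duplex, "flavour vanilla")


class TestCenterOfMass:
    def test_two_unit_atoms(self, duplex):
        from baseflip import Atom, Structure
        atoms = [Atom(1, "X1", "C", "UNK", "A", 1, mass=1.0),
                 Atom(2, "X2", "C", "UNK", "A", 1, mass=1.0)]
        st = Structure(atoms, np.array([[0., 0, 0], [2., 0, 0]]))
        np.testing.assert_allclose(
            center_of_mass(select_atoms(st, "chain A")), [1, 0, 0])

    def test_against_brute_force(self, duplex):
        sel = select_atoms(duplex, "chain A and resid 12 and base")
        num = np.zeros(3)
        den = 0.0
        for i in sel.indices:
            m = duplex.atoms[i].mass
            num += m * duplex.coords[0, i]
            den += m
        np.testing.assert_allclose(center_of_mass(sel), num / den, atol=1e-12)

    def test_single_atom(self, duplex):
        sel = select_atoms(duplex, "chain A and resid 12 and name N3")
        np.testing.assert_allclose(center_of_mass(sel), sel.positions[0])

    def test_empty_set(self, duplex):
        with pytest.raises(EmptySetError):
            center_of_mass(select_atoms(duplex, "chain Z"))

    def test_rigid_motion_equivariance(self, duplex):
        from baseflip import apply_transform
        rng = np.random.default_rng(4)
        sel_expr = "chain B and resid 23"
        for _ in range(5):
            t = random_rigid_transform(rng)
            moved = apply_transform(duplex, t)
            com0 = center_of_mass(select_atoms(duplex, sel_expr))
            com1 = center_of_mass(select_atoms(moved, sel_expr))
            np.testing.assert_allclose(com1, t.apply(com0), atol=1e-9)


class TestMutation:
    def test_methyl_removed(self):
        st = build_duplex(DuplexSpec("GAT", with_hydrogens=True))
        before = {a.name for a in st.atoms
                  if a.chain_id == "A" and a.residue_number == 3}
        mut = mutate_thymine_to_uracil(st, "A", 3)
        after = {a.name for a in mut.atoms
                 if a.chain_id == "A" and a.residue_number == 3}
        assert before - after == {"C7", "H71", "H72", "H73"}
        assert mut.residue_name_of("A", 3) == "DU"

    def test_other_atoms_untouched(self):
        st = build_duplex(DuplexSpec("GAT", with_hydrogens=True))
        mut = mutate_thymine_to_uracil(st, "A", 3)
        kept = [i for i, a in enumerate(st.atoms)
                if not (a.residue_number == 3 and a.chain_id == "A"
                        and a.name in ("C7", "H71", "H72", "H73"))]
        np.testing.assert_allclose(mut.coords[0], st.coords[0, kept], atol=0)

    def test_rejects_non_thymine(self, duplex):
        with pytest.raises(MutationError):
            mutate_thymine_to_uracil(duplex, "A", 12)  # already uracil

    def test_mutated_duplex_matches_direct_build(self):
        st = mutate_thymine_to_uracil(
            build_duplex(DuplexSpec("CAGGATGTATATATCTG", with_hydrogens=True)),
            "A", 12)
        direct = build_duplex(DuplexSpec("CAGGATGTATATATCTG", (12,),
                                         with_hydrogens=True))
        assert st.residue_name_of("A", 12) == direct.residue_name_of("A", 12)
        a = {x.name for x in st.atoms if x.residue_number == 12
             and x.chain_id == "A"}
        b = {x.name for x in direct.atoms if x.residue_number == 12
             and x.chain_id == "A"}
        # demethylation does not invent the H5 proton the direct build has
        assert b - a == {"H5"}
        assert a <= b
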