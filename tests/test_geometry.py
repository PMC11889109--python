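"""Flip-geometry descriptors: pseudo-dihedral schemes, distances, base-pair
and step parameters, duplex bend."""

import numpy as np
import pytest

from baseflip import (CPD, CPDa, CPDb, DuplexSpec, StepParameters,
                      apply_base_flip, apply_transform, base_pair_parameters,
                      bend_angle, build_duplex, flip_metrics, metrics_table,
                      pair_com_distance, pseudo_dihedral, select_atoms,
                      step_parameters, u_groove_distance, wc_hbond_distances,
                      write_pdb)
from baseflip.errors import AtomLookupError, SchemeError
from baseflip.geometry import _dihedral_points, scheme_groups
from conftest import random_rigid_transform


def dihedral_oracle(p0, p1, p2, p3):
    """Independent 4-point dihedral via plane normals."""
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return np.degrees(np.arctan2(np.dot(m, n2), np.dot(n1, n2)))


class TestPseudoDihedral:
    def test_analytic_four_points(self):
        # perpendicular construction: dihedral exactly 90 degrees
        p1 = np.array([1.0, 0.0, 0.0])
        p2 = np.array([0.0, 0.0, 0.0])
        p3 = np.array([0.0, 0.0, 1.0])
        p4 = np.array([0.0, 1.0, 1.0])
        assert _dihedral_points(p1, p2, p3, p4) == pytest.approx(
            dihedral_oracle(p1, p2, p3, p4), abs=1e-9)
        assert abs(_dihedral_points(p1, p2, p3, p4)) == pytest.approx(90.0)

    def test_flip_to_150_matches_com_oracle(self, duplex):
        flipped = apply_base_flip(duplex, ("A", 12), 150.0, "major")
        got = pseudo_dihedral(flipped, ("A", 12), CPD)
        assert got == pytest.approx(150.0, abs=1.0)
        # independent recomputation from exported group COMs
        coms = [g.com() for g in scheme_groups(flipped, ("A", 12), CPD)]
        assert abs(abs(dihedral_oracle(*coms)) - 150.0) < 1.0

    def test_rigid_motion_invariance(self, flipped_duplex):
        rng = np.random.default_rng(21)
        ref = {s.name: pseudo_dihedral(flipped_duplex, ("A", 12), s)
               for s in (CPD, CPDa, CPDb)}
        for _ in range(5):
            moved = apply_transform(flipped_duplex,
                                    random_rigid_transform(rng))
            for s in (CPD, CPDa, CPDb):
                assert pseudo_dihedral(moved, ("A", 12), s) \
                    == pytest.approx(ref[s.name], abs=1e-6)

    def test_groove_sign_convention(self, duplex):
        # a flip generated toward a groove reads with the matching sign in
        # the scheme that generated it
        for mag in (60, 120, 170):
            for s in (CPD, CPDa, CPDb):
                major = apply_base_flip(duplex, ("A", 12), mag, "major",
                                        scheme=s)
                minor = apply_base_flip(duplex, ("A", 12), mag, "minor",
                                        scheme=s)
                assert pseudo_dihedral(major, ("A", 12), s) > 0
                assert pseudo_dihedral(minor, ("A", 12), s) < 0

    def test_terminal_residue_fails(self, duplex):
        with pytest.raises(SchemeError):
            pseudo_dihedral(duplex, ("A", 17), CPD)
        with pytest.raises(SchemeError):
            pseudo_dihedral(duplex, ("A", 1), CPDb)


class TestGrooveDistance:
    def test_constructed_seven_angstrom(self):
        # uracil-bearing duplex with the opposite strand stripped down to a
        # single residue whose P is moved exactly 7 A from N1
        st = build_duplex(DuplexSpec("GAUAG"))
        n1 = st.coords[0, st.atom_index("A", 3, "N1")]
        keep = [i for i, a in enumerate(st.atoms)
                if a.chain_id == "A" or (a.chain_id == "B"
                                         and a.residue_number == 7)]
        from baseflip import Structure
        sub = Structure([st.atoms[i] for i in keep], st.coords[:, keep])
        pi = sub.atom_index("B", 7, "P")
        direction = sub.coords[0, pi] - n1
        sub.coords[0, pi] = n1 + 7.0 * direction / np.linalg.norm(direction)
        assert u_groove_distance(sub, ("A", 3)) == pytest.approx(7.0,
                                                                 abs=1e-9)

    def test_exhaustive_minimum_oracle(self, duplex, flipped_duplex):
        for st in (duplex, flipped_duplex):
            got = u_groove_distance(st, ("A", 12))
            n1 = st.coords[0, st.atom_index("A", 12, "N1")]
            brute = min(np.linalg.norm(st.coords[0, i] - n1)
                        for i, a in enumerate(st.atoms)
                        if a.name == "P" and a.chain_id == "B")
            assert got == pytest.approx(brute, abs=1e-12)

    def test_missing_n1(self, duplex):
        with pytest.raises(AtomLookupError):
            u_groove_distance(duplex, ("B", 40))


class TestHbonds:
    def test_paired_duplex_values(self, duplex):
        n1h3, o4h6 = wc_hbond_distances(duplex, ("A", 12), ("B", 23))
        assert n1h3 == pytest.approx(1.9, abs=0.3)
        assert o4h6 == pytest.approx(2.0, abs=0.3)

    def test_monotone_with_flip_angle(self, duplex):
        prev = wc_hbond_distances(duplex, ("A", 12), ("B", 23))
        for ang in (60, 120, 175):
            fl = apply_base_flip(duplex, ("A", 12), ang, "major")
            cur = wc_hbond_distances(fl, ("A", 12), ("B", 23))
            assert cur[0] > prev[0] and cur[1] > prev[1]
            prev = cur
        assert prev[0] > 5.0 and prev[1] > 5.0

    def test_hand_set_distance(self):
        from baseflip import Atom, Structure
        atoms = [Atom(1, "N1", "N", "DA", "B", 2),
                 Atom(2, "H3", "H", "DU", "A", 1),
                 Atom(3, "O4", "O", "DU", "A", 1),
                 Atom(4, "H61", "H", "DA", "B", 2)]
        st = Structure(atoms, np.array([[0.0, 0, 0], [2.0, 0, 0],
                                        [0.0, 5, 0], [0.0, 3, 0]]))
        d1, d2 = wc_hbond_distances(st, ("A", 1), ("B", 2))
        assert d1 == pytest.approx(2.0) and d2 == pytest.approx(2.0)

    def test_requires_hydrogens(self, duplex_noh):
        with pytest.raises(AtomLookupError):
            wc_hbond_distances(duplex_noh, ("A", 12), ("B", 23))


class TestPairComDistance:
    def test_identity_is_zero(self, duplex):
        assert pair_com_distance(duplex, ("A", 12), ("A", 12)) == 0.0

    def test_summation_oracle(self, duplex):
        got = pair_com_distance(duplex, ("A", 12), ("B", 23))
        coms = []
        for ch, num in (("A", 12), ("B", 23)):
            num_v, den = np.zeros(3), 0.0
            for i in duplex.residue_indices(ch, num):
                a = duplex.atoms[i]
                if a.element == "H":
                    continue
                num_v += a.mass * duplex.coords[0, i]
                den += a.mass
            coms.append(num_v / den)
        assert got == pytest.approx(np.linalg.norm(coms[0] - coms[1]),
                                    abs=1e-12)

    def test_selection_ordering(self, duplex):
        base = pair_com_distance(duplex, ("A", 12), ("B", 23), "base")
        nucleoside = pair_com_distance(duplex, ("A", 12), ("B", 23),
                                       "nucleoside")
        nucleotide = pair_com_distance(duplex, ("A", 12), ("B", 23))
        assert base < nucleoside < nucleotide

    def test_grows_with_flip(self, duplex, flipped_duplex):
        assert pair_com_distance(flipped_duplex, ("A", 12), ("B", 23)) \
            > pair_com_distance(duplex, ("A", 12), ("B", 23)) + 2.0


class TestPairAndStepParameters:
    def test_constructed_buckle_recovery(self, duplex):
        # rotate the partner base about the pair x-axis (long axis) and
        # recover the rotation as buckle
        from baseflip.geometry import _pair_frame
        st = duplex.copy()
        Tm, om = _pair_frame(st, (("A", 9), ("B", 26)))
        idx = select_atoms(st, "chain B and resid 26 and base").indices
        from baseflip.synthetic import _rotate_about_axis
        st.coords[0, idx] = _rotate_about_axis(st.coords[0, idx], om,
                                               Tm[:, 0], 20.0)
        g = base_pair_parameters(st, (("A", 9), ("B", 26)))
        assert abs(abs(g.buckle) - 20.0) < 2.0
        assert abs(g.opening) < 2.0

    def test_constructed_opening_recovery(self, duplex):
        from baseflip.geometry import _pair_frame
        st = duplex.copy()
        Tm, om = _pair_frame(st, (("A", 9), ("B", 26)))
        idx = select_atoms(st, "chain B and resid 26 and base").indices
        from baseflip.synthetic import _rotate_about_axis
        st.coords[0, idx] = _rotate_about_axis(st.coords[0, idx], om,
                                               Tm[:, 2], 35.0)
        g = base_pair_parameters(st, (("A", 9), ("B", 26)))
        assert abs(abs(g.opening) - 35.0) < 2.0
        assert abs(g.buckle) < 2.0

    def test_roll_round_trip(self):
        st = build_duplex(DuplexSpec("ATAT", steps=StepParameters(roll=5.0)))
        g = step_parameters(st, ((("A", 2), ("B", 7)), (("A", 3), ("B", 6))))
        assert g.roll == pytest.approx(5.0, abs=0.5)
        assert g.twist == pytest.approx(36.0, abs=0.5)
        assert g.rise == pytest.approx(3.38, abs=0.05)


class TestBendAngle:
    def test_straight_duplex(self, duplex):
        assert bend_angle(duplex) < 5.0

    def test_designed_forty_degree_arc(self):
        # 13-mer, twist 0, roll 5 deg/step: segment directions separated by
        # 8 steps x 5 deg = 40 deg
        st = build_duplex(DuplexSpec("A" * 13,
                                     steps=StepParameters(twist=0.0,
                                                          roll=5.0)))
        assert bend_angle(st) == pytest.approx(40.0, abs=5.0)

    def test_rotation_invariance(self, duplex):
        rng = np.random.default_rng(31)
        moved = apply_transform(duplex, random_rigid_transform(rng))
        assert bend_angle(moved) == pytest.approx(bend_angle(duplex),
                                                  abs=1e-6)

    def test_too_short(self):
        st = build_duplex(DuplexSpec("ACGT"))
        with pytest.raises(ValueError):
            bend_angle(st)


class TestBatchMetrics:
    def test_three_flipped_structures(self, duplex, tmp_path):
        want = {"s0": None, "s-100": -100.0, "s175": 175.0}
        write_pdb(duplex, tmp_path / "s0.pdb")
        write_pdb(apply_base_flip(duplex, ("A", 12), 100, "minor"),
                  tmp_path / "s-100.pdb")
        write_pdb(apply_base_flip(duplex, ("A", 12), 175, "major"),
                  tmp_path / "s175.pdb")
        table = metrics_table(sorted(tmp_path.glob("*.pdb")))
        assert len(table) == 3 and (table["error"] == "").all()
        by = table.set_index("structure")
        assert by.loc["s-100", "dihedral_deg"] == pytest.approx(-100, abs=1)
        assert by.loc["s175", "dihedral_deg"] == pytest.approx(175, abs=1)
        assert (by["d_u_groove_A"] > 0).all()

    def test_bad_file_is_logged_not_fatal(self, tmp_path):
        (tmp_path / "junk.pdb").write_text("not a pdb\n")
        table = metrics_table([tmp_path / "junk.pdb"])
        assert len(table) == 1 and table.loc[0, "error"] != ""

    def test_empty_input(self):
        assert len(metrics_table([])) == 0


class TestFlipMetricsRecord:
    def test_record_completeness(self, flipped_duplex):
        m = flip_metrics(flipped_duplex, ("A", 12), CPD)
        assert m.scheme == "CPD"
        assert m.dihedral == pytest.approx(175.0, abs=1.0)
        assert m.groove_side == 1
        assert m.d_u_groove > 0
        assert m.hbond_n1_h3 is not None and m.hbond_n1_h3 > 5.0
        assert m.com_pair_distance is not None
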