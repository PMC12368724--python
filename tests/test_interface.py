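"""Shrake-Rupley SASA, interface differencing, polarity and H-bonds."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from secdimer import (
    classify_polarity,
    detect_hbonds,
    interface_residues,
    read_pdb,
    shrake_rupley_sasa,
    write_pdb,
)
from secdimer.datasets import sfbgly_interface_residues
from secdimer.interface import Structure


def single_atom(radius_element="C"):
    return Structure.from_atoms([("A", 1, "ALA", "CA", radius_element, 0.0, 0.0, 0.0)])


class TestSasa:
    @given(r_el=st.sampled_from(["C", "N", "O", "S"]))
    def test_isolated_sphere_matches_closed_form(self, r_el):
        st_ = single_atom(r_el)
        sasa, _ = shrake_rupley_sasa(st_, probe=1.4, n_points=960)
        expected = 4.0 * np.pi * (st_.radius[0] + 1.4) ** 2
        assert abs(sasa[0] - expected) / expected < 0.005

    def test_probe_radius_enters_the_sphere(self):
        sasa, _ = shrake_rupley_sasa(single_atom("N"), probe=1.4)
        assert sasa[0] == pytest.approx(4 * np.pi * (1.55 + 1.4) ** 2, rel=1e-9)

    def test_distant_atoms_are_additive(self):
        st_ = Structure.from_atoms([
            ("A", 1, "ALA", "CA", "C", 0.0, 0.0, 0.0),
            ("A", 2, "ALA", "CA", "C", 100.0, 0.0, 0.0),
        ])
        sasa, res = shrake_rupley_sasa(st_)
        single, _ = shrake_rupley_sasa(single_atom())
        assert sasa.sum() == pytest.approx(2 * single[0], rel=1e-12)
        assert len(res) == 2

    @given(dx=st.floats(min_value=1.0, max_value=4.0))
    def test_adding_a_neighbour_only_lowers_sasa(self, dx):
        base, _ = shrake_rupley_sasa(single_atom())
        pair = Structure.from_atoms([
            ("A", 1, "ALA", "CA", "C", 0.0, 0.0, 0.0),
            ("A", 1, "ALA", "CB", "C", dx, 0.0, 0.0),
        ])
        sasa, _ = shrake_rupley_sasa(pair)
        assert sasa[0] <= base[0] + 1e-9

    def test_point_density_convergence_on_peptide(self, pentapeptide):
        s960, _ = shrake_rupley_sasa(pentapeptide, n_points=960)
        s4000, _ = shrake_rupley_sasa(pentapeptide, n_points=4000)
        assert abs(s4000.sum() - s960.sum()) / s4000.sum() < 0.01

    def test_matches_independent_reference_implementation(self, pentapeptide):
        struc = pytest.importorskip("biotite.structure")
        arr = struc.AtomArray(len(pentapeptide))
        arr.coord = pentapeptide.coords.astype(np.float32)
        arr.chain_id = pentapeptide.chain
        arr.res_id = pentapeptide.res_id
        arr.res_name = pentapeptide.res_name
        arr.atom_name = pentapeptide.atom_name
        arr.element = pentapeptide.element
        ref = struc.sasa(arr, probe_radius=1.4, point_number=960,
                         vdw_radii=pentapeptide.radius)
        mine, _ = shrake_rupley_sasa(pentapeptide, n_points=960)
        assert np.all(np.abs(mine - ref) <= 0.02 * np.maximum(ref, 1e-9))


class TestPdbIO:
    def test_three_atom_handwritten_pdb(self, tmp_path):
        text = (
            "ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N\n"
            "ATOM      2  CA  ALA A   1       2.400   2.100   3.100  1.00  0.00           C\n"
            "ATOM      3  O   ALA A   1       3.000   3.500   3.000  1.00  0.00           O\n"
            "END\n")
        p = tmp_path / "mini.pdb"
        p.write_text(text)
        st_ = read_pdb(p)
        assert len(st_) == 3
        assert np.allclose(st_.coords[0], [1.0, 2.0, 3.0])
        assert list(st_.element) == ["N", "C", "O"]

    def test_waters_are_excluded(self, tmp_path):
        text = (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "HETATM    2  O   HOH A 101       5.000   5.000   5.000  1.00  0.00           O\n"
            "END\n")
        p = tmp_path / "wat.pdb"
        p.write_text(text)
        st_ = read_pdb(p)
        assert len(st_) == 1
        assert "HOH" not in st_.res_name

    def test_write_read_round_trip(self, tmp_path, contact_dimer):
        p = write_pdb(contact_dimer, tmp_path / "dimer.pdb")
        back = read_pdb(p)
        assert np.allclose(back.coords, contact_dimer.coords, atol=1e-3)
        assert (back.atom_name == contact_dimer.atom_name).all()
        assert (back.chain == contact_dimer.chain).all()
        assert (back.res_id == contact_dimer.res_id).all()

    def test_unknown_element_needs_fallback_radius(self):
        atoms = [("A", 1, "UNK", "X1", "XX", 0.0, 0.0, 0.0)]
        with pytest.raises(ValueError, match="radius"):
            Structure.from_atoms(atoms)
        st_ = Structure.from_atoms(atoms, fallback_radius=1.7)
        assert st_.radius[0] == 1.7


class TestPolarity:
    @pytest.mark.parametrize("name,expected", [
        ("TYR", "apolar"), ("ASN", "polar"), ("GLY", "apolar"),
        ("ASP", "polar"), ("MET", "apolar"), ("ARG", "polar"),
    ])
    def test_classical_scheme(self, name, expected):
        assert classify_polarity(name) == expected

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            classify_polarity("XYZ")

    def test_published_interface_residue_set_is_63_percent_apolar(self):
        table = sfbgly_interface_residues()
        labels = [classify_polarity(n) for n in table["res_name"]]
        assert len(labels) == 30
        assert labels.count("apolar") == 19
        assert round(100 * labels.count("apolar") / len(labels)) == 63


class TestInterface:
    def test_distant_chains_have_empty_interface(self, distant_dimer):
        report = interface_residues(distant_dimer, "A", "B")
        assert report.n_residues == 0
        assert report.total_buried == pytest.approx(0.0, abs=1e-9)
        assert report.hbonds == []

    def test_contact_dimer_buries_area_symmetrically(self, contact_dimer):
        report = interface_residues(contact_dimer, "A", "B")
        assert report.n_residues > 0
        buried = {"A": 0.0, "B": 0.0}
        for r in report.residues:
            assert r.buried >= 0.0
            assert 0.0 <= r.relative_buried <= 100.0
            buried[r.chain] += r.buried
        assert buried["A"] == pytest.approx(buried["B"], rel=0.05)
        assert report.total_buried_per_monomer == pytest.approx(
            (buried["A"] + buried["B"]) / 2)

    def test_complex_sasa_not_larger_than_sum_of_chains(self, contact_dimer):
        a = contact_dimer.select_chain("A")
        b = contact_dimer.select_chain("B")
        sa, _ = shrake_rupley_sasa(a)
        sb, _ = shrake_rupley_sasa(b)
        sab, _ = shrake_rupley_sasa(contact_dimer)
        assert sab.sum() <= sa.sum() + sb.sum() + 1e-9

    def test_missing_chain_rejected(self, contact_dimer):
        with pytest.raises(KeyError):
            interface_residues(contact_dimer, "A", "C")


class TestHbonds:
    @staticmethod
    def donor_acceptor_pair(distance):
        return Structure.from_atoms([
            ("A", 1, "SER", "N",  "N", -20.0, 0.0, 0.0),
            ("A", 1, "SER", "CA", "C", -19.0, 0.0, 0.0),
            ("A", 1, "SER", "CB", "C", -1.5, 0.0, 0.0),
            ("A", 1, "SER", "OG", "O", 0.0, 0.0, 0.0),
            ("B", 5, "ASP", "N",  "N", 20.0, 0.0, 0.0),
            ("B", 5, "ASP", "CA", "C", 19.0, 0.0, 0.0),
            ("B", 5, "ASP", "CG", "C", distance + 1.3, 0.0, 0.0),
            ("B", 5, "ASP", "OD1", "O", distance, 0.0, 0.0),
        ])

    def test_pair_within_cutoff_is_one_bond(self):
        bonds = detect_hbonds(self.donor_acceptor_pair(2.9), "A", "B")
        assert len(bonds) == 1
        (b,) = bonds
        assert (b.donor_atom, b.acceptor_atom) == ("OG", "OD1")
        assert b.distance == pytest.approx(2.9)

    def test_pair_beyond_cutoff_is_no_bond(self):
        assert detect_hbonds(self.donor_acceptor_pair(4.0), "A", "B") == []

    def test_proline_backbone_nitrogen_cannot_donate(self):
        st_ = Structure.from_atoms([
            ("A", 1, "PRO", "N", "N", 0.0, 0.0, 0.0),
            ("B", 2, "ASP", "OD1", "O", 2.9, 0.0, 0.0),
        ])
        assert detect_hbonds(st_, "A", "B") == []

    def test_symmetric_mates_reported_separately(self):
        # two C2-related copies of the same donor/acceptor pair
        st_ = Structure.from_atoms([
            ("A", 1, "ASN", "ND2", "N", 0.0, 0.0, 0.0),
            ("B", 2, "ALA", "O",   "O", 2.9, 0.0, 0.0),
            ("B", 1, "ASN", "ND2", "N", 50.0, 0.0, 0.0),
            ("A", 2, "ALA", "O",   "O", 52.9, 0.0, 0.0),
        ])
        bonds = detect_hbonds(st_, "A", "B")
        assert len(bonds) == 2
        assert {b.donor_chain for b in bonds} == {"A", "B"}
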