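"""Bead structures, PDB round-trips and geometric primitives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ubconj as u
from ubconj import synthetic as syn
from ubconj.structures import PDBParseError, PDBWriteError

PDB_3CA = """\
ATOM      1  CA  ALA A   1      11.104   6.134  -6.504  1.00  0.00
ATOM      2  CA  GLY A   2      12.560   8.100  -4.000  1.00  0.00
ATOM      3  CA  LYS A   3       1.234   5.678   9.999  1.00  0.00
END
"""


class TestParsePDB:
    def test_three_records_in_file_order(self):
        s = u.parse_pdb(PDB_3CA)
        assert len(s) == 3
        assert s.res_names == ["ALA", "GLY", "LYS"]
        assert np.allclose(s.coords[0], [11.104, 6.134, -6.504])

    def test_altloc_keeps_blank_and_a_only(self):
        text = (
            "ATOM      1  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00\n"
            "ATOM      2  CA AGLY A   2       2.000   0.000   0.000  1.00  0.00\n"
            "ATOM      3  CA BGLY A   2       9.000   9.000   9.000  1.00  0.00\n"
            "ATOM      4  CA  LYS A   3       3.000   0.000   0.000  1.00  0.00\n"
        )
        s = u.parse_pdb(text)
        assert len(s) == 3
        assert np.allclose(s.coords[1], [2.0, 0.0, 0.0])  # altloc 'A' position

    def test_insertion_code_rejected(self):
        bad = "ATOM      1  CA  ALA A   1A      1.000   0.000   0.000  1.00  0.00\n"
        with pytest.raises(PDBParseError, match="insertion"):
            u.parse_pdb(bad)

    def test_malformed_columns_name_line_number(self):
        bad = PDB_3CA.replace("12.560", "12.5a0")
        with pytest.raises(PDBParseError, match="line 2"):
            u.parse_pdb(bad)

    def test_missing_ca_reported(self):
        text = (
            "ATOM      1  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00\n"
            "ATOM      2  CB  GLY A   2       2.000   0.000   0.000  1.00  0.00\n"
        )
        with pytest.raises(PDBParseError, match="A:2"):
            u.parse_pdb(text)

    def test_all_atom_mode_keeps_every_atom(self):
        text = (
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00\n"
            "ATOM      2  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00\n"
        )
        s = u.parse_pdb(text, mode="all-atom")
        assert len(s) == 2

    def test_ideal_helix_spacing_recovered(self):
        # generate CA positions at exactly 3.8 A spacing, re-measure
        t = np.arange(5)
        coords = np.stack([3.8 * t, np.zeros(5), np.zeros(5)], axis=1)
        lines = [
            f"ATOM  {i+1:5d}  CA  ALA A{i+1:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
            for i, (x, y, z) in enumerate(coords)
        ]
        s = u.parse_pdb("\n".join(lines))
        d = np.linalg.norm(np.diff(s.coords, axis=0), axis=1)
        assert np.allclose(d, 3.8, atol=1e-6)


class TestWritePDB:
    def test_round_trip_identity(self):
        s = u.parse_pdb(PDB_3CA)
        s2 = u.parse_pdb(u.write_pdb(s))
        assert s2.res_names == s.res_names
        assert np.array_equal(s2.res_ids, s.res_ids)
        assert np.allclose(s2.coords, s.coords, atol=5e-4)

    def test_one_record_per_bead_serials(self):
        body = syn.make_dummy_rigid_body(291, 20.0, seed=0)
        text = u.write_pdb(body)
        atom_lines = [l for l in text.splitlines() if l.startswith("ATOM")]
        assert len(atom_lines) == 291
        assert int(atom_lines[0][6:11]) == 1
        assert int(atom_lines[-1][6:11]) == 291

    def test_coordinate_rounding_to_three_decimals(self):
        s = u.parse_pdb(PDB_3CA)
        s.coords[0, 0] = 1.23456
        assert " 1.235" in u.write_pdb(s).splitlines()[0]

    def test_residue_overflow(self):
        s = u.parse_pdb(PDB_3CA)
        s.res_ids = np.array([1, 2, 10000])
        with pytest.raises(PDBWriteError):
            u.write_pdb(s)

    def test_cross_check_against_gemmi(self):
        gemmi = pytest.importorskip("gemmi")
        body = syn.make_dummy_rigid_body(25, 12.0, seed=4)
        st_ = gemmi.read_pdb_string(u.write_pdb(body))
        coords = np.array(
            [[a.pos.x, a.pos.y, a.pos.z]
             for mdl in st_ for ch in mdl for res in ch for a in res]
        )
        assert np.allclose(coords, body.coords, atol=5e-4)


class TestGeometry:
    def test_two_beads_rg(self):
        s = u.parse_pdb(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00\n"
            "ATOM      2  CA  ALA A   2      10.000   0.000   0.000  1.00  0.00\n"
        )
        assert u.radius_of_gyration(s) == pytest.approx(5.0)

    def test_solid_sphere_limit(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(20000, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts *= 20.0 * rng.uniform(size=(20000, 1)) ** (1 / 3)
        assert u.radius_of_gyration(pts) == pytest.approx(np.sqrt(3 / 5) * 20, rel=0.02)

    def test_single_bead_degenerate(self):
        with pytest.raises(ValueError):
            u.radius_of_gyration(np.zeros((1, 3)))

    @settings(deadline=None, max_examples=25)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_rg_matches_brute_force(self, seed):
        coords = np.random.default_rng(seed).normal(scale=15, size=(100, 3))
        centroid = coords.mean(axis=0)
        brute = np.sqrt(sum(np.sum((c - centroid) ** 2) for c in coords) / 100)
        assert u.radius_of_gyration(coords) == pytest.approx(brute, rel=1e-10)

    def test_collinear_histogram(self):
        coords = np.array([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0.0]])
        h = u.distance_histogram(coords, 1.0)
        assert h.total_weight == 3
        assert h.counts[7] == 1  # the 7.6 A pair

    @settings(deadline=None, max_examples=25)
    @given(st.integers(min_value=0, max_value=10_000),
           st.floats(min_value=0.05, max_value=2.0))
    def test_histogram_total_weight_invariant(self, seed, bin_width):
        coords = np.random.default_rng(seed).normal(scale=10, size=(40, 3))
        h = u.distance_histogram(coords, bin_width)
        assert h.total_weight == 40 * 39 / 2

    def test_histogram_mean_matches_brute_force(self):
        coords = np.random.default_rng(3).normal(scale=10, size=(50, 3))
        h = u.distance_histogram(coords, 0.1)
        mean_hist = (h.counts * h.centers).sum() / h.total_weight
        from scipy.spatial.distance import pdist

        assert abs(mean_hist - pdist(coords).mean()) < 0.05  # within half a bin
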