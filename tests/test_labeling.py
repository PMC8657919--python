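import math

import numpy as np
import pytest

from prospr.io_formats import Residue, StructureChain
from prospr.labeling import (ANGLE_GAP_CLASS, ASA_NA_CLASS, DIST_BIN_EDGES,
                             IGNORE, SS_CLASSES, SS_GAP_CLASS, atom_sasa,
                             bin_angle, bin_asa, bin_distance, cb_coordinate,
                             chain_relative_asa, dihedral, distance_labels,
                             label_chain, parse_dssp, relative_asa,
                             assign_secondary_structure, torsion_labels)
from prospr.synthetic_fixtures import HELIX_PHI, HELIX_PSI, ideal_helix


def _res(name, **atoms):
    return Residue(name=name,
                   atoms={k: np.asarray(v, float) for k, v in atoms.items()},
                   resseq=1)


class TestCbCoordinate:
    def test_glycine_uses_ca(self):
        r = _res("GLY", CA=(1, 2, 3))
        np.testing.assert_array_equal(cb_coordinate(r), [1, 2, 3])

    def test_alanine_uses_cb(self):
        r = _res("ALA", CA=(0, 0, 0), CB=(0, 0, 1))
        np.testing.assert_array_equal(cb_coordinate(r), [0, 0, 1])

    def test_missing_cb_falls_back_to_ca(self, caplog):
        r = _res("ALA", CA=(5, 5, 5))
        with caplog.at_level("WARNING"):
            out = cb_coordinate(r)
        np.testing.assert_array_equal(out, [5, 5, 5])
        assert "CB" in caplog.text

    def test_missing_ca_is_unresolved(self):
        r = _res("ALA", N=(0, 0, 0))
        assert cb_coordinate(r) is None


class TestBinning:
    @pytest.mark.parametrize("d,expected", [
        (0.0, 0), (3.99, 0), (4.0, 1), (5.999, 1), (6.0, 2),
        (7.999, 2), (8.0, 3), (19.999, 8), (20.0, 9), (100.0, 9),
    ])
    def test_distance_examples(self, d, expected):
        assert bin_distance(d) == expected

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            bin_distance(-0.1)

    def test_distance_brute_force_sweep(self):
        # exhaustive check against explicit interval logic on a 0.01 grid
        for d in np.arange(0.0, 25.0, 0.01):
            if d < 4.0:
                expected = 0
            elif d >= 20.0:
                expected = 9
            else:
                expected = 1 + int((d - 4.0) // 2.0)
            assert bin_distance(float(d)) == expected, d

    @pytest.mark.parametrize("a,expected", [
        (-180.0, 0), (-57.0, 12), (0.0, 18), (179.999, 35), (None, 36),
    ])
    def test_angle_examples(self, a, expected):
        assert bin_angle(a) == expected

    def test_angle_brute_force_sweep(self):
        for a in np.arange(-180.0, 180.0, 0.01):
            expected = min(int(math.floor((a + 180.0) / 10.0)), 35)
            assert bin_angle(float(a)) == expected, a

    @pytest.mark.parametrize("r,expected", [
        (0.0, 0), (0.05, 0), (0.95, 9), (1.0, 9), (None, 10),
    ])
    def test_asa_examples(self, r, expected):
        assert bin_asa(r) == expected

    def test_asa_brute_force_sweep(self):
        for r in np.arange(0.0, 1.0, 0.001):
            assert bin_asa(float(r)) == min(int(10 * r), 9)

    def test_distance_bins_monotone(self):
        ds = np.arange(0.0, 30.0, 0.05)
        bins = [bin_distance(float(d)) for d in ds]
        assert all(b2 >= b1 for b1, b2 in zip(bins, bins[1:]))

    def test_bin_edges_round_trip(self):
        # a representative distance of each class maps back to that class
        reps = [2.0] + [e + 1.0 for e in DIST_BIN_EDGES]
        assert [bin_distance(r) for r in reps] == list(range(10))


class TestDihedral:
    def test_trans_is_180(self):
        a = dihedral(np.array([1.0, 1, 0]), np.array([1.0, 0, 0]),
                     np.array([2.0, 0, 0]), np.array([2.0, -1, 0]))
        assert abs(a) == pytest.approx(180.0) or a == pytest.approx(-180.0)
        assert -180.0 <= a < 180.0

    def test_cis_is_0(self):
        a = dihedral(np.array([1.0, 1, 0]), np.array([1.0, 0, 0]),
                     np.array([2.0, 0, 0]), np.array([2.0, 1, 0]))
        assert a == pytest.approx(0.0, abs=1e-9)

    def test_collinear_returns_none(self):
        p = [np.array([float(k), 0, 0]) for k in range(4)]
        assert dihedral(*p) is None

    def test_helix_fixture_round_trip(self, helix12):
        res = helix12.residues
        for i in range(2, 9):
            phi = dihedral(res[i - 1].atoms["C"], res[i].atoms["N"],
                           res[i].atoms["CA"], res[i].atoms["C"])
            psi = dihedral(res[i].atoms["N"], res[i].atoms["CA"],
                           res[i].atoms["C"], res[i + 1].atoms["N"])
            assert phi == pytest.approx(HELIX_PHI, abs=2.0)
            assert psi == pytest.approx(HELIX_PSI, abs=2.0)

    def test_sign_convention_right_handed(self):
        # +90 degree rotation viewed along the b2 axis
        a = dihedral(np.array([0.0, 1, 0]), np.array([0.0, 0, 0]),
                     np.array([1.0, 0, 0]), np.array([1.0, 0, 1]))
        assert a == pytest.approx(90.0)


class TestRelativeAsa:
    def test_isolated_residue_near_max_exposure(self):
        chain = StructureChain("A", [
            _res("ALA", N=(0, 1.4, 0), CA=(0, 0, 0), C=(1.4, 0, 0),
                 O=(2.0, 1.0, 0), CB=(-0.8, -1.0, 0.8)),
        ])
        assert relative_asa(chain, 0) >= 0.9

    def test_caged_residue_buried(self):
        # surround a single CA by a dense cage of atoms on a sphere
        from prospr.labeling import _sphere_points

        cage_atoms = {"CA": np.zeros(3)}
        chain_res = [_res("ALA", **{k: tuple(v) for k, v in cage_atoms.items()})]
        residues = [chain_res[0]]
        for k, p in enumerate(_sphere_points(80) * 4.0):
            residues.append(_res("ALA", CA=tuple(p)))
        chain = StructureChain("A", residues)
        assert relative_asa(chain, 0, n_points=240) < 0.02

    def test_sphere_sampling_converged(self, helix12):
        a = chain_relative_asa(helix12, n_points=960)
        b = chain_relative_asa(helix12, n_points=1920)
        diffs = [abs(x - y) for x, y in zip(a, b)]
        assert max(diffs) < 0.02

    def test_absent_residue_is_na(self):
        chain = StructureChain("A", [
            _res("ALA", CA=(0, 0, 0), CB=(0, 0, 1.5)),
            Residue(name="UNK", atoms={}, resseq=2, present=False),
        ])
        assert relative_asa(chain, 1) is None

    def test_atom_sasa_single_atom_is_full_sphere(self):
        area = atom_sasa(np.zeros((1, 3)), np.array([1.7]))
        expected = 4 * np.pi * (1.7 + 1.4) ** 2
        assert area[0] == pytest.approx(expected, rel=1e-6)


class TestSecondaryStructure:
    def test_dssp_letter_table(self, tmp_path):
        chain = ideal_helix(4)
        dssp = tmp_path / "t.dssp"
        header = "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC\n"
        # classic DSSP layout: the SS letter sits at column index 16
        rows = "".join(f"    {k + 1:d}    {k + 1:d} A A  H  >\n"
                       for k in range(4))
        dssp.write_text(header + rows)
        classes = parse_dssp(dssp, chain)
        np.testing.assert_array_equal(classes, [0, 0, 0, 0])

    def test_fallback_labels_helix_interior_h(self):
        chain = ideal_helix(20)
        ss = assign_secondary_structure(chain)
        interior = ss[3:-3]
        frac_h = (interior == SS_CLASSES["H"]).mean()
        assert frac_h >= 0.8

    def test_missing_residue_gets_gap_class(self):
        chain = ideal_helix(10)
        chain.residues[4] = Residue(name="UNK", atoms={}, resseq=5,
                                    present=False)
        ss = assign_secondary_structure(chain)
        assert ss[4] == SS_GAP_CLASS


class TestLabelSet:
    def test_distance_map_symmetric_zero_diagonal(self, compact40):
        d = distance_labels(compact40)
        np.testing.assert_array_equal(d, d.T)
        assert np.all(np.diag(d) == 0)

    def test_chain_end_torsions_undefined(self, helix16_labels):
        assert helix16_labels.phi[0] == ANGLE_GAP_CLASS
        assert helix16_labels.psi[-1] == ANGLE_GAP_CLASS

    def test_missing_residue_propagates_to_all_labels(self):
        chain = ideal_helix(10)
        chain.residues[5] = Residue(name="UNK", atoms={}, resseq=6,
                                    present=False)
        labels = label_chain(chain, sasa_points=120)
        assert labels.ss[5] == SS_GAP_CLASS
        assert labels.phi[5] == ANGLE_GAP_CLASS
        assert labels.asa[5] == ASA_NA_CLASS
        assert np.all(labels.dist_bins[5] == IGNORE)
        assert labels.length == 10  # shape keeps a slot for the gap

    def test_helix_adjacent_cb_bin(self, helix16_labels):
        # ideal helix: |CB(i) - CB(i+1)| lies in (4, 6) -> distance class 1
        sub = np.diag(helix16_labels.dist_bins, k=1)
        assert np.all(sub == 1)
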