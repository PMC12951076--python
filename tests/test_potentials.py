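"""Potential derivation: binning, inverse Boltzmann, affinity weights,
local frames, orientation histograms, table serialization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hybridsp import atomtypes
from hybridsp import potentials as pot
from hybridsp.potentials import (
    ContactHistogram,
    OrientationHistogram,
    accumulate_contacts,
    accumulate_orientation,
    affinity_weight,
    build_local_frame,
    derive_orientation_potential,
    derive_potential,
    train_distance_potential,
)
from hybridsp.structio import ComplexRecord, Structure

from conftest import make_atom, single_pair_complex

LIG = atomtypes.get_scheme("ligand_sybyl23")
PROT = atomtypes.get_scheme("protein_residue100")


class TestAffinityWeight:
    def test_closed_forms(self):
        assert affinity_weight(6.0, 6.0) == pytest.approx(1.0)
        assert affinity_weight(12.0, 6.0) == pytest.approx(math.e)
        assert affinity_weight(0.0, 6.0) == pytest.approx(math.exp(-1.0))

    def test_invalid_mean_raises(self):
        with pytest.raises(ValueError):
            affinity_weight(5.0, 0.0)

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(0, 15), st.floats(0, 15), st.floats(0.5, 12))
    def test_strictly_increasing_in_affinity(self, a1, a2, mean):
        lo, hi = sorted((a1, a2))
        if hi - lo < 1e-6 * mean:   # below float resolution of the exponent
            return
        assert affinity_weight(lo, mean) < affinity_weight(hi, mean)


class TestAccumulateContacts:
    def test_pair_at_3A_lands_in_bin_5(self):
        hist = ContactHistogram("ligand_sybyl23", "protein_residue100")
        cx = single_pair_complex(3.0, "C.3", "GLY", "CA")
        report = accumulate_contacts(cx, 1.0, hist)
        assert report.in_range_pairs == 1
        i = LIG.index_of("C.3")
        j = PROT.index_of("GLY:CA")
        assert hist.counts[i, j, 5] == 1.0
        assert hist.counts.sum() == 1.0

    def test_upper_bound_is_half_open(self):
        hist = ContactHistogram("ligand_sybyl23", "protein_residue100")
        report = accumulate_contacts(single_pair_complex(6.0), 1.0, hist)
        assert report.in_range_pairs == 0
        assert hist.counts.sum() == 0.0

    def test_sub_r0_pair_is_clash_not_count(self):
        hist = ContactHistogram("ligand_sybyl23", "protein_residue100")
        report = accumulate_contacts(single_pair_complex(1.5), 1.0, hist)
        assert report.clashes == 1
        assert hist.counts.sum() == 0.0

    def test_conservation_of_total_weight(self):
        rng = np.random.default_rng(0)
        hist = ContactHistogram("ligand_sybyl23", "protein_residue100")
        total = 0.0
        for k in range(5):
            cx = _random_complex(rng, n_lig=3, n_rec=20)
            w = float(rng.uniform(0.5, 2.0))
            total += accumulate_contacts(cx, w, hist).total_weight
        assert hist.counts.sum() == pytest.approx(total, rel=1e-12)

    def test_kdtree_equals_naive_all_pairs(self):
        """Accelerated neighbor search must match the brute-force loop."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            cx = _random_complex(rng, n_lig=int(rng.integers(1, 6)),
                                 n_rec=int(rng.integers(5, 60)))
            hist = ContactHistogram("ligand_sybyl23", "protein_residue100")
            accumulate_contacts(cx, 1.0, hist)
            assert np.array_equal(hist.counts, _naive_histogram(cx))


def _random_complex(rng, n_lig=3, n_rec=20):
    lig_types = ["C.3", "N.3", "O.3", "C.ar"]
    residues = ["GLY", "ALA", "SER", "LEU"]
    lig = Structure([
        make_atom(i, f"C{i}", lig_types[i % 4].split(".")[0], "LIG", 1,
                  rng.uniform(-2, 2, 3), lig_types[i % 4])
        for i in range(n_lig)])
    rec = Structure([
        make_atom(i, "CA", "C", residues[i % 4], i + 1, rng.uniform(-7, 7, 3))
        for i in range(n_rec)])
    return ComplexRecord(receptor=rec, ligand=lig, complex_id="rnd")


def _naive_histogram(cx):
    """Independent oracle: explicit double loop over all atom pairs."""
    hist = ContactHistogram("ligand_sybyl23", "protein_residue100")
    for la in cx.ligand.atoms:
        i = LIG.index_of(atomtypes.ligand_type_of(la, cx.ligand))
        for ra in cx.receptor.atoms:
            j = PROT.index_of(atomtypes.protein_type_of(ra))
            d = float(np.linalg.norm(la.position - ra.position))
            if hist.r0 <= d < hist.rc:
                hist.counts[i, j, int((d - hist.r0) / hist.dr)] += 1.0
    return hist.counts


class TestDerivePotential:
    def test_pair_independent_counts_give_zero_energy(self):
        hist = ContactHistogram("ligand_sybyl23", "protein_residue100")
        profile = np.linspace(1.0, 3.0, hist.n_bins)
        hist.counts[:] = profile[None, None, :]
        table = derive_potential(hist)
        # identical per-pair distributions: g_ij == g, dW vanishes to
        # machine precision (the reference mean rounds at ~1e-15)
        assert np.max(np.abs(table.delta_w)) < 1e-12

    def test_two_pair_two_bin_hand_evaluation(self):
        """Hand-evaluated inverse Boltzmann on a 2-pair, 2-bin histogram.

        Pair A counts (2, 0), pair B counts (0, 2) on [2.0, 2.4) with
        midpoints 2.1, 2.3; pseudocount 0. Expected values computed
        independently below from the density/reference definitions.
        """
        hist = ContactHistogram("ligand_sybyl23", "protein_residue100",
                                r0=2.0, rc=2.4, dr=0.2)
        ia, ja = LIG.index_of("C.3"), PROT.index_of("GLY:CA")
        ib, jb = LIG.index_of("O.3"), PROT.index_of("ALA:SC1")
        hist.counts[ia, ja] = [2.0, 0.0]
        hist.counts[ib, jb] = [0.0, 2.0]
        cap = 10.0
        table = derive_potential(hist, min_pair_total=0.0, cap=cap)

        # independent oracle: direct evaluation of the defining formulas
        r = np.array([2.1, 2.3])
        shell = 4 * np.pi * r**2 * 0.2
        vol = (4 * np.pi / 3) * (2.4**3 - 2.0**3)
        g_a = (np.array([2.0, 0.0]) / shell) / (2.0 / vol)
        g_b = (np.array([0.0, 2.0]) / shell) / (2.0 / vol)
        g_ref = (g_a + g_b) / 2
        expected_a0 = -math.log(g_a[0] / g_ref[0])
        expected_b1 = -math.log(g_b[1] / g_ref[1])
        assert table.delta_w[ia, ja, 0] == pytest.approx(expected_a0, rel=1e-12)
        assert table.delta_w[ib, jb, 1] == pytest.approx(expected_b1, rel=1e-12)
        # zero-count bins of included pairs hit the cap
        assert table.delta_w[ia, ja, 1] == cap
        assert table.delta_w[ib, jb, 0] == cap

    def test_sparse_pair_rule(self):
        hist = ContactHistogram("ligand_sybyl23", "protein_residue100")
        i, j = LIG.index_of("C.3"), PROT.index_of("GLY:CA")
        hist.counts[i, j, :] = 5.0
        i2, j2 = LIG.index_of("O.3"), PROT.index_of("ALA:SC1")
        hist.counts[i2, j2, 0] = 0.5  # below min_pair_total=1
        table = derive_potential(hist, min_pair_total=1.0)
        assert np.all(table.delta_w[i2, j2] == 0.0)

    def test_empty_histogram_raises(self):
        hist = ContactHistogram("ligand_sybyl23", "protein_residue100")
        with pytest.raises(ValueError):
            derive_potential(hist)

    def test_energies_capped(self):
        hist = ContactHistogram("ligand_sybyl23", "protein_residue100")
        i, j = LIG.index_of("C.3"), PROT.index_of("GLY:CA")
        i2, j2 = LIG.index_of("O.3"), PROT.index_of("GLY:N")
        hist.counts[i, j, 0] = 1e9
        hist.counts[i, j, 1:] = 1e-9
        hist.counts[i2, j2, :] = 1.0
        table = derive_potential(hist, cap=5.0)
        assert np.all(np.abs(table.delta_w) <= 5.0)


class TestTrainDistance:
    def _complexes(self, affinities):
        rng = np.random.default_rng(1)
        out = []
        for k, a in enumerate(affinities):
            cx = _random_complex(rng, n_lig=2, n_rec=25)
            out.append(ComplexRecord(receptor=cx.receptor, ligand=cx.ligand,
                                     affinity=a, complex_id=f"c{k}"))
        return out

    def test_unweighted_equals_weighted_at_mean(self):
        cxs = self._complexes([6.0, 6.0, 6.0])
        t_u, h_u = train_distance_potential(cxs, weighted=False)
        t_w, h_w = train_distance_potential(cxs, weighted=True)
        assert np.array_equal(h_u.counts, h_w.counts)
        assert np.array_equal(t_u.delta_w, t_w.delta_w)

    def test_weighted_mean_and_weights(self):
        cxs = self._complexes([4.0, 8.0])
        _, hist = train_distance_potential(cxs, weighted=True)
        assert hist.affinity_mean == pytest.approx(6.0)
        # same geometry accumulated per complex; total weight ratio e^(2/3)
        w_lo, w_hi = math.exp(-1 / 3), math.exp(1 / 3)
        _, h0 = train_distance_potential([cxs[0]], weighted=False)
        _, h1 = train_distance_potential([cxs[1]], weighted=False)
        expected = w_lo * h0.counts + w_hi * h1.counts
        assert np.allclose(hist.counts, expected, rtol=1e-12)

    def test_empty_manifest_raises(self):
        with pytest.raises(ValueError, match="empty"):
            train_distance_potential([])

    def test_weighted_missing_affinity_raises(self):
        cxs = self._complexes([5.0, None])
        with pytest.raises(ValueError, match="affinit"):
            train_distance_potential(cxs, weighted=True)


class TestLocalFrame:
    def test_axis_aligned(self):
        origin, axes = build_local_frame([0, 0, 0], [1, 0, 0], [0, 1, 0])
        assert np.allclose(origin, [0, 0, 0])
        assert np.allclose(axes, np.eye(3))

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(3, 3))
        _, axes = build_local_frame(*pts)
        from scipy.stats import special_ortho_group
        rot = special_ortho_group.rvs(3, random_state=7)
        _, axes_rot = build_local_frame(*(pts @ rot.T))
        assert np.allclose(axes_rot, axes @ rot.T, atol=1e-10)

    def test_right_handed_orthonormal(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            _, axes = build_local_frame(*rng.normal(size=(3, 3)))
            assert np.allclose(axes @ axes.T, np.eye(3), atol=1e-10)
            assert np.linalg.det(axes) == pytest.approx(1.0)

    def test_collinear_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            build_local_frame([0, 0, 0], [1, 0, 0], [2, 0, 0])


def _frame_complex(lig_offset):
    """GLY backbone frame at known geometry plus one ligand atom."""
    rec = Structure([
        make_atom(0, "N", "N", "GLY", 1, [0, 0, 0]),
        make_atom(1, "CA", "C", "GLY", 1, [1.5, 0, 0]),
        make_atom(2, "C", "C", "GLY", 1, [2.0, 1.4, 0]),
        make_atom(3, "O", "O", "GLY", 1, [9.0, 9.0, 9.0]),
    ])
    lig = Structure([make_atom(0, "C1", "C", "LIG", 1, lig_offset, "C.3")])
    return ComplexRecord(receptor=rec, ligand=lig, complex_id="frame")


class TestOrientation:
    def test_atom_on_frame_z_axis_bins(self):
        # frame origin at N=(0,0,0); x along CA; z = x cross (C-N) = +z axis
        cx = _frame_complex([0, 0, 3.0])
        hist = OrientationHistogram()
        n = accumulate_orientation(cx, 1.0, hist)
        assert n == 1
        i = LIG.index_of("C.3")
        f = hist.frame_labels.index("GLY:bb")
        r_bin = int((3.0 - hist.r0) / hist.dr)          # = 2
        top_cos = hist.n_cos - 1                         # cos(theta) = +1
        phi_zero_bin = hist.n_phi // 2                   # phi = 0 convention
        assert hist.counts[i, f, r_bin, top_cos, phi_zero_bin] == 1.0

    def test_beyond_rc_not_counted(self):
        hist = OrientationHistogram()
        assert accumulate_orientation(_frame_complex([0, 0, 7.0]), 1.0, hist) == 0

    def test_rigid_motion_invariance(self):
        from scipy.stats import special_ortho_group
        cx = _frame_complex([1.0, 2.0, 2.5])
        h1 = OrientationHistogram()
        accumulate_orientation(cx, 1.0, h1)
        rot = special_ortho_group.rvs(3, random_state=11)
        tvec = np.array([4.0, -2.0, 7.0])
        moved = ComplexRecord(receptor=cx.receptor.transformed(rot, tvec),
                              ligand=cx.ligand.transformed(rot, tvec),
                              complex_id="m")
        h2 = OrientationHistogram()
        accumulate_orientation(moved, 1.0, h2)
        assert np.array_equal(h1.counts, h2.counts)

    def test_uniform_cells_give_zero_potential(self):
        hist = OrientationHistogram()
        hist.counts[:] = 2.0
        table = derive_orientation_potential(hist)
        assert np.max(np.abs(table.delta_w)) < 1e-12

    def test_concentrated_cell_is_favorable(self):
        hist = OrientationHistogram()
        hist.counts[:] = 1.0
        i = LIG.index_of("C.3")
        f = 0
        hist.counts[i, f, 3, 2, 1] = 50.0
        table = derive_orientation_potential(hist)
        assert table.delta_w[i, f, 3, 2, 1] < 0.0

    def test_empty_histogram_raises(self):
        with pytest.raises(ValueError):
            derive_orientation_potential(OrientationHistogram())


class TestTableIO:
    def test_distance_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(5)
        hist = ContactHistogram("ligand_sybyl23", "protein_residue100")
        hist.counts[rng.integers(0, 23, 40), rng.integers(0, 100, 40),
                    rng.integers(0, 20, 40)] = rng.uniform(1, 50, 40)
        table = derive_potential(hist, provenance="test")
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        pot.write_table(table, p1)
        again = pot.read_table(p1)
        pot.write_table(again, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert np.allclose(table.delta_w, again.delta_w, rtol=1e-5)

    def test_orientation_round_trip(self, tmp_path):
        hist = OrientationHistogram()
        hist.counts[:] = 1.0
        hist.counts[2, 1, 3, 4, 5] = 9.0
        table = derive_orientation_potential(hist)
        p = tmp_path / "o.tsv"
        pot.write_table(table, p)
        again = pot.read_table(p)
        assert isinstance(again, pot.OrientationTable)
        assert np.allclose(table.delta_w, again.delta_w, rtol=1e-5)
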