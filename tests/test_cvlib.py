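"""Collective variables: centres, distances, Q, Rg, reversal symmetry, I/O."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tetrafes import cvlib
from tetrafes.errors import InputError, ParseError


def _model(positions, ids, groups):
    return cvlib.BeadModel(np.asarray(positions, float), np.asarray(ids), np.asarray(groups, object))


def _four_bead_line():
    return _model([(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0)],
                  [1, 2, 3, 4], ["core"] * 4)


positive_d = st.lists(st.floats(0.1, 50.0), min_size=6, max_size=6).map(np.array)


class TestNucleosomeCenters:
    def test_single_core_beads_are_their_own_centers(self):
        centers = cvlib.nucleosome_centers(_four_bead_line())
        assert np.allclose(centers, [(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0)])

    def test_center_is_centroid_of_core_beads(self):
        m = _model([(0, 0, 0), (2, 0, 0)] + [(9, 9, 9)] * 3,
                   [1, 1, 2, 3, 4], ["core"] * 5)
        assert np.allclose(cvlib.nucleosome_centers(m)[0], (1, 0, 0))

    def test_flexible_beads_do_not_move_centers(self):
        base = cvlib.nucleosome_centers(_four_bead_line())
        m = _model([(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0), (100, 100, 100)],
                   [1, 2, 3, 4, 1], ["core", "core", "core", "core", "flexible"])
        assert np.allclose(cvlib.nucleosome_centers(m), base)

    def test_missing_nucleosome_is_an_input_error(self):
        m = _model([(0, 0, 0), (1, 0, 0), (2, 0, 0)], [1, 2, 3], ["core"] * 3)
        with pytest.raises(InputError):
            cvlib.nucleosome_centers(m)

    def test_core_bead_required_per_nucleosome(self):
        with pytest.raises(InputError, match="core"):
            _model([(0, 0, 0), (1, 0, 0)], [1, 2], ["core", "flexible"])


class TestDistanceVector:
    def test_colinear_centers(self):
        centers = np.array([(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0)], float)
        assert np.allclose(cvlib.distance_vector(centers).d, [1, 2, 3, 1, 2, 1])

    def test_unit_square(self):
        centers = np.array([(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)], float)
        r2 = np.sqrt(2.0)
        assert np.allclose(cvlib.distance_vector(centers).d, [1, r2, 1, 1, r2, 1])

    def test_rigid_rotation_invariance(self, rng):
        centers = rng.standard_normal((4, 3)) * 5
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        rotated = centers @ q.T + rng.standard_normal(3)
        assert np.allclose(cvlib.distance_vector(centers).d,
                           cvlib.distance_vector(rotated).d)


class TestFractionNativeContacts:
    def test_reference_gives_unity(self):
        ref = cvlib.ReferenceDistances(cvlib.DistanceVector([5, 6, 7, 5, 6, 5]))
        assert cvlib.fraction_native_contacts(ref.d_ref, ref) == pytest.approx(1.0)

    def test_one_sigma_displacement(self):
        # every |d - d_ref| = sigma = 2 nm -> Q = exp(-1/2)
        d_ref = np.array([5.0, 6, 7, 5, 6, 5])
        ref = cvlib.ReferenceDistances(cvlib.DistanceVector(d_ref), sigma=2.0)
        q = cvlib.fraction_native_contacts(cvlib.DistanceVector(d_ref + 2.0), ref)
        assert q == pytest.approx(np.exp(-0.5), rel=1e-12)

    def test_far_structures_have_negligible_q(self):
        d_ref = np.array([5.0, 6, 7, 5, 6, 5])
        ref = cvlib.ReferenceDistances(cvlib.DistanceVector(d_ref), sigma=2.0)
        assert cvlib.fraction_native_contacts(cvlib.DistanceVector(d_ref + 20.0), ref) < 1e-21

    def test_monotone_decrease_in_single_deviation(self):
        d_ref = np.array([5.0, 6, 7, 5, 6, 5])
        ref = cvlib.ReferenceDistances(cvlib.DistanceVector(d_ref))
        qs = []
        for delta in (0.0, 0.5, 1.0, 2.0, 4.0):
            d = d_ref.copy()
            d[2] += delta
            qs.append(cvlib.fraction_native_contacts(cvlib.DistanceVector(d), ref))
        assert all(a > b for a, b in zip(qs, qs[1:]))


class TestRadiusOfGyration:
    def test_single_bead(self):
        m = _model([(3, 4, 5)], [1], ["core"])
        assert cvlib.radius_of_gyration(m) == 0.0

    def test_symmetric_pair(self):
        m = _model([(-2, 0, 0), (2, 0, 0)], [1, 1], ["core", "core"])
        assert cvlib.radius_of_gyration(m) == pytest.approx(2.0)

    def test_square_matches_brute_force(self):
        s = 3.0
        pos = np.array([(0, 0, 0), (s, 0, 0), (s, s, 0), (0, s, 0)], float)
        m = _model(pos, [1, 1, 1, 1], ["core"] * 4)
        brute = np.sqrt(np.mean(np.sum((pos - pos.mean(0)) ** 2, axis=1)))
        assert cvlib.radius_of_gyration(m) == pytest.approx(brute)
        assert cvlib.radius_of_gyration(m) == pytest.approx(s / np.sqrt(2.0))


class TestReversalSymmetry:
    def test_stated_permutation(self):
        d = cvlib.DistanceVector([1, 2, 3, 4, 5, 6])
        assert np.allclose(cvlib.reverse_order(d).d, [6, 5, 3, 4, 2, 1])

    @given(positive_d)
    def test_involution(self, d):
        dd = cvlib.reverse_order(cvlib.reverse_order(d))
        assert np.array_equal(dd.d, d)

    def test_fixed_point_when_pairs_match(self):
        d = cvlib.DistanceVector([7, 3, 9, 4, 3, 7])  # d12=d34, d13=d24
        assert np.array_equal(cvlib.reverse_order(d).d, d.d)

    def test_symmetric_features_example(self):
        s = cvlib.symmetric_features(np.array([1.0, 2, 3, 4, 5, 6]))
        assert np.allclose(s, [7, 6, 7, 10, 3, 4])

    @given(positive_d)
    def test_features_invariant_under_reversal(self, d):
        s1 = cvlib.symmetric_features(d)
        s2 = cvlib.symmetric_features(cvlib.reverse_order(d))
        assert np.array_equal(s1, s2)

    @given(st.floats(0.5, 40.0), st.floats(0.5, 40.0))
    def test_sum_product_determines_unordered_pair(self, a, b):
        # recover {a, b} from (a+b, a*b) via the quadratic roots
        s, p = a + b, a * b
        disc = max(s * s - 4.0 * p, 0.0)
        roots = sorted([(s - np.sqrt(disc)) / 2, (s + np.sqrt(disc)) / 2])
        assert np.allclose(roots, sorted([a, b]), rtol=1e-6, atol=1e-6)

    def test_feature_jacobian_matches_finite_differences(self, rng):
        d = rng.uniform(2, 30, 6)
        J = cvlib.symmetric_features_jacobian(d)
        h = 1e-6
        for j in range(6):
            e = np.zeros(6)
            e[j] = h
            fd = (cvlib.symmetric_features(d + e) - cvlib.symmetric_features(d - e)) / (2 * h)
            assert np.allclose(J[..., :, j], fd, atol=1e-5)


class TestStructureIO:
    def test_csv_round_trip(self, tmp_path):
        m = _four_bead_line()
        path = tmp_path / "beads.csv"
        cvlib.write_bead_structure(m, path, format="csv")
        back = cvlib.read_bead_structure(path, format="csv")
        assert np.allclose(back.positions, m.positions)
        assert np.array_equal(back.nucleosome_id, m.nucleosome_id)
        assert back.n_nucleosomes == 4

    def test_missing_group_column_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("x,y,z,nucleosome_id\n0,0,0,1\n")
        with pytest.raises(ParseError, match="group"):
            cvlib.read_bead_structure(path, format="csv")

    def test_unknown_group_label_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("x,y,z,nucleosome_id,group\n0,0,0,1,core\n1,0,0,2,rigid\n")
        with pytest.raises(ParseError, match="line 3"):
            cvlib.read_bead_structure(path, format="csv")

    def test_pdb_round_trip_within_tolerance(self, tmp_path, rng):
        pos = rng.uniform(-5, 5, (8, 3))
        m = _model(pos, [1, 1, 2, 2, 3, 3, 4, 4],
                   ["core", "flexible"] * 4)
        path = tmp_path / "beads.pdb"
        cvlib.write_bead_structure(m, path, format="pdb")
        back = cvlib.read_bead_structure(path, format="pdb")
        assert np.allclose(back.positions, m.positions, atol=1e-3)
        assert np.array_equal(back.nucleosome_id, m.nucleosome_id)
        assert np.array_equal(back.group, m.group)

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(InputError):
            cvlib.read_bead_structure(tmp_path / "x.xyz", format="xyz")
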