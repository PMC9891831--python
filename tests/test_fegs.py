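import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fegsnet.fegs import (
    aac,
    build_curve,
    distance_quotient_matrix,
    dpc,
    eigen_feature,
    featurize_dataset,
    fegs_vector,
    read_feature_matrix,
    write_feature_matrix,
)
from fegsnet.physchem import PhysChemIndexTable, cone_geometry
from fegsnet.sequence_io import AMINO_ACIDS, LabeledDataset, ProteinSequence

residue_text = st.text(alphabet=AMINO_ACIDS, min_size=2, max_size=60)


@pytest.fixture(scope="module")
def alpha_geometry():
    """Alphabetical ordering: A rank 1 ... Y rank 20."""
    return cone_geometry(np.arange(1.0, 21.0))


@pytest.fixture(scope="module")
def a_last_geometry():
    """A holds rank 20 (largest property value)."""
    values = np.arange(1.0, 21.0)
    values[0] = 100.0
    return cone_geometry(values)


def power_iteration_lambda(M, iters=10_000, tol=1e-14):
    """Independent leading-eigenvalue oracle (plain power iteration)."""
    rng = np.random.default_rng(0)
    v = rng.random(M.shape[0])
    v /= np.linalg.norm(v)
    lam = 0.0
    for _ in range(iters):
        w = M @ v
        new_lam = float(v @ w)
        nw = np.linalg.norm(w)
        if nw == 0:
            return 0.0
        v = w / nw
        if abs(new_lam - lam) < tol:
            break
        lam = new_lam
    return float(v @ (M @ v))


def brute_force_path_lengths(points):
    """O(L^2 * L) per-pair edge summation oracle."""
    L = len(points)
    out = np.zeros((L, L))
    for i in range(L):
        for j in range(L):
            lo, hi = min(i, j), max(i, j)
            out[i, j] = sum(
                np.linalg.norm(points[k + 1] - points[k]) for k in range(lo, hi)
            )
    return out


class TestCurve:
    def test_starts_at_origin_with_n_plus_1_points(self, alpha_geometry):
        curve = build_curve("ACDMKV", alpha_geometry)
        assert curve.points.shape == (7, 3)
        np.testing.assert_array_equal(curve.points[0], np.zeros(3))

    def test_consecutive_points_distinct(self, alpha_geometry):
        curve = build_curve("ACACACAC", alpha_geometry)
        steps = np.diff(curve.points, axis=0)
        assert np.all(np.linalg.norm(steps, axis=1) > 0)

    def test_hand_derived_aa_walk(self, a_last_geometry):
        # With A at rank 20: vertex (1,0,1); pair point of AA is (1.25,0,1.25)
        curve = build_curve("AA", a_last_geometry)
        np.testing.assert_allclose(curve.points[1], (1.0, 0.0, 1.0), atol=1e-12)
        np.testing.assert_allclose(curve.points[2], (2.25, 0.0, 2.25), atol=1e-12)

    def test_first_step_uses_vertex_then_pair_points(self, alpha_geometry):
        s = "MKV"
        curve = build_curve(s, alpha_geometry)
        idx = [AMINO_ACIDS.index(c) for c in s]
        np.testing.assert_allclose(curve.points[1], alpha_geometry.vertex[idx[0]])
        np.testing.assert_allclose(
            curve.points[2] - curve.points[1], alpha_geometry.pair[idx[0], idx[1]]
        )

    def test_too_short_sequence_rejected(self, alpha_geometry):
        with pytest.raises(ValueError, match="at least 2"):
            build_curve("A", alpha_geometry)


class TestQuotientMatrix:
    def test_diagonal_zero_symmetric_bounded(self, alpha_geometry):
        M = distance_quotient_matrix(build_curve("ACDEFGHIKLMNP", alpha_geometry))
        np.testing.assert_array_equal(np.diag(M), 0.0)
        np.testing.assert_allclose(M, M.T)
        off = M[~np.eye(M.shape[0], dtype=bool)]
        assert np.all(off > 0) and np.all(off <= 1.0 + 1e-12)

    def test_adjacent_entries_are_one(self, alpha_geometry):
        M = distance_quotient_matrix(build_curve("WYACDMK", alpha_geometry))
        np.testing.assert_allclose(np.diag(M, 1), 1.0)

    def test_collinear_equal_steps_give_all_ones(self, alpha_geometry):
        # poly-A: every step after the first is the same AA pair vector, so
        # residue points P_1..P_N are collinear with equal spacing
        M = distance_quotient_matrix(build_curve("A" * 10, alpha_geometry))
        off = M[~np.eye(M.shape[0], dtype=bool)]
        np.testing.assert_allclose(off, 1.0)

    def test_matrix_size_is_sequence_length(self, alpha_geometry):
        M = distance_quotient_matrix(build_curve("ACDMKVLW", alpha_geometry))
        assert M.shape == (8, 8)

    def test_prefix_sum_path_lengths_match_brute_force(self, alpha_geometry):
        rng = np.random.default_rng(5)
        for length in (2, 3, 7, 19, 30):
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
            curve = build_curve(seq, alpha_geometry)
            pts = curve.points[1:]
            path = brute_force_path_lengths(pts)
            euclid = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
            M = distance_quotient_matrix(curve)
            expected = np.divide(
                euclid, path, out=np.zeros_like(path), where=path > 0
            )
            np.testing.assert_allclose(M, expected, atol=1e-12)

    def test_single_point_curve_rejected(self):
        from fegsnet.fegs import Curve3D

        with pytest.raises(ValueError, match="at least 2"):
            distance_quotient_matrix(Curve3D(np.zeros((2, 3))))


class TestEigenFeature:
    def test_two_by_two_exchange_matrix(self):
        assert eigen_feature(np.array([[0.0, 1.0], [1.0, 0.0]]), 2) == pytest.approx(0.5)

    def test_agrees_with_power_iteration_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            A = rng.random((50, 50))
            M = (A + A.T) / 2
            np.fill_diagonal(M, 0.0)
            assert eigen_feature(M, 50) == pytest.approx(
                power_iteration_lambda(M) / 50, abs=1e-8
            )

    def test_nonnegative_for_valid_quotient_matrices(self, alpha_geometry):
        rng = np.random.default_rng(3)
        for _ in range(5):
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=40))
            M = distance_quotient_matrix(build_curve(seq, alpha_geometry))
            assert eigen_feature(M, 40) >= 0

    def test_non_finite_entries_rejected(self):
        M = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError, match="non-finite"):
            eigen_feature(M, 2)

    def test_doubled_sequence_feature_stays_bounded(self, alpha_geometry):
        rng = np.random.default_rng(9)
        for _ in range(5):
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=25))
            lam = eigen_feature(distance_quotient_matrix(build_curve(seq, alpha_geometry)))
            lam2 = eigen_feature(
                distance_quotient_matrix(build_curve(seq + seq, alpha_geometry))
            )
            assert lam2 <= 2 * lam + 1


class TestCompositions:
    @pytest.mark.parametrize(
        "seq, checks",
        [
            ("AAAA", {"A": 1.0}),
            ("ACDE", {"A": 0.25, "C": 0.25, "D": 0.25, "E": 0.25, "F": 0.0}),
        ],
    )
    def test_aac_examples(self, seq, checks):
        v = aac(seq)
        for residue, expected in checks.items():
            assert v[AMINO_ACIDS.index(residue)] == pytest.approx(expected)

    def test_dpc_examples(self):
        v = dpc("AAA")
        assert v[0] == pytest.approx(1.0)  # AA is the first dipeptide column
        v = dpc("ACAC")
        ac = AMINO_ACIDS.index("A") * 20 + AMINO_ACIDS.index("C")
        ca = AMINO_ACIDS.index("C") * 20 + AMINO_ACIDS.index("A")
        assert v[ac] == pytest.approx(2 / 3)
        assert v[ca] == pytest.approx(1 / 3)

    @given(residue_text)
    def test_compositions_are_distributions(self, seq):
        a, d = aac(seq), dpc(seq)
        assert a.sum() == pytest.approx(1.0)
        assert d.sum() == pytest.approx(1.0)
        assert np.all(a >= 0) and np.all(d >= 0)

    @given(residue_text, st.randoms(use_true_random=False))
    def test_aac_invariant_under_any_permutation(self, seq, rnd):
        shuffled = list(seq)
        rnd.shuffle(shuffled)
        np.testing.assert_allclose(aac(seq), aac("".join(shuffled)))

    def test_dpc_invariant_under_dipeptide_multiset_preserving_permutation(self):
        # ACAAC and AACAC share the dipeptide multiset {AC, AC, CA, AA}
        np.testing.assert_allclose(dpc("ACAAC"), dpc("AACAC"))

    def test_dpc_sees_order_where_aac_does_not(self):
        assert not np.allclose(dpc("ACAC"), dpc("CACA"))
        np.testing.assert_allclose(aac("ACAC"), aac("CACA"))

    def test_empty_and_short_inputs_rejected(self):
        with pytest.raises(ValueError):
            aac("")
        with pytest.raises(ValueError):
            dpc("A")


class TestFegsVector:
    def test_dimension_is_p_plus_420(self, small_table):
        v = fegs_vector("ACDMKVLWYH", small_table)
        assert v.shape == (len(small_table) + 420,)

    def test_single_property_table_gives_421(self, small_table):
        one = small_table.subset(1)
        assert fegs_vector("ACDMKVLWYH", one).shape == (421,)

    def test_reversal_changes_eigen_block_not_aac(self, small_table):
        P = len(small_table)
        v1, v2 = fegs_vector("ACD", small_table), fegs_vector("DCA", small_table)
        np.testing.assert_allclose(v1[P : P + 20], v2[P : P + 20])
        assert not np.allclose(v1[:P], v2[:P])

    def test_deterministic_bit_identical(self, small_table):
        v1 = fegs_vector("MKVLWYACDE", small_table)
        v2 = fegs_vector("MKVLWYACDE", small_table)
        np.testing.assert_array_equal(v1, v2)

    def test_matches_scalar_pipeline(self, small_table):
        """The vectorised per-property block equals the documented scalar path."""
        seq = "ACDMKVLWYHAC"
        v = fegs_vector(seq, small_table)
        for p, geometry in enumerate(small_table.geometries):
            lam = eigen_feature(distance_quotient_matrix(build_curve(seq, geometry)))
            assert v[p] == pytest.approx(lam, abs=1e-9)


class TestFeaturizeDataset:
    def test_rows_match_per_sequence_vectors(self, small_table, tiny_dataset):
        X, layout = featurize_dataset(tiny_dataset, small_table)
        assert X.shape == (len(tiny_dataset), len(small_table) + 420)
        np.testing.assert_allclose(
            X[3], fegs_vector(tiny_dataset.sequences[3], small_table), atol=1e-9
        )
        assert len(layout.columns) == X.shape[1]

    def test_empty_dataset_keeps_layout(self, small_table):
        X, layout = featurize_dataset(LabeledDataset([], []), small_table)
        assert X.shape == (0, len(small_table) + 420)
        assert len(layout) == len(small_table) + 420

    def test_failing_sequence_is_named(self, small_table):
        ds = LabeledDataset([ProteinSequence("shorty", "A")], [1])
        with pytest.raises(ValueError, match="shorty"):
            featurize_dataset(ds, small_table)


def test_feature_matrix_file_round_trip(tmp_path, small_table, tiny_dataset):
    X, layout = featurize_dataset(tiny_dataset, small_table)
    path = tmp_path / "features.tsv"
    write_feature_matrix(path, tiny_dataset.ids, X, layout)
    ids, X2, layout2 = read_feature_matrix(path)
    assert ids == tiny_dataset.ids
    assert layout2.columns == layout.columns
    assert layout2.descriptor == "fegs"
    np.testing.assert_allclose(X2, X, rtol=1e-9)
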