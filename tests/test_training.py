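import numpy as np
import pytest

from emts2pca import (
    build_rms_profile,
    classify_by_rms,
    compute_rms,
    validate_training_matrix,
)
from emts2pca.data_model import (
    ATTRIBUTED_A,
    ATTRIBUTED_B,
    REJECTED,
    UNATTRIBUTED,
    DataError,
)
from emts2pca.training import RmsProfile, build_pca_space


class TestPcaSpace:
    def test_two_gene_eigendecomposition_matches_closed_form(self):
        # 2 x n matrix: sample covariance C = X X^T / n has a closed form
        x = np.array([[1.0, -1.0, 2.0, -2.0], [0.5, -0.5, 1.5, -1.5]])
        space = build_pca_space(x)
        c = x @ x.T / x.shape[1]
        a, b, d = c[0, 0], c[0, 1], c[1, 1]
        tr, det = a + d, a * d - b * b
        lam1 = (tr + np.sqrt(tr**2 - 4 * det)) / 2
        lam2 = (tr - np.sqrt(tr**2 - 4 * det)) / 2
        np.testing.assert_allclose(space.eigenvalues[:2], [lam1, lam2], atol=1e-12)
        v1 = np.array([b, lam1 - a])
        v1 = v1 / np.linalg.norm(v1)
        got = space.axes[:, 0]
        np.testing.assert_allclose(np.abs(got @ v1), 1.0, atol=1e-10)

    def test_total_variance_conserved_in_projection(self, rng):
        x = rng.normal(size=(30, 8))
        space = build_pca_space(x)
        assert np.sum(space.coords**2) == pytest.approx(np.sum(x**2))

    def test_matches_sklearn_pca_on_centered_rows(self, rng):
        sklearn = pytest.importorskip("sklearn.decomposition")
        x = rng.normal(size=(40, 10))
        x -= x.mean(axis=1, keepdims=True)
        space = build_pca_space(x)
        # sklearn PCA treats rows of x.T (samples) as observations; its
        # components on pre-centered data span the same leading directions
        pca = sklearn.PCA(n_components=3).fit(x.T)
        for k in range(3):
            cos = abs(pca.components_[k] @ space.axes[:, k])
            assert cos == pytest.approx(1.0, abs=1e-8)

    def test_deterministic_sign_convention(self, rng):
        x = rng.normal(size=(25, 6))
        s1 = build_pca_space(x)
        s2 = build_pca_space(x.copy())
        np.testing.assert_array_equal(s1.axes, s2.axes)
        for k in range(s1.axes.shape[1]):
            j = np.argmax(np.abs(s1.axes[:, k]))
            assert s1.axes[j, k] > 0

    def test_duplicate_columns_projection_deterministic(self):
        col = np.array([1.0, -2.0, 0.5])
        x = np.column_stack([col, col, -col, -col])
        space = build_pca_space(x)
        assert space.eigenvalues[0] > 0
        np.testing.assert_allclose(space.coords[0], space.coords[1], atol=1e-12)


class TestComputeRms:
    def test_query_at_barycenter_is_zero(self):
        ref = np.array([[0.0, 0.0], [2.0, 2.0], [5.0, 5.0]])
        is_g = np.array([True, True, False])
        assert compute_rms(ref, is_g, np.array([1.0, 1.0]), [0, 1]) == 0.0

    def test_single_axis_distance(self):
        ref = np.array([[0.0], [0.0]])
        is_g = np.array([True, True])
        assert compute_rms(ref, is_g, np.array([3.0]), [0]) == pytest.approx(3.0)

    def test_three_axes_matches_direct_arithmetic(self):
        ref = np.array([[1.0, 2.0, 3.0], [3.0, 0.0, 1.0]])
        is_g = np.array([True, True])
        q = np.array([4.0, -1.0, 2.0])
        bary = ref.mean(axis=0)  # (2, 1, 2)
        expect = np.sqrt(((q - bary) ** 2).mean())
        assert compute_rms(ref, is_g, q, [0, 1, 2]) == pytest.approx(expect)

    def test_empty_axis_subset_errors(self):
        with pytest.raises(DataError):
            compute_rms(np.zeros((2, 2)), np.array([True, True]), np.zeros(2), [])


def _profile(ref, is_a, query):
    return build_rms_profile(np.asarray(ref, float), np.asarray(is_a), np.asarray(query, float), [0, 1])


class TestClassifyByRms:
    def test_query_within_group_a_range_attributed(self):
        ref = [[0, 0], [1, 0], [0, 1], [10, 10], [11, 10], [10, 11]]
        is_a = [True] * 3 + [False] * 3
        assert classify_by_rms(_profile(ref, is_a, [0.4, 0.4])) == ATTRIBUTED_A

    def test_label_swap_symmetry(self):
        ref = [[0, 0], [1, 0], [0, 1], [10, 10], [11, 10], [10, 11]]
        is_a = np.array([True] * 3 + [False] * 3)
        q = [10.4, 10.4]
        assert classify_by_rms(_profile(ref, is_a, q)) == ATTRIBUTED_B
        assert classify_by_rms(_profile(ref, ~np.array(is_a), q)) == ATTRIBUTED_A

    def test_query_far_from_both_unattributed(self):
        ref = [[0, 0], [1, 0], [0, 1], [10, 10], [11, 10], [10, 11]]
        is_a = [True] * 3 + [False] * 3
        assert classify_by_rms(_profile(ref, is_a, [300, -300])) == UNATTRIBUTED

    def test_midpoint_of_mirror_groups_unattributed(self):
        ref = [[-5, 0], [-6, 1], [-6, -1], [5, 0], [6, 1], [6, -1]]
        is_a = [True] * 3 + [False] * 3
        assert classify_by_rms(_profile(ref, is_a, [0.0, 0.0])) == UNATTRIBUTED

    def test_interleaved_reference_groups_rejected(self):
        # one A sample farther from A's barycenter than a B sample is
        ref = [[0, 0], [0.2, 0], [40, 0], [10, 0], [10.5, 0], [9.5, 0]]
        is_a = [True] * 3 + [False] * 3
        assert classify_by_rms(_profile(ref, is_a, [0.1, 0])) == REJECTED


class TestValidateTrainingMatrix:
    truth = {"s1": True, "s2": True, "s3": False}

    def test_one_correct_rest_unattributed_validates(self):
        decisions = {"s1": ATTRIBUTED_A, "s2": UNATTRIBUTED, "s3": UNATTRIBUTED}
        assert validate_training_matrix(decisions, self.truth) == (True, 1)

    def test_zero_correct_not_validated(self):
        decisions = {"s1": UNATTRIBUTED, "s2": UNATTRIBUTED, "s3": UNATTRIBUTED}
        assert validate_training_matrix(decisions, self.truth) == (False, 0)

    def test_any_misclassification_invalidates(self):
        decisions = {"s1": ATTRIBUTED_A, "s2": ATTRIBUTED_A, "s3": ATTRIBUTED_A}
        valid, c = validate_training_matrix(decisions, self.truth)
        assert not valid and c == 2

    def test_rejected_decisions_are_neutral(self):
        decisions = {"s1": ATTRIBUTED_A, "s2": REJECTED, "s3": REJECTED}
        assert validate_training_matrix(decisions, self.truth) == (True, 1)


class TestContinuationCheck:
    def _matrix(self, decisions, truth):
        from emts2pca.combinatorics import HalfMatrix, TenSampleDesign
        from emts2pca.training import TrainingMatrix, validate_training_matrix

        design = TenSampleDesign(
            HalfMatrix("A", ("x1", "x2")), HalfMatrix("B", ("y1", "y2"))
        )
        valid, c = validate_training_matrix(decisions, truth)
        return TrainingMatrix(
            design=design, gene_ids=["g1", "g2"], values=np.zeros((2, 4)),
            validated=valid, c=c, decisions=decisions,
        )

    def test_boundary_at_ninety_percent_inclusive(self):
        from emts2pca import continuation_check

        learning = [f"s{i}" for i in range(10)]
        truth = {s: True for s in learning}
        # exactly 9 of 10 covered
        decisions = {s: ATTRIBUTED_A for s in learning[:9]}
        decisions[learning[9]] = UNATTRIBUTED
        tm = self._matrix(decisions, truth)
        ok, covered = continuation_check([tm], learning, truth)
        assert ok and sum(covered.values()) == 9

    def test_insufficient_coverage_fails(self):
        from emts2pca import continuation_check

        learning = [f"s{i}" for i in range(10)]
        truth = {s: True for s in learning}
        decisions = {s: ATTRIBUTED_A for s in learning[:5]}
        decisions.update({s: UNATTRIBUTED for s in learning[5:]})
        tm = self._matrix(decisions, truth)
        ok, _ = continuation_check([tm], learning, truth)
        assert not ok
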