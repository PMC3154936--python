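import numpy as np
import pytest

from emts2pca import (
    build_validation_space,
    classify_testing,
    reclassify_with_subset,
    select_axis_subset,
)
from emts2pca.data_model import ATTRIBUTED_A, ATTRIBUTED_B, UNATTRIBUTED
from emts2pca.prediction import ValidationSpace, variance_decomposition
from emts2pca.signature import StandardizedMatrix


def _std_matrix(rng, n_genes=12, n_learning=8, n_testing=4, effect=2.0):
    """Standardized-matrix stand-in with a planted two-group structure."""
    learning = [f"l{i}" for i in range(n_learning)]
    testing = [f"t{i}" for i in range(n_testing)]
    half = n_learning // 2
    values = rng.normal(0, 0.2, size=(n_genes, n_learning + n_testing))
    sign = np.array([1.0] * half + [-1.0] * (n_learning - half)
                    + [1.0] * (n_testing // 2) + [-1.0] * (n_testing - n_testing // 2))
    values += np.outer(np.resize([1.0, -1.0], n_genes), sign) * effect
    std = StandardizedMatrix(
        gene_ids=[f"g{i}" for i in range(n_genes)],
        sample_ids=learning + testing,
        learning_ids=learning,
        values=values,
        provenance=np.ones(n_genes, dtype=int),
    )
    is_a = {s: i < half for i, s in enumerate(learning)}
    return std, is_a, testing


class TestBuildValidationSpace:
    def test_learning_groups_separate_on_leading_axis(self, rng):
        std, is_a, _ = _std_matrix(rng)
        space = build_validation_space(std, is_a)
        coords = space.learning_coords[:, 0]
        a = coords[space.learning_is_a]
        b = coords[~space.learning_is_a]
        pooled_sd = np.sqrt((a.var() + b.var()) / 2)
        assert abs(a.mean() - b.mean()) > 4 * pooled_sd

    def test_learning_coordinates_independent_of_testing_projection(self, rng):
        std, is_a, _ = _std_matrix(rng)
        space_full = build_validation_space(std, is_a)
        # restrict ξ to learning columns only and rebuild
        restricted = StandardizedMatrix(
            gene_ids=std.gene_ids,
            sample_ids=std.learning_ids,
            learning_ids=std.learning_ids,
            values=std.values[:, : len(std.learning_ids)],
            provenance=std.provenance,
        )
        space_learn = build_validation_space(restricted, is_a)
        np.testing.assert_allclose(
            space_full.learning_coords, space_learn.learning_coords, atol=1e-10
        )

    def test_degenerate_xi_prime_errors(self, rng):
        std, is_a, _ = _std_matrix(rng)
        std.values[:] = 1.0
        from emts2pca.data_model import DataError

        with pytest.raises(DataError):
            build_validation_space(std, is_a)


class TestClassifyTesting:
    def test_testing_samples_attributed_to_their_group(self, rng):
        std, is_a, testing = _std_matrix(rng)
        space = build_validation_space(std, is_a)
        decisions = [classify_testing(space, t).decision for t in testing]
        assert decisions == [ATTRIBUTED_A, ATTRIBUTED_A, ATTRIBUTED_B, ATTRIBUTED_B]

    def test_case_by_case_equals_batch(self, rng):
        # learning geometry is fixed: order of classification cannot matter
        std, is_a, testing = _std_matrix(rng)
        space = build_validation_space(std, is_a)
        one_by_one = [classify_testing(space, t).decision for t in testing]
        shuffled = [classify_testing(space, t).decision for t in reversed(testing)]
        assert one_by_one == list(reversed(shuffled))

    def test_group_relabel_swaps_decision(self, rng):
        std, is_a, testing = _std_matrix(rng)
        space = build_validation_space(std, is_a)
        swapped = build_validation_space(std, {s: not v for s, v in is_a.items()})
        for t in testing:
            d1 = classify_testing(space, t).decision
            d2 = classify_testing(swapped, t).decision
            assert {d1, d2} in ({ATTRIBUTED_A, ATTRIBUTED_B},)

    def test_symmetric_midpoint_unattributed(self):
        # two mirror groups; a query exactly at the origin
        learning = [f"l{i}" for i in range(6)]
        coords = np.array(
            [[-5, 0.3], [-5.5, -0.2], [-4.5, 0.0], [5, 0.3], [5.5, -0.2], [4.5, 0.0],
             [0.0, 0.0]]
        )
        space = ValidationSpace(
            sample_ids=learning + ["q"],
            learning_ids=learning,
            learning_is_a=np.array([True] * 3 + [False] * 3),
            psi=coords,
            eigenvalues=np.array([1.0, 0.5]),
            groups=("A", "B"),
        )
        assert classify_testing(space, "q", axes=[0, 1]).decision == UNATTRIBUTED


class TestVarianceDecomposition:
    def test_identity_on_random_coordinates(self, rng):
        for _ in range(20):
            coords = rng.normal(size=(12, 5))
            is_a = rng.random(12) < 0.5
            if is_a.all() or not is_a.any():
                continue
            v_inter, v_within, v_total = variance_decomposition(
                coords, is_a, list(range(5))
            )
            assert v_inter + v_within == pytest.approx(v_total, abs=1e-9)


def _toy_space(coords, is_a, n_learning):
    ids = [f"l{i}" for i in range(n_learning)] + [
        f"t{i}" for i in range(coords.shape[0] - n_learning)
    ]
    return ValidationSpace(
        sample_ids=ids,
        learning_ids=ids[:n_learning],
        learning_is_a=np.asarray(is_a),
        psi=coords,
        eigenvalues=np.ones(coords.shape[1]),
        groups=("A", "B"),
    )


class TestSelectAxisSubset:
    def test_separating_axis_wins_over_noise_axis(self, rng):
        sep = np.array([-3.0, -3.1, -2.9, 3.0, 3.1, 2.9])
        noise = rng.normal(0, 3, size=6)
        coords = np.column_stack([sep, noise])
        space = _toy_space(coords, [True] * 3 + [False] * 3, 6)
        best = select_axis_subset(space, max_axes=2)
        assert best.axes == (0,)
        # oracle: direct arithmetic for the chosen subset
        v_inter, v_within, _ = variance_decomposition(
            coords[:6], space.learning_is_a, [0]
        )
        assert best.ratio == pytest.approx(v_inter / v_within)

    def test_tie_broken_toward_fewer_axes(self):
        sep = np.array([-3.0, -3.0, -3.0, 3.0, 3.0, 3.0])
        coords = np.column_stack([sep, sep])  # identical structure on both axes
        space = _toy_space(coords, [True] * 3 + [False] * 3, 6)
        best = select_axis_subset(space, max_axes=2)
        assert best.axes == (0,)

    def test_best_subset_at_least_as_good_as_top_three(self, rng):
        coords = rng.normal(size=(10, 6))
        coords[:5, 0] -= 4
        coords[5:, 0] += 4
        space = _toy_space(coords, [True] * 5 + [False] * 5, 10)
        best = select_axis_subset(space, max_axes=6)
        v_inter, v_within, _ = variance_decomposition(
            coords, space.learning_is_a, [0, 1, 2]
        )
        assert best.ratio >= v_inter / v_within - 1e-12


class TestReclassifyWithSubset:
    def test_outlier_recovered_on_selected_subset(self):
        # separable on axis 0; axis 1 pure noise pushes the query outside
        # every RMS range when both axes are used
        base0 = np.array([-3.0, -3.2, -2.8, 3.0, 3.2, 2.8])
        base1 = np.array([0.1, -0.1, 0.0, 0.1, -0.1, 0.0])
        coords = np.column_stack([base0, base1])
        query = np.array([[-3.0, 9.0]])  # clearly group A on axis 0
        space = _toy_space(np.vstack([coords, query]), [True] * 3 + [False] * 3, 6)
        assert classify_testing(space, "t0", axes=[0, 1]).decision == UNATTRIBUTED
        subset = select_axis_subset(space, max_axes=2)
        redo = reclassify_with_subset(space, subset, ["t0"])
        assert redo["t0"].decision == ATTRIBUTED_A

    def test_attributed_samples_unchanged_in_strong_signal(self, rng):
        std, is_a, testing = _std_matrix(rng, n_genes=20, n_testing=8)
        space = build_validation_space(std, is_a)
        before = {t: classify_testing(space, t).decision for t in testing}
        subset = select_axis_subset(space, max_axes=min(5, space.n_axes))
        after = {
            t: classify_testing(space, t, axes=list(subset.axes)).decision
            for t in testing
        }
        changed = [t for t in testing if before[t] != after[t]
                   and before[t] != UNATTRIBUTED]
        assert len(changed) <= 1

    def test_empty_unattributed_list_is_noop(self, rng):
        std, is_a, _ = _std_matrix(rng)
        space = build_validation_space(std, is_a)
        subset = select_axis_subset(space, max_axes=2)
        assert reclassify_with_subset(space, subset, []) == {}
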