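import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ksrv import (
    OmicsDataset,
    ValidationError,
    compute_weights,
    find_neighbors,
    impute_layers,
    transfer_labels,
)
from ksrv.imputation import NeighborAssignment


def _assignment(distances, indices=None):
    d = np.atleast_2d(np.asarray(distances, dtype=float))
    if indices is None:
        indices = np.tile(np.arange(d.shape[1]), (d.shape[0], 1))
    return NeighborAssignment(
        neighbor_indices=np.asarray(indices), cosine_distances=d
    )


class TestFindNeighbors:
    def test_exact_match_is_nearest_at_distance_zero(self, rng):
        refs = rng.normal(size=(8, 4))
        spots = refs[[3]]
        a = find_neighbors(spots, refs, k=1)
        assert a.neighbor_indices[0, 0] == 3
        assert a.cosine_distances[0, 0] < 1e-12

    def test_k_equal_to_refs_selects_all_sorted(self, rng):
        refs = rng.normal(size=(6, 3))
        spots = rng.normal(size=(2, 3))
        a = find_neighbors(spots, refs, k=6)
        assert sorted(a.neighbor_indices[0]) == list(range(6))
        assert np.all(np.diff(a.cosine_distances, axis=1) >= -1e-15)

    def test_matches_brute_force_sort(self, rng):
        refs = rng.normal(size=(10, 5))
        spots = rng.normal(size=(4, 5))
        a = find_neighbors(spots, refs, k=3)
        rn = refs / np.linalg.norm(refs, axis=1, keepdims=True)
        sn = spots / np.linalg.norm(spots, axis=1, keepdims=True)
        for i in range(4):
            d = 1 - sn[i] @ rn.T
            oracle = np.argsort(d, kind="stable")[:3]
            assert set(a.neighbor_indices[i]) == set(oracle)

    def test_zero_norm_spot_gets_unit_distances(self, rng):
        refs = rng.normal(size=(5, 3))
        with pytest.warns(UserWarning, match="zero-norm"):
            a = find_neighbors(np.zeros((1, 3)), refs, k=2)
        np.testing.assert_allclose(a.cosine_distances, 1.0)

    def test_k_clamped_to_reference_size(self, rng):
        refs = rng.normal(size=(4, 3))
        with pytest.warns(UserWarning, match="clamped"):
            a = find_neighbors(rng.normal(size=(1, 3)), refs, k=9)
        assert a.k == 4


class TestWeights:
    def test_symmetric_distances_share_weight(self):
        w = compute_weights(_assignment([[0.5, 0.5]])).weights
        np.testing.assert_allclose(w, [[0.5, 0.5]])

    def test_hand_evaluated_three_neighbor_case(self):
        # d = (0, 1, 1): a = (1, 0.5, 0.5); a* = a/2 = (0.5, 0.25, 0.25)
        w = compute_weights(_assignment([[0.0, 1.0, 1.0]])).weights
        np.testing.assert_allclose(w, [[0.5, 0.25, 0.25]])

    def test_all_zero_distances_take_uniform_weights(self):
        w = compute_weights(_assignment([[0.0, 0.0, 0.0, 0.0]])).weights
        np.testing.assert_allclose(w, 0.25)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        k=st.integers(2, 50),
        seed=st.integers(0, 10_000),
    )
    def test_weight_rows_sum_to_one_and_stay_in_unit_interval(self, k, seed):
        d = np.random.default_rng(seed).uniform(0, 2, size=(5, k))
        w = compute_weights(_assignment(d)).weights
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(w >= 0) and np.all(w <= 1)


def _ref_with_layers(S, U, labels=None):
    n, g = S.shape
    return OmicsDataset(
        matrix=S + U,
        gene_ids=[f"g{i}" for i in range(g)],
        obs_ids=[f"c{i}" for i in range(n)],
        spliced=S,
        unspliced=U,
        labels=labels,
    )


class TestImputeLayers:
    def test_one_hot_weights_copy_the_neighbor_row(self, rng):
        S = rng.uniform(size=(5, 3))
        U = rng.uniform(size=(5, 3))
        ref = _ref_with_layers(S, U)
        a = _assignment([[0.0, 1.0]], indices=[[2, 4]])
        a = NeighborAssignment(a.neighbor_indices, a.cosine_distances,
                               weights=np.array([[1.0, 0.0]]))
        S_pred, U_pred = impute_layers(a, ref)
        np.testing.assert_allclose(S_pred[0], S[2])
        np.testing.assert_allclose(U_pred[0], U[2])

    def test_identical_neighbors_average_to_their_value(self, rng):
        e = rng.uniform(size=3)
        S = np.tile(e, (4, 1))
        ref = _ref_with_layers(S, S * 2)
        a = compute_weights(_assignment([[0.1, 0.4, 0.2, 0.9]]))
        S_pred, U_pred = impute_layers(a, ref)
        np.testing.assert_allclose(S_pred[0], e, atol=1e-12)
        np.testing.assert_allclose(U_pred[0], 2 * e, atol=1e-12)

    def test_matches_explicit_weighted_sum_loop(self, rng):
        S = rng.uniform(size=(6, 4))
        U = rng.uniform(size=(6, 4))
        ref = _ref_with_layers(S, U)
        a = compute_weights(
            _assignment([[0.2, 0.5, 0.1, 0.7]], indices=[[5, 0, 3, 1]])
        )
        S_pred, _ = impute_layers(a, ref)
        oracle = sum(
            a.weights[0, j] * S[a.neighbor_indices[0, j]] for j in range(4)
        )
        assert np.max(np.abs(S_pred[0] - oracle)) < 1e-12

    def test_convexity_of_imputed_values(self, rng):
        S = rng.uniform(size=(10, 5))
        ref = _ref_with_layers(S, S)
        idx = np.array([rng.choice(10, 4, replace=False) for _ in range(3)])
        a = compute_weights(_assignment(rng.uniform(0.1, 1, (3, 4)), indices=idx))
        S_pred, _ = impute_layers(a, ref)
        for i in range(3):
            nbr = S[a.neighbor_indices[i]]
            assert np.all(S_pred[i] >= nbr.min(axis=0) - 1e-12)
            assert np.all(S_pred[i] <= nbr.max(axis=0) + 1e-12)

    def test_missing_layer_is_named(self, rng):
        ds = OmicsDataset(rng.uniform(size=(4, 3)),
                          ["a", "b", "c"], ["1", "2", "3", "4"])
        with pytest.raises(ValidationError, match="spliced"):
            impute_layers(compute_weights(_assignment([[0.1, 0.2]])), ds)

    def test_self_recovery_with_single_neighbor(self, rng):
        S = rng.uniform(size=(8, 5))
        U = rng.uniform(size=(8, 5))
        ref = _ref_with_layers(S, U)
        scores = rng.normal(size=(8, 3))
        a = compute_weights(find_neighbors(scores, scores, k=1))
        S_pred, U_pred = impute_layers(a, ref)
        np.testing.assert_allclose(S_pred, S)
        np.testing.assert_allclose(U_pred, U)


class TestLabelTransfer:
    def test_unanimous_neighborhood(self):
        a = compute_weights(_assignment([[0.1, 0.2, 0.3]]))
        res = transfer_labels(a, np.array(["T", "T", "T"], dtype=object))
        np.testing.assert_allclose(res.scores, [[1.0]])
        assert res.assigned[0] == "T"

    def test_hand_summed_scores(self):
        a = NeighborAssignment(
            neighbor_indices=np.array([[0, 1, 2]]),
            cosine_distances=np.zeros((1, 3)),
            weights=np.array([[0.5, 0.3, 0.2]]),
        )
        res = transfer_labels(a, np.array(["A", "B", "A"], dtype=object))
        np.testing.assert_allclose(res.scores, [[0.7, 0.3]])
        assert res.assigned[0] == "A"

    def test_exact_tie_resolves_lexicographically(self):
        a = NeighborAssignment(
            neighbor_indices=np.array([[0, 1]]),
            cosine_distances=np.zeros((1, 2)),
            weights=np.array([[0.5, 0.5]]),
        )
        res = transfer_labels(a, np.array(["B", "A"], dtype=object))
        assert res.assigned[0] == "A"

    def test_scores_partition_the_weights(self, rng):
        a = compute_weights(_assignment(rng.uniform(0.1, 1.0, (6, 7))))
        labels = rng.choice(np.array(["x", "y", "z"], dtype=object), 7)
        res = transfer_labels(a, labels)
        np.testing.assert_allclose(res.scores.sum(axis=1), 1.0, atol=1e-12)

    def test_leave_one_out_accuracy_on_separated_clusters(self, rng):
        # 3 angular clusters separated by >= 5 within-cluster sd; neighbor
        # search is cosine-based, so separation must be directional
        centers = np.array([[10, 0], [0, 10], [-8, -8.0]])
        pts = np.vstack([rng.normal(c, 1.0, size=(30, 2)) for c in centers])
        labels = np.repeat(np.array(["a", "b", "c"], dtype=object), 30)
        correct = 0
        a = find_neighbors(pts, pts, k=6)
        # drop each point's self-match, keep 5 true neighbors
        trimmed = NeighborAssignment(
            neighbor_indices=a.neighbor_indices[:, 1:],
            cosine_distances=a.cosine_distances[:, 1:],
        )
        res = transfer_labels(compute_weights(trimmed), labels)
        correct = np.mean(res.assigned == labels)
        assert correct > 0.95
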