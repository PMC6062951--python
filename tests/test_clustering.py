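"""Single linkage, leaf positions, KS scoring, consistency selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from redeval import (
    best_model,
    ks_score,
    leaf_positions,
    prefilter_reductions,
    score_all,
    single_linkage,
)
from redeval.clustering import LinkageTree
from redeval.metrics import DissimilarityMatrix


def dmat(values, masks=None):
    n = len(values)
    masks = masks or ["0"] * n
    labels = tuple((i, m) for i, m in enumerate(masks))
    return DissimilarityMatrix(labels, np.asarray(values, dtype=float))


def brute_force_single_linkage_heights(V):
    """O(N^3) agglomeration by direct minimum search; independent of the
    library implementation."""
    clusters = [{i} for i in range(len(V))]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = min(V[i, j] for i in clusters[a] for j in clusters[b])
                if d < best[0]:
                    best = (d, (a, b))
        d, (a, b) = best
        heights.append(d)
        clusters[a] |= clusters[b]
        del clusters[b]
    return heights


class TestSingleLinkage:
    def test_three_point_hand_case(self):
        D = dmat([[0, 0.1, 0.5], [0.1, 0, 0.4], [0.5, 0.4, 0]])
        tree = single_linkage(D)
        np.testing.assert_allclose(tree.merges[:, 2], [0.1, 0.4])
        assert set(tree.merges[0, :2]) == {0, 1}

    def test_two_points(self):
        tree = single_linkage(dmat([[0, 0.3], [0.3, 0]]))
        assert tree.merges.shape == (1, 4)
        assert tree.merges[0, 2] == pytest.approx(0.3)

    @pytest.mark.parametrize("n,seed", [(5, 0), (12, 1), (25, 2), (50, 3)])
    def test_heights_match_brute_force(self, n, seed):
        rng = np.random.default_rng(seed)
        V = rng.uniform(0.1, 1.0, (n, n))
        V = (V + V.T) / 2
        np.fill_diagonal(V, 0)
        tree = single_linkage(dmat(V))
        np.testing.assert_allclose(sorted(tree.merges[:, 2]),
                                   sorted(brute_force_single_linkage_heights(V)),
                                   rtol=1e-12)
        assert np.all(np.diff(tree.merges[:, 2]) >= 0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            single_linkage(dmat([[0, np.inf], [np.inf, 0]]))


class TestLeafPositions:
    def test_positions_are_permutation(self):
        rng = np.random.default_rng(4)
        V = rng.uniform(0.1, 1, (9, 9))
        V = (V + V.T) / 2
        np.fill_diagonal(V, 0)
        pos = leaf_positions(single_linkage(dmat(V)))
        assert sorted(pos) == list(range(1, 10))

    def test_two_block_matrix_gives_contiguous_blocks(self):
        """Within-block distances all below every between-block distance:
        each block must occupy a contiguous position range."""
        n = 6
        V = np.full((n, n), 0.9)
        for blk in ([0, 1, 2], [3, 4, 5]):
            for i in blk:
                for j in blk:
                    V[i, j] = 0.1 if i != j else 0.0
        pos = leaf_positions(single_linkage(dmat(V)))
        a, b = sorted(pos[:3]), sorted(pos[3:])
        assert a == list(range(a[0], a[0] + 3))
        assert b == list(range(b[0], b[0] + 3))

    def test_single_leaf(self):
        assert leaf_positions(LinkageTree(np.empty((0, 4)), 1)).tolist() == [1]


class TestKsScore:
    def test_identical_samples_score_zero(self):
        a = np.array([1, 5, 9, 12])
        assert ks_score(a, a) == 0.0

    def test_disjoint_ranges_score_one(self):
        assert ks_score(np.arange(1, 11), np.arange(20, 30)) == 1.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 400), min_size=1, max_size=60),
           st.lists(st.integers(1, 400), min_size=1, max_size=60))
    def test_matches_ecdf_oracle(self, a, b):
        """Direct ECDF sup-difference evaluated on the pooled grid."""
        a, b = np.array(a, float), np.array(b, float)
        grid = np.union1d(a, b)
        ecdf = lambda s: np.searchsorted(np.sort(s), grid, side="right") / len(s)
        oracle = np.max(np.abs(ecdf(a) - ecdf(b)))
        assert ks_score(a, b) == pytest.approx(oracle, abs=1e-12)
        assert ks_score(b, a) == ks_score(a, b)

    def test_invariant_under_monotone_relabelling(self):
        rng = np.random.default_rng(5)
        a = rng.integers(1, 100, 30).astype(float)
        b = rng.integers(1, 100, 30).astype(float)
        f = lambda x: np.exp(x / 10)  # strictly increasing
        assert ks_score(f(a), f(b)) == pytest.approx(ks_score(a, b))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_score(np.array([]), np.array([1.0]))


def two_block_matrix(masks_left, masks_right, gap=0.9):
    """Models in the left block are mutually close, right block likewise,
    blocks separated by ``gap``."""
    masks = masks_left + masks_right
    n = len(masks)
    rng = np.random.default_rng(0)
    V = np.full((n, n), gap) + rng.uniform(0, 0.01, (n, n))
    nl = len(masks_left)
    for blk in (range(nl), range(nl, n)):
        for i in blk:
            for j in blk:
                V[i, j] = 0.1 + 0.01 * abs(i - j)
    V = (V + V.T) / 2
    np.fill_diagonal(V, 0)
    return dmat(V, masks)


class TestScoreAll:
    def test_separated_reduction_scores_one(self):
        D = two_block_matrix(["0"] * 6, ["1"] * 6)
        table = score_all(single_linkage(D), D.labels, alpha=0.2)
        row = table.set_index("bitmask")
        assert row.loc["1", "score"] == 1.0
        assert not row.loc["1", "consistent"]
        assert row.loc["0", "score"] == 0.0
        assert best_model(table) == "0"

    def test_interleaved_reduction_is_consistent_and_best(self):
        # six tight ("0", "1") pairs, pairs far apart: the reduced models
        # interleave with the full models leaf-by-leaf
        masks = ["0", "1"] * 6
        n = len(masks)
        rng = np.random.default_rng(1)
        V = 0.1 + rng.uniform(0, 0.05, (n, n))
        for i in range(0, n, 2):
            V[i, i + 1] = V[i + 1, i] = 0.001 * (1 + i)
        V = (V + V.T) / 2
        np.fill_diagonal(V, 0)
        D = dmat(V, masks)
        table = score_all(single_linkage(D), D.labels, alpha=0.5)
        row = table.set_index("bitmask")
        assert row.loc["1", "score"] < 0.5
        assert row.loc["1", "best"]

    def test_consistency_monotone_in_alpha(self):
        D = two_block_matrix(["00"] * 4 + ["11"] * 4, ["10"] * 4 + ["01"] * 4)
        tree = single_linkage(D)
        sets = []
        for alpha in (0.05, 0.2, 0.6, 1.01):
            t = score_all(tree, D.labels, alpha)
            sets.append(set(t[t["consistent"]]["bitmask"]))
        for small, large in zip(sets, sets[1:]):
            assert small <= large

    def test_missing_full_model_rejected(self):
        D = two_block_matrix(["1"] * 3, ["1"] * 3)
        with pytest.raises(ValueError):
            score_all(single_linkage(D), D.labels)

    def test_deterministic_best_marker(self):
        D = two_block_matrix(["00", "00", "11", "11"], ["10", "10", "01", "01"])
        tree = single_linkage(D)
        a = score_all(tree, D.labels)
        b = score_all(tree, D.labels)
        pd.testing.assert_frame_equal(a, b)
        assert a["best"].sum() <= 1


class TestPrefilter:
    @pytest.fixture()
    def table(self):
        return pd.DataFrame({
            "bitmask": ["00", "01", "10", "11"],
            "size": [0, 1, 1, 2],
            "score": [0.0, 0.17, 1.00, 1.00],
            "consistent": [True, True, False, False],
        })

    def test_half_threshold(self, table):
        assert prefilter_reductions(table, 0.5) == ["00", "01"]

    def test_zero_keeps_only_full(self, table):
        assert prefilter_reductions(table, 0.0) == ["00"]

    def test_above_one_keeps_all(self, table):
        assert prefilter_reductions(table, 1.1) == ["00", "01", "10", "11"]
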