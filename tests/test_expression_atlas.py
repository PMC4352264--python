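import itertools

import numpy as np
import pandas as pd
import pytest

from famkit.core_io import ExpressionMatrix
from famkit.expression_atlas import (
    hcluster,
    normalize_log2,
    pair_expression_similarity,
)
from famkit.synthetic_data import gen_expression_blocks, gen_expression_pairs


def matrix_of(rows, genes=None):
    rows = np.atleast_2d(np.asarray(rows, float))
    genes = genes or [f"g{x}" for x in range(rows.shape[0])]
    samples = [f"s{x}" for x in range(rows.shape[1])]
    return ExpressionMatrix(genes, samples, rows)


class TestNormalize:
    def test_constant_row_is_zero(self):
        out = normalize_log2(matrix_of([[5, 5, 5]]))
        assert np.allclose(out.to_numpy(), 0.0)

    def test_dyadic_example(self):
        out = normalize_log2(matrix_of([[0, 1, 3]]), pseudocount=1)
        assert out.to_numpy().tolist() == [[-1.0, 0.0, 1.0]]

    def test_rows_center_to_zero(self):
        rng = np.random.default_rng(1)
        out = normalize_log2(matrix_of(rng.uniform(0, 100, (10, 7))))
        assert np.abs(out.to_numpy().sum(axis=1)).max() < 1e-9

    def test_uniform_scaling_invariance(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(1, 50, (4, 6))
        a = normalize_log2(matrix_of(base), pseudocount=0)
        b = normalize_log2(matrix_of(2.0 * base), pseudocount=0)
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ExpressionMatrix(["g"], ["s1", "s2"], np.array([[-1.0, 1.0]]))


def brute_force_average_linkage(points):
    """Independent agglomerative oracle: recompute all cluster distances
    (euclidean, average linkage) from scratch at every step."""
    clusters = {i: [i] for i in range(len(points))}
    heights = []
    next_id = len(points)
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean([
                np.linalg.norm(points[x] - points[y])
                for x in clusters[a] for y in clusters[b]
            ])
            if best is None or d < best[0] - 1e-12:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return heights


class TestHCluster:
    def test_identical_rows_merge_first(self):
        m = matrix_of([[1, 2, 3], [9, 1, 4], [1, 2, 3], [5, 5, 5]])
        axis = hcluster(normalize_log2(m))
        assert axis.linkage[0, 2] == pytest.approx(0.0)
        merged = {int(axis.linkage[0, 0]), int(axis.linkage[0, 1])}
        assert merged == {0, 2}

    def test_merge_heights_match_bruteforce_oracle(self):
        rng = np.random.default_rng(8)
        data = rng.normal(size=(12, 5))
        df = pd.DataFrame(data, index=[f"g{x}" for x in range(12)],
                          columns=[f"s{x}" for x in range(5)])
        axis = hcluster(df)
        expected = brute_force_average_linkage(list(data))
        assert np.allclose(sorted(axis.linkage[:, 2]), sorted(expected))

    def test_row_order_invariance(self):
        m, _ = gen_expression_blocks(seed=5)
        t = normalize_log2(m)
        ref = hcluster(t)
        shuffled = t.iloc[::-1]
        other = hcluster(shuffled)
        # same merge heights and same partition at every height
        assert np.allclose(np.sort(ref.linkage[:, 2]), np.sort(other.linkage[:, 2]))
        assert set(map(frozenset, _cut_groups(ref))) == set(
            map(frozenset, _cut_groups(other)))

    def test_blocks_cluster_together(self):
        m, truth = gen_expression_blocks(n_blocks=3, genes_per_block=4, seed=2)
        axis = hcluster(normalize_log2(m))
        order = [truth.set_index("gene").loc[g, "block"] for g in axis.leaf_order]
        # leaf order visits each block contiguously
        changes = sum(1 for a, b in zip(order, order[1:]) if a != b)
        assert changes == 2

    def test_single_item_rejected(self):
        with pytest.raises(ValueError):
            hcluster(normalize_log2(matrix_of([[1, 2, 3]])))


def _cut_groups(axis, k=3):
    from scipy.cluster.hierarchy import fcluster

    flat = fcluster(axis.linkage, k, criterion="maxclust")
    groups = {}
    for label, cluster in zip(axis.labels, flat):
        groups.setdefault(cluster, []).append(label)
    return groups.values()


class TestPairSimilarity:
    def test_identical_and_opposite_rows(self):
        t = pd.DataFrame([[1.0, -1.0, 0.0], [1.0, -1.0, 0.0], [-1.0, 1.0, 0.0]],
                         index=["a", "b", "c"], columns=["s1", "s2", "s3"])
        sims, _ = pair_expression_similarity(t, [("a", "b"), ("a", "c")])
        assert sims[0].correlation == pytest.approx(1.0)
        assert sims[0].similar
        assert sims[1].correlation == pytest.approx(-1.0)
        assert not sims[1].similar

    def test_missing_gene_named(self):
        t = pd.DataFrame([[1.0, 2.0]], index=["a"], columns=["s1", "s2"])
        with pytest.raises(KeyError, match="nope"):
            pair_expression_similarity(t, [("a", "nope")])

    def test_simulation_recovery(self):
        m_hi, pairs_hi = gen_expression_pairs(50, 0.95, n_samples=21, seed=11)
        m_lo, pairs_lo = gen_expression_pairs(50, 0.0, n_samples=21, seed=12)
        sims_hi, _ = pair_expression_similarity(normalize_log2(m_hi), pairs_hi)
        sims_lo, _ = pair_expression_similarity(normalize_log2(m_lo), pairs_lo)
        assert abs(np.mean([s.correlation for s in sims_hi]) - 0.95) < 0.1
        assert abs(np.mean([s.correlation for s in sims_lo]) - 0.0) < 0.1
        accuracy = (np.mean([s.similar for s in sims_hi])
                    + np.mean([not s.similar for s in sims_lo])) / 2
        assert accuracy >= 0.9

    def test_summary_by_selection_class(self):
        t = pd.DataFrame(np.eye(4), index=list("abcd"),
                         columns=["s1", "s2", "s3", "s4"])
        t.loc["b"] = t.loc["a"]
        sims, summary = pair_expression_similarity(
            t, [("a", "b"), ("c", "d")],
            selection={("a", "b"): "purifying", ("c", "d"): "diversifying"})
        frac = summary.set_index("selection")["fraction_similar"]
        assert frac["purifying"] == 1.0
        assert frac["diversifying"] == 0.0
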