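import io

import dendropy
import numpy as np
import pytest

from famkit.phylogeny import (
    DistanceMatrix,
    TreeParams,
    bootstrap_support,
    extract_clades,
    neighbor_joining,
    p_distance,
)
from famkit.synthetic_data import (
    gen_clade_alignment,
    gen_random_tree,
    gen_supported_tree,
    tree_path_distances,
)


class TestPDistance:
    def test_identity(self):
        dm = p_distance({"a": "AAAA", "b": "AAAA"})
        assert dm.get("a", "b") == 0.0

    def test_quarter(self):
        dm = p_distance({"a": "AAAA", "b": "AAAT"})
        assert dm.get("a", "b") == 0.25

    def test_pairwise_deletion_sites(self):
        dm = p_distance({"a": "A-CD", "b": "ABCD"}, "pairwise_deletion")
        assert dm.get("a", "b") == 0.0

    def test_complete_deletion_drops_column_for_all(self):
        aln = {"a": "A-CD", "b": "ABCD", "c": "ABCE"}
        dm = p_distance(aln, "complete_deletion")
        # column 2 dropped for everyone: b vs c differ at 1 of 3 sites
        assert dm.get("b", "c") == pytest.approx(1 / 3)

    def test_no_comparable_sites(self):
        with pytest.raises(ValueError, match="comparable"):
            p_distance({"a": "A--", "b": "-BB"})


class TestNeighborJoining:
    def test_three_taxa_three_point_formulas(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float))
        tree = neighbor_joining(dm)
        lengths = {n.name: n.length for n in tree.root.children}
        assert lengths == pytest.approx({"A": 0.5, "B": 1.5, "C": 2.5})

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["A", "B"], np.zeros((2, 2))))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_additivity_recovery(self, seed):
        true_tree = gen_random_tree(6 + seed, seed=seed)
        dm = tree_path_distances(true_tree)
        nj = neighbor_joining(dm)
        assert set(nj.bipartitions()) == set(true_tree.bipartitions())
        back = tree_path_distances(nj)
        idx = [back.taxa.index(t) for t in dm.taxa]
        assert np.abs(dm.d - back.d[np.ix_(idx, idx)]).max() < 1e-9

    def test_equal_distances_zero_internal_branches(self):
        n = 6
        d = np.full((n, n), 2.0)
        np.fill_diagonal(d, 0.0)
        tree = neighbor_joining(DistanceMatrix([f"t{x}" for x in range(n)], d))
        internal = [node for node in tree.root.walk()
                    if not node.is_leaf() and node is not tree.root]
        assert all(abs(node.length) < 1e-12 for node in internal)

    def test_tree_length_invariant_under_taxon_permutation(self):
        base = gen_random_tree(8, seed=5)
        dm = tree_path_distances(base)
        ref_len = neighbor_joining(dm).total_branch_length()
        rng = np.random.default_rng(0)
        for _ in range(5):
            perm = rng.permutation(len(dm.taxa))
            dm2 = DistanceMatrix([dm.taxa[p] for p in perm],
                                 dm.d[np.ix_(perm, perm)])
            assert neighbor_joining(dm2).total_branch_length() == pytest.approx(
                ref_len, abs=1e-9)

    def test_agrees_with_dendropy_on_noisy_matrix(self):
        # independent NJ implementation as cross-check, non-additive input
        rng = np.random.default_rng(42)
        dm = tree_path_distances(gen_random_tree(7, seed=3))
        noisy = dm.d + rng.uniform(0, 0.05, dm.d.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0.0)
        ours = neighbor_joining(DistanceMatrix(dm.taxa, noisy))
        csv = "," + ",".join(dm.taxa) + "\n" + "\n".join(
            t + "," + ",".join(repr(float(x)) for x in noisy[i])
            for i, t in enumerate(dm.taxa))
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(io.StringIO(csv), delimiter=",")
        theirs = pdm.nj_tree()
        assert ours.total_branch_length() == pytest.approx(theirs.length(), abs=1e-9)


class TestBootstrap:
    def test_uniform_signal_gives_full_support(self):
        # two groups differing at every site: resampling cannot break the split
        aln = {"a1": "AAAAAAAA", "a2": "AAAAAAAA",
               "b1": "TTTTTTTT", "b2": "TTTTTTTT",
               "b3": "TTTTTTTT", "a3": "AAAAAAAA"}
        tree = bootstrap_support(aln, TreeParams(bootstrap_replicates=50, rng_seed=1))
        supports = [n.support for n in tree.root.walk() if n.support is not None]
        assert supports and all(s == 100.0 for s in supports)

    def test_seed_determinism(self):
        aln, _ = gen_clade_alignment([3, 3], n_sites=120, seed=9)
        runs = [bootstrap_support(aln, TreeParams(bootstrap_replicates=60, rng_seed=7))
                for _ in range(2)]
        sups = [sorted(n.support for n in t.root.walk() if n.support is not None)
                for t in runs]
        assert sups[0] == sups[1]

    def test_reference_topology_independent_of_seed(self):
        aln, _ = gen_clade_alignment([3, 3], n_sites=120, seed=9)
        t1 = bootstrap_support(aln, TreeParams(bootstrap_replicates=20, rng_seed=1))
        t2 = bootstrap_support(aln, TreeParams(bootstrap_replicates=20, rng_seed=999))
        assert set(t1.bipartitions()) == set(t2.bipartitions())

    def test_replicate_count_convergence(self):
        aln, _ = gen_clade_alignment([2, 2, 2], n_sites=150, seed=13,
                                     within_divergence=0.1)
        small = bootstrap_support(aln, TreeParams(bootstrap_replicates=100, rng_seed=3))
        large = bootstrap_support(aln, TreeParams(bootstrap_replicates=1000, rng_seed=4))
        s_small = {k: n.support for k, n in small.bipartitions().items()}
        s_large = {k: n.support for k, n in large.bipartitions().items()}
        assert set(s_small) == set(s_large)
        for split in s_small:
            assert abs(s_small[split] - s_large[split]) <= 10.0


class TestExtractClades:
    def test_single_supported_edge(self):
        tree = gen_supported_tree([["a", "b"]], ["c", "d", "e"], clade_support=90)
        clades, singletons = extract_clades(tree, 50)
        assert len(clades) == 1
        assert clades[0].members == frozenset({"a", "b"})
        assert set(singletons) == {"c", "d", "e"}

    def test_threshold_is_strict(self):
        tree = gen_supported_tree([["a", "b"]], ["c", "d", "e"], clade_support=50)
        clades, singletons = extract_clades(tree, 50)
        assert clades == [] and len(singletons) == 5

    def test_family_scale_layout(self):
        # 21 planted groups covering 94 taxa, 9 singletons
        sizes = [4] * 16 + [6] * 5
        names = [[f"c{g}m{m}" for m in range(s)] for g, s in enumerate(sizes)]
        singles = [f"single{x}" for x in range(9)]
        tree = gen_supported_tree(names, singles, clade_support=95, other_support=30)
        clades, singletons = extract_clades(tree, 50)
        assert len(clades) == 21
        assert sum(len(c.members) for c in clades) == 94
        assert len(singletons) == 9
        assert {frozenset(g) for g in names} == {c.members for c in clades}
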