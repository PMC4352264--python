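"""Distance-based phylogenetics: p-distance, neighbor-joining, bootstrap, clades.

The tree built here is the classical Saitou-Nei neighbor-joining tree on
amino-acid p-distances, with branch support from non-parametric bootstrap
over alignment columns and clade calling at a support threshold (strictly
greater than the threshold).  Negative NJ branch lengths are retained by
default; ``clamp_negative`` zeroes them for presentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "PhyloTree",
    "Clade",
    "TreeParams",
    "p_distance",
    "neighbor_joining",
    "bootstrap_support",
    "extract_clades",
]

GAP_CHARS = {"-", "."}


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if len(set(self.taxa)) != n:
            raise ValueError("duplicate taxa")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite distances")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("nonzero diagonal")
        if np.any(self.d < -1e-12):
            raise ValueError("negative distances")

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.taxa.index(a), self.taxa.index(b)])


@dataclass
class TreeNode:
    """A node of an (unrooted, stored rooted-at-trifurcation) phylogeny."""

    name: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    length: float = 0.0          # branch to the parent
    support: float | None = None  # bootstrap % of the edge to the parent

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves())

    def walk(self) -> Iterable["TreeNode"]:
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class PhyloTree:
    root: TreeNode
    taxa: list[str]

    def total_branch_length(self) -> float:
        return sum(n.length for n in self.root.walk() if n is not self.root)

    def bipartitions(self) -> dict[frozenset[str], TreeNode]:
        """Internal edges as canonical splits.

        Each edge below the root with >= 2 leaves on each side defines a
        split, keyed by the side not containing the first taxon.
        """
        all_taxa = frozenset(self.taxa)
        out: dict[frozenset[str], TreeNode] = {}
        ref = self.taxa[0]
        for node in self.root.walk():
            if node is self.root or node.is_leaf():
                continue
            side = node.leaf_names()
            if len(side) < 2 or len(all_taxa - side) < 2:
                continue
            key = side if ref not in side else all_taxa - side
            out[key] = node
        return out

    def newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf():
                return f"{node.name}:{node.length:.10g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None else f"{node.support:g}"
            return f"({inner}){label}:{node.length:.10g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"


@dataclass(frozen=True)
class Clade:
    members: frozenset[str]
    support: float


@dataclass(frozen=True)
class TreeParams:
    bootstrap_replicates: int = 1000
    support_threshold: float = 50.0
    gap_policy: Literal["pairwise_deletion", "complete_deletion"] = "pairwise_deletion"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.bootstrap_replicates < 1:
            raise ValueError("need >= 1 bootstrap replicate")
        if not 0 <= self.support_threshold <= 100:
            raise ValueError("support threshold must be in [0, 100]")


def _alignment_array(alignment: Mapping[str, str]) -> tuple[list[str], np.ndarray]:
    taxa = list(alignment)
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    arr = np.array([list(alignment[t]) for t in taxa])
    return taxa, arr


def p_distance(alignment: Mapping[str, str],
               gap_policy: str = "pairwise_deletion") -> DistanceMatrix:
    """Proportion of differing sites per pair of aligned sequences.

    ``pairwise_deletion`` compares, for each pair, the sites where neither
    sequence has a gap; ``complete_deletion`` first drops every column in
    which any taxon has a gap.  A pair with no comparable sites is an error.
    """
    taxa, arr = _alignment_array(alignment)
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa")
    gap = np.isin(arr, list(GAP_CHARS))
    if gap_policy == "complete_deletion":
        keep = ~gap.any(axis=0)
        arr, gap = arr[:, keep], gap[:, keep]
    elif gap_policy != "pairwise_deletion":
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    n = len(taxa)
    d = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            ok = ~gap[a] & ~gap[b]
            m = int(ok.sum())
            if m == 0:
                raise ValueError(f"no comparable sites between {taxa[a]!r} and {taxa[b]!r}")
            d[a, b] = d[b, a] = np.count_nonzero(arr[a, ok] != arr[b, ok]) / m
    return DistanceMatrix(taxa, d)


def neighbor_joining(dm: DistanceMatrix, clamp_negative: bool = False) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    At each step the pair minimizing Q(a,b) = (n-2)·d(a,b) − R(a) − R(b) is
    joined (ties broken by smallest (row, column) index for bitwise
    reproducibility); branch lengths come from the standard three-point
    formulas.  The returned tree is unrooted, stored with a trifurcating
    root.
    """
    if len(dm.taxa) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.taxa]
    d = dm.d.copy()
    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        best, best_q = None, np.inf
        for a in range(n):
            for b in range(a + 1, n):
                q = (n - 2) * d[a, b] - r[a] - r[b]
                if q < best_q - 1e-15:
                    best, best_q = (a, b), q
        a, b = best
        la = d[a, b] / 2 + (r[a] - r[b]) / (2 * (n - 2))
        lb = d[a, b] - la
        if clamp_negative:
            la, lb = max(la, 0.0), max(lb, 0.0)
        nodes[a].length, nodes[b].length = la, lb
        parent = TreeNode(children=[nodes[a], nodes[b]])
        new_d = (d[a, :] + d[b, :] - d[a, b]) / 2
        keep = [x for x in range(n) if x not in (a, b)]
        d = np.vstack([d[keep][:, keep], new_d[keep]])
        d = np.hstack([d, np.append(new_d[keep], 0.0)[:, None]])
        nodes = [nodes[x] for x in keep] + [parent]
    # final three-point resolution
    (a, b, c) = (0, 1, 2)
    la = (d[a, b] + d[a, c] - d[b, c]) / 2
    lb = (d[a, b] + d[b, c] - d[a, c]) / 2
    lc = (d[a, c] + d[b, c] - d[a, b]) / 2
    if clamp_negative:
        la, lb, lc = max(la, 0.0), max(lb, 0.0), max(lc, 0.0)
    nodes[a].length, nodes[b].length, nodes[c].length = la, lb, lc
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return PhyloTree(root=root, taxa=list(dm.taxa))


def bootstrap_support(alignment: Mapping[str, str],
                      params: TreeParams = TreeParams()) -> PhyloTree:
    """Reference NJ tree with bootstrap supports on its internal edges.

    Columns are resampled with replacement (seeded); each replicate tree's
    bipartitions are tallied and each reference internal edge receives the
    percentage of replicates containing its split.  The reference topology
    itself does not depend on the seed.
    """
    taxa, arr = _alignment_array(alignment)
    if len(taxa) < 4:
        raise ValueError("bootstrap needs >= 4 taxa")
    ref_tree = neighbor_joining(p_distance(alignment, params.gap_policy))
    ref_splits = ref_tree.bipartitions()
    counts = {split: 0 for split in ref_splits}
    rng = np.random.default_rng(params.rng_seed)
    n_cols = arr.shape[1]
    for _ in range(params.bootstrap_replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep_aln = {t: "".join(arr[x, cols]) for x, t in enumerate(taxa)}
        rep_tree = neighbor_joining(p_distance(rep_aln, params.gap_policy))
        for split in rep_tree.bipartitions():
            if split in counts:
                counts[split] += 1
    for split, node in ref_splits.items():
        node.support = 100.0 * counts[split] / params.bootstrap_replicates
    return ref_tree


def extract_clades(tree: PhyloTree, threshold: float = 50.0) -> tuple[list[Clade], list[str]]:
    """Maximal supported clades and the leftover singleton taxa.

    Every internal edge with support strictly above ``threshold`` defines a
    candidate clade (the smaller side of its bipartition; on a size tie the
    side not containing the first taxon).  Only inclusion-maximal candidates
    are reported; taxa covered by no clade are returned as singletons.
    """
    all_taxa = frozenset(tree.taxa)
    candidates: list[Clade] = []
    for split, node in tree.bipartitions().items():
        if node.support is None or node.support <= threshold:
            continue
        other = all_taxa - split
        members = split if len(split) <= len(other) else other
        candidates.append(Clade(members=members, support=node.support))
    maximal = [
        c for c in candidates
        if not any(c.members < o.members for o in candidates)
    ]
    # deduplicate identical member sets, keep highest support
    seen: dict[frozenset[str], Clade] = {}
    for c in maximal:
        if c.members not in seen or c.support > seen[c.members].support:
            seen[c.members] = c
    clades = sorted(seen.values(), key=lambda c: sorted(c.members)[0])
    covered = frozenset().union(*(c.members for c in clades)) if clades else frozenset()
    singletons = sorted(all_taxa - covered)
    return clades, singletons
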