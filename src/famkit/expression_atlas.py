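"""Expression-atlas processing: log2 normalization, hierarchical clustering,
and expression-pattern similarity within duplicate gene pairs.

The heatmap transform is row-centered log2 signal: each gene's profile
becomes its log2(x + pseudocount) values minus their mean over samples, so a
cell reads as a log2 fold change against the gene's average — the
conventional presentation of organ/tissue expression atlases.  A z-score
variant is available.  Clustering is agglomerative (scipy), euclidean
distance and average linkage by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .core_io import ExpressionMatrix

__all__ = [
    "ClusteredAxis",
    "PairSimilarity",
    "normalize_log2",
    "normalize_zscore",
    "hcluster",
    "pair_expression_similarity",
]


@dataclass
class ClusteredAxis:
    """One axis of a clustered heatmap: linkage matrix plus the leaf order."""

    labels: list[str]
    linkage: np.ndarray
    leaf_order: list[str]


@dataclass(frozen=True)
class PairSimilarity:
    gene_a: str
    gene_b: str
    correlation: float
    similar: bool


def normalize_log2(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """Row-centered log2 transform; constant genes map to all-zero rows."""
    values = matrix.values
    if np.any(values < 0):
        raise ValueError("negative expression values")
    logged = np.log2(values + pseudocount)
    centered = logged - logged.mean(axis=1, keepdims=True)
    return pd.DataFrame(centered, index=matrix.gene_ids, columns=matrix.sample_ids)


def normalize_zscore(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-gene z-score of log2 signal; zero-variance rows stay zero."""
    logged = np.log2(matrix.values + pseudocount)
    centered = logged - logged.mean(axis=1, keepdims=True)
    sd = logged.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame(centered / sd, index=matrix.gene_ids, columns=matrix.sample_ids)


def hcluster(transformed: pd.DataFrame, axis: Literal["genes", "samples"] = "genes",
             metric: str = "euclidean", linkage: str = "average") -> ClusteredAxis:
    """Agglomerative clustering of one axis of a (transformed) matrix.

    Ties in merge distance are resolved deterministically by scipy's
    index-ordered agglomeration, so equal inputs give identical trees.
    """
    data = transformed.to_numpy() if axis == "genes" else transformed.to_numpy().T
    labels = list(transformed.index if axis == "genes" else transformed.columns)
    if len(labels) < 2:
        raise ValueError(f"need at least 2 items on the {axis} axis")
    Z = hierarchy.linkage(pdist(data, metric=metric), method=linkage)
    order = [labels[i] for i in hierarchy.leaves_list(Z)]
    return ClusteredAxis(labels=labels, linkage=Z, leaf_order=order)


def pair_expression_similarity(
    transformed: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    threshold: float = 0.8,
    selection: dict[tuple[str, str], str] | None = None,
) -> tuple[list[PairSimilarity], pd.DataFrame]:
    """Pearson correlation of transformed expression profiles per pair.

    A pair is 'similar' when r >= threshold.  When a mapping of pair ->
    selection class is given, the summary reports the fraction of similar
    pairs per class (the diagnostic contrast between purifying- and
    diversifying-selected duplicates).
    """
    results: list[PairSimilarity] = []
    for a, b in pairs:
        for g in (a, b):
            if g not in transformed.index:
                raise KeyError(f"gene {g!r} missing from expression matrix")
        ra = transformed.loc[a].to_numpy(dtype=float)
        rb = transformed.loc[b].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            r = float(np.corrcoef(ra, rb)[0, 1])
        if np.isnan(r):  # constant profile: correlation undefined, call it 0
            r = 0.0
        results.append(PairSimilarity(a, b, r, r >= threshold))
    rows = []
    if selection:
        by_class: dict[str, list[bool]] = {}
        for res in results:
            cls = selection.get((res.gene_a, res.gene_b)) or selection.get(
                (res.gene_b, res.gene_a), "unclassified")
            by_class.setdefault(cls, []).append(res.similar)
        for cls, flags in by_class.items():
            rows.append((cls, len(flags), sum(flags), sum(flags) / len(flags)))
    summary = pd.DataFrame(rows, columns=["selection", "n_pairs", "n_similar",
                                          "fraction_similar"])
    return results, summary
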