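"""Expression fold changes, regulated-gene filtering, k-means trajectory
clustering and the condition dendrogram.

Input is a post-summarisation log2 abundance matrix (genes x conditions A-E)
with sample A as the unstressed reference.  A gene is "regulated" when its
absolute fold change versus A strictly exceeds the threshold (default
1.8-fold) in at least one of B-E.  Regulated genes are clustered on their
log2-FC trajectories over B-E with Euclidean k-means (default k = 3); the
kept solution is the best of ``n_restarts`` by within-cluster sum of
squares, and clusters are relabelled canonically by descending mean FC in
condition B so labels are stable across seeds on well-separated data.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .set_stats import CorrelationResult, GeneSet, spearman

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "fold_changes",
    "filter_regulated",
    "kmeans_patterns",
    "sample_dendrogram",
    "length_regulation_correlation",
]

DEFAULT_FOLD_THRESHOLD = 1.8


class ExpressionMatrix:
    """log2 abundance, genes x conditions, with a reference condition."""

    def __init__(self, values: pd.DataFrame, reference: str = "A") -> None:
        if reference not in values.columns:
            raise ValueError(f"reference condition {reference!r} absent")
        if values.index.has_duplicates:
            raise ValueError("duplicate gene identifiers")
        self.values = values.astype(float)
        self.values.index.name = "gene_id"
        self.reference = reference

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t")


def read_expression(path: str | Path, reference: str = "A") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df, reference=reference)


def fold_changes(m: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene log2 FC of every non-reference condition versus the reference."""
    ref = m.values[m.reference]
    fc = m.values.drop(columns=[m.reference]).sub(ref, axis=0)
    return fc


def filter_regulated(
    fc: pd.DataFrame, threshold_fold: float = DEFAULT_FOLD_THRESHOLD
) -> GeneSet:
    """Genes whose |FC| strictly exceeds the fold threshold somewhere."""
    if threshold_fold <= 1:
        raise ValueError("threshold_fold must exceed 1")
    cut = math.log2(threshold_fold)
    mask = (fc.abs() > cut).any(axis=1)
    return GeneSet(
        name="regulated",
        genes=frozenset(fc.index[mask]),
        provenance=f">|{threshold_fold}|-fold in >=1 non-reference condition",
    )


def kmeans_patterns(
    fc: pd.DataFrame,
    regulated: GeneSet,
    k: int = 3,
    n_restarts: int = 20,
    seed: int = 0,
) -> tuple[pd.Series, pd.DataFrame, float]:
    """K-means on regulated genes' FC trajectories.

    Returns (assignments as 1-based labels indexed by gene, per-cluster mean
    trajectory, silhouette score).  Cluster 1 has the highest mean FC in the
    first non-reference condition (B under the default layout).
    """
    genes = sorted(regulated.genes & set(fc.index))
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(genes):
        raise ValueError(f"k={k} exceeds {len(genes)} regulated genes")
    x = fc.loc[genes].to_numpy()
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(x)
    b_col = 0  # first non-reference condition, condition B canonically
    order = np.argsort(-km.cluster_centers_[:, b_col], kind="stable")
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series([relabel[r] for r in raw], index=genes, name="cluster")
    centers = pd.DataFrame(
        km.cluster_centers_[order], index=range(1, k + 1), columns=fc.columns
    )
    sil = (
        float(silhouette_score(x, raw)) if 1 < k < len(genes) else float("nan")
    )
    return labels, centers, sil


def sample_dendrogram(
    m: ExpressionMatrix, regulated: GeneSet
) -> tuple[np.ndarray, str]:
    """Hierarchical clustering of condition columns over regulated genes.

    Distance 1 - Pearson correlation, average linkage.  Returns the scipy
    linkage matrix and a Newick serialisation with branch lengths.
    """
    genes = sorted(regulated.genes & set(m.genes))
    sub = m.values.loc[genes]
    if sub.shape[1] < 3:
        raise ValueError("need at least three conditions")
    for cond in sub.columns:
        if sub[cond].nunique() <= 1:
            raise ValueError(f"condition {cond!r} is constant; correlation undefined")
    corr = np.corrcoef(sub.to_numpy().T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2  # numerical symmetry
    link = hierarchy.average(squareform(dist, checks=False))
    newick = _to_newick(link, list(sub.columns))
    return link, newick


def _to_newick(link: np.ndarray, labels: Sequence[str]) -> str:
    tree = hierarchy.to_tree(link)

    def rec(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


def length_regulation_correlation(
    fc: pd.DataFrame,
    gene_lengths: Mapping[str, int],
    condition: str = "B",
    subset: GeneSet | None = None,
) -> CorrelationResult:
    """Spearman between log2 FC (condition vs reference) and log2 gene length."""
    genes = [g for g in fc.index if g in gene_lengths]
    if subset is not None:
        genes = [g for g in genes if g in subset]
    x = [math.log2(gene_lengths[g]) for g in genes]
    y = fc.loc[genes, condition].tolist()
    return spearman(x, y, method="t")
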