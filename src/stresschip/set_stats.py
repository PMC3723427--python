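"""Gene-set overlap and rank-correlation statistics.

Overlap significance is the one-sided hypergeometric upper tail: with a
universe of N genes, drawing |B| genes at random, the probability of hitting
at least the observed |A ∩ B| members of A.  The universe is the set of
genes that passed profiling, not every annotated gene — a conservative
choice when profiling drops genes non-randomly.

Spearman rank correlations use average ranks on ties with the two-sided
t-approximation p-value; for n <= 8 an exact permutation p (enumerating all
n! rank assignments) is available and is the default at those sizes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GeneSet",
    "OverlapResult",
    "CorrelationResult",
    "hypergeometric_overlap",
    "category_enrichment",
    "spearman",
    "regulation_correlation",
]

SPEARMAN_EXACT_N_MAX = 8


@dataclass(frozen=True)
class GeneSet:
    """Named set of gene identifiers with provenance (test/threshold)."""

    name: str
    genes: frozenset[str]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def intersection(self, other: "GeneSet") -> "GeneSet":
        return GeneSet(
            name=f"{self.name}&{other.name}",
            genes=self.genes & other.genes,
            provenance=f"intersection({self.provenance}; {other.provenance})",
        )


@dataclass(frozen=True)
class OverlapResult:
    set_a: int
    set_b: int
    intersection: int
    universe: int
    p_value: float
    fold_enrichment: float


@dataclass(frozen=True)
class CorrelationResult:
    rs: float
    p_value: float
    n: int


def hypergeometric_overlap(a: GeneSet, b: GeneSet, universe: GeneSet) -> OverlapResult:
    """Upper-tail P[X >= |a ∩ b|], X ~ Hypergeometric(|U|, |a|, |b|)."""
    if len(universe) == 0:
        raise ValueError("empty universe")
    if not a.genes <= universe.genes or not b.genes <= universe.genes:
        raise ValueError("sets must be subsets of the universe")
    n_u, n_a, n_b = len(universe), len(a), len(b)
    k = len(a.genes & b.genes)
    p = float(stats.hypergeom.sf(k - 1, n_u, n_a, n_b))
    expected = n_a * n_b / n_u
    fold = k / expected if expected > 0 else math.nan
    return OverlapResult(n_a, n_b, k, n_u, min(p, 1.0), fold)


def category_enrichment(
    genes: GeneSet, category: GeneSet, universe: GeneSet
) -> OverlapResult:
    """Over-representation of ``genes`` in ``category`` (e.g. a length group)."""
    return hypergeometric_overlap(genes, category, universe)


def spearman(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> CorrelationResult:
    """Spearman rank correlation with average ranks on ties.

    ``method``: ``"t"`` (two-sided t approximation), ``"permutation"``
    (exact, n <= 8), or ``"auto"`` (exact when n <= 8, else t).
    Constant input makes rs undefined (NaN) and is flagged by p = NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y differ in length")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(math.nan, math.nan, n)
    if method == "auto":
        method = "permutation" if n <= SPEARMAN_EXACT_N_MAX else "t"
    rs, p_t = stats.spearmanr(x, y)
    if method == "t":
        return CorrelationResult(float(rs), float(p_t), n)
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    if n > SPEARMAN_EXACT_N_MAX:
        raise ValueError(f"exact permutation p limited to n <= {SPEARMAN_EXACT_N_MAX}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    perms = np.array(list(itertools.permutations(range(n))))
    rs_all = _pearson_rows(rx[perms], ry)
    rs_obs = _pearson_rows(rx[None, :], ry)[0]
    p = float(np.mean(np.abs(rs_all) >= abs(rs_obs) - 1e-12))
    return CorrelationResult(float(rs), p, n)


def _pearson_rows(rows: np.ndarray, y: np.ndarray) -> np.ndarray:
    rows = rows - rows.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((rows**2).sum(axis=1) * (yc**2).sum())
    return rows @ yc / denom


def regulation_correlation(
    fold_changes: Mapping[str, float],
    promoter_deltas: Mapping[str, float],
    split: str = "all",
) -> CorrelationResult:
    """Spearman between per-gene log2 fold change and promoter signal change.

    ``split`` restricts to up-regulated (FC > 0) or down-regulated (FC < 0)
    genes, mirroring the separate analysis of activated and repressed sets.
    """
    if split not in {"all", "up_only", "down_only"}:
        raise ValueError(f"unknown split {split!r}")
    genes = [
        g for g, fc in fold_changes.items()
        if g in promoter_deltas
        and math.isfinite(fc) and math.isfinite(promoter_deltas[g])
        and (
            split == "all"
            or (split == "up_only" and fc > 0)
            or (split == "down_only" and fc < 0)
        )
    ]
    if len(genes) < 10:
        raise ValueError(f"only {len(genes)} genes in split {split!r}; need >= 10")
    fc = [fold_changes[g] for g in genes]
    dv = [promoter_deltas[g] for g in genes]
    return spearman(fc, dv, method="t")
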