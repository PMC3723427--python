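"""Per-gene differential-occupancy testing across conditions.

Each gene is tested with the Kruskal–Wallis rank test ("non-parametric
ANOVA"): one group of observations per condition, observations being the
probe values inside the central-ORF window.  Probes are the only replicated
measurement available per condition once the two culture replicates are
merged, so they serve as the observational unit; a bin-level alternative is
available through ``unit="bins"``.  Genes with p below alpha (0.05 by
default, uncorrected, with Benjamini–Hochberg available by flag) form the
"changed" set for downstream overlap statistics.

A paired two-sided Wilcoxon signed-rank test compares the per-gene central-
ORF values of two conditions within each gene-length group (Welch's t by
flag).
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .set_stats import GeneSet

__all__ = [
    "GeneChangeResult",
    "kruskal_wallis",
    "detect_changed_genes",
    "per_lengthgroup_change_test",
]

logger = logging.getLogger(__name__)

EXACT_N_MAX = 12


@dataclass(frozen=True)
class GeneChangeResult:
    gene_id: str
    statistic: float
    p_value: float
    n_per_condition: tuple[int, ...]


def _kw_statistic(groups: Sequence[np.ndarray]) -> float:
    """Tie-corrected Kruskal–Wallis H (helper shared with the exact path)."""
    alldata = np.concatenate(groups)
    n = alldata.size
    ranks = stats.rankdata(alldata)
    offset = 0
    ssbn = 0.0
    for g in groups:
        r = ranks[offset : offset + g.size]
        ssbn += r.sum() ** 2 / g.size
        offset += g.size
    h = 12.0 / (n * (n + 1)) * ssbn - 3 * (n + 1)
    _, counts = np.unique(alldata, return_counts=True)
    tie = 1 - np.sum(counts**3 - counts) / (n**3 - n)
    return h if tie == 0 else h / tie


def kruskal_wallis(
    groups: Sequence[Sequence[float]], method: str = "chi2"
) -> tuple[float, float]:
    """Kruskal–Wallis H and p over >= 2 groups.

    ``method="chi2"`` uses the chi-squared approximation with k-1 degrees of
    freedom; ``"permutation"`` enumerates every assignment of the pooled
    observations to the group sizes (total n <= 12) and returns the exact
    tail probability P[H >= H_obs].  All-identical observations give
    H = 0, p = 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    if method == "chi2":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            h, p = stats.kruskal(*arrays)
        return float(h), float(p)
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    n = pooled.size
    if n > EXACT_N_MAX:
        raise ValueError(f"exact permutation p limited to total n <= {EXACT_N_MAX}")
    sizes = [a.size for a in arrays]
    h_obs = _kw_statistic(arrays)
    hits = 0
    total = 0
    idx = np.arange(n)
    # enumerate distinct index partitions group by group
    for assignment in _partitions(tuple(idx), tuple(sizes)):
        gs = [pooled[np.array(part)] for part in assignment]
        if _kw_statistic(gs) >= h_obs - 1e-12:
            hits += 1
        total += 1
    return float(h_obs), hits / total


def _partitions(items: tuple, sizes: tuple):
    if len(sizes) == 1:
        yield (items,)
        return
    for combo in itertools.combinations(items, sizes[0]):
        rest = tuple(x for x in items if x not in combo)
        for tail in _partitions(rest, sizes[1:]):
            yield (combo,) + tail


def detect_changed_genes(
    observations: Mapping[str, Mapping[str, Sequence[float]]],
    alpha: float = 0.05,
    correction: str | None = None,
) -> tuple[GeneSet, pd.DataFrame]:
    """Kruskal–Wallis per gene over its per-condition observation groups.

    ``observations`` maps gene_id -> condition -> probe values.  Genes
    missing a condition (or with an empty group) are excluded and logged.
    With ``correction="bh"`` selection uses Benjamini–Hochberg adjusted
    p-values; default mirrors an uncorrected p < alpha cut.
    """
    conditions: list[str] | None = None
    rows = []
    for gene_id, per_cond in observations.items():
        if conditions is None:
            conditions = list(per_cond)
        groups = [np.asarray(per_cond.get(c, ()), dtype=float) for c in conditions]
        if any(g.size == 0 for g in groups):
            logger.warning("gene %s missing observations for a condition; excluded", gene_id)
            continue
        h, p = kruskal_wallis(groups)
        rows.append((gene_id, h, p, tuple(g.size for g in groups)))
    table = pd.DataFrame(rows, columns=["gene_id", "H", "p", "n_per_condition"])
    pvals = table["p"].to_numpy()
    if correction == "bh":
        table["p_adj"] = stats.false_discovery_control(pvals) if len(pvals) else pvals
        selected = table["p_adj"] < alpha
    elif correction is None:
        selected = pvals < alpha
    else:
        raise ValueError(f"unknown correction {correction!r}")
    table["selected"] = selected
    changed = GeneSet(
        name="changed",
        genes=frozenset(table.loc[table["selected"], "gene_id"]),
        provenance=f"kruskal-wallis p<{alpha}"
        + (f" ({correction})" if correction else " (uncorrected)"),
    )
    return changed, table


def per_lengthgroup_change_test(
    values_a: Mapping[str, float],
    values_b: Mapping[str, float],
    length_groups: Mapping[str, str],
    test: str = "wilcoxon",
    min_genes: int = 5,
) -> pd.DataFrame:
    """Paired condition-pair test of central-ORF values within length groups.

    Returns one row per length group with the statistic and two-sided p;
    groups with fewer than ``min_genes`` paired genes get a missing p and a
    warning.  ``test`` is ``"wilcoxon"`` (signed-rank) or ``"welch"``.
    """
    common = [
        g for g in values_a
        if g in values_b and g in length_groups
        and math.isfinite(values_a[g]) and math.isfinite(values_b[g])
    ]
    rows = []
    by_group: dict[str, list[str]] = {}
    for g in common:
        by_group.setdefault(length_groups[g], []).append(g)
    for group, members in sorted(by_group.items()):
        a = np.array([values_a[g] for g in members])
        b = np.array([values_b[g] for g in members])
        if len(members) < min_genes:
            warnings.warn(
                f"length group {group!r}: only {len(members)} genes; p omitted",
                stacklevel=2,
            )
            rows.append((group, len(members), np.nan, np.nan))
            continue
        diffs = b - a
        if test == "wilcoxon":
            if np.all(diffs == 0):
                stat, p = 0.0, 1.0
            else:
                stat, p = stats.wilcoxon(b, a)
        elif test == "welch":
            stat, p = stats.ttest_rel(b, a)
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append((group, len(members), float(stat), float(p)))
    return pd.DataFrame(rows, columns=["group", "n", "statistic", "p"])
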