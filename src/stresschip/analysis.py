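"""In-memory analysis stages over a loaded dataset.

These functions hold the science of the pipeline; :mod:`stresschip.pipeline`
wraps them with file I/O, caching and a manifest, and the same routines can
be driven directly on an in-memory :class:`SimulatedDataset` without
touching disk.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotations import assign_length_groups, derive_flanks, length_group_labels
from .change_detection import detect_changed_genes, per_lengthgroup_change_test
from .chromatin_norm import NormalizationPolicy
from .expression import (
    filter_regulated,
    fold_changes,
    kmeans_patterns,
    length_regulation_correlation,
    sample_dendrogram,
)
from .metagene import central_orf_summary
from .promoter_profiles import (
    DEFAULT_BIN_WIDTH,
    DEFAULT_WINDOW,
    cluster_promoter_averages,
    profile_promoter,
    promoter_peak,
)
from .set_stats import (
    GeneSet,
    category_enrichment,
    hypergeometric_overlap,
    regulation_correlation,
)
from .signal_io import median_normalize

__all__ = [
    "normalize_tracks",
    "central_observations",
    "detect_all_species",
    "lengthgroup_ab_test",
    "overlap_analysis",
    "expression_analysis",
    "promoter_analysis",
]


def normalize_tracks(ds, mode: str = "additive"):
    """Per-species cross-condition median equalisation."""
    return {sp: median_normalize(ts, mode=mode) for sp, ts in ds.tracksets.items()}


def central_observations(ds, norm, species, fraction: float = 0.4):
    """Central-ORF probe observations and scalar means.

    Returns ``(observations, central)`` where
    ``observations[species][gene][condition]`` is the probe-value array used
    as the per-gene test unit and ``central[...]`` its mean.
    """
    observations: dict[str, dict] = {}
    central: dict[str, dict] = {}
    for sp in species:
        observations[sp] = {}
        central[sp] = {}
        for g in ds.genes:
            per_obs, per_val = {}, {}
            for cond, track in norm[sp].tracks.items():
                s = central_orf_summary(track, g, fraction)
                per_obs[cond] = s.probe_values
                per_val[cond] = s.value
            observations[sp][g.gene_id] = per_obs
            central[sp][g.gene_id] = per_val
    return observations, central


def detect_all_species(observations, alpha: float = 0.05, correction=None):
    """Changed-gene set and result table per species."""
    out = {}
    for sp, obs in observations.items():
        cs, table = detect_changed_genes(obs, alpha=alpha, correction=correction)
        out[sp] = (GeneSet(f"changed_{sp}", cs.genes, cs.provenance), table)
    return out


def lengthgroup_ab_test(central_sp, length_groups, cond_a="A", cond_b="B"):
    """Paired Wilcoxon of central-ORF values between two conditions, per
    gene-length group."""
    return per_lengthgroup_change_test(
        {g: v[cond_a] for g, v in central_sp.items()},
        {g: v[cond_b] for g, v in central_sp.items()},
        length_groups,
    )


def overlap_analysis(changed, length_groups, reference_species="Gcn5",
                     short_label=None):
    """Hypergeometric overlap of the reference changed set with every other
    changed set, plus short-gene enrichment of each intersection."""
    universe = GeneSet("universe", frozenset(length_groups), "profiled genes")
    if short_label is None:
        short_label = length_group_labels([1000, 2000, 3000])[0]
    short = GeneSet(
        short_label,
        frozenset(g for g, lab in length_groups.items() if lab == short_label),
        "length group",
    )
    rows = []
    ref = changed[reference_species]
    for sp, cs in changed.items():
        if sp == reference_species:
            continue
        ov = hypergeometric_overlap(ref, cs, universe)
        enr = category_enrichment(ref.intersection(cs), short, universe)
        rows.append(
            {
                "set_a": reference_species, "set_b": sp,
                "n_a": ov.set_a, "n_b": ov.set_b,
                "intersection": ov.intersection, "universe": ov.universe,
                "overlap_p": ov.p_value, "overlap_fold": ov.fold_enrichment,
                "short_gene_p": enr.p_value, "short_gene_fold": enr.fold_enrichment,
            }
        )
    return pd.DataFrame(rows)


def expression_analysis(ds, fold_threshold=1.8, k=3, n_restarts=20, seed=0):
    """Fold changes, regulated set, k-means clusters, dendrogram and the
    FC-versus-length correlations."""
    fc = fold_changes(ds.expression)
    regulated = filter_regulated(fc, fold_threshold)
    labels, centers, sil = kmeans_patterns(
        fc, regulated, k=k, n_restarts=n_restarts, seed=seed
    )
    link, newick = sample_dendrogram(ds.expression, regulated)
    lengths = {g.gene_id: g.length for g in ds.genes}
    corr_all = length_regulation_correlation(fc, lengths)
    corr_reg = length_regulation_correlation(fc, lengths, subset=regulated)
    return {
        "fc": fc,
        "regulated": regulated,
        "labels": labels,
        "centers": centers,
        "silhouette": sil,
        "linkage": link,
        "newick": newick,
        "fc_length_all": corr_all,
        "fc_length_regulated": corr_reg,
    }


def promoter_analysis(
    ds,
    norm,
    regulated: GeneSet,
    fc: pd.DataFrame,
    species=("Gcn5", "H3K18ac", "H4K16ac"),
    window=DEFAULT_WINDOW,
    bin_width=DEFAULT_BIN_WIDTH,
    policy: NormalizationPolicy = NormalizationPolicy(),
    clusters: dict | None = None,
):
    """Promoter profiles and peaks of regulated genes, peak-level B-A deltas,
    regulation correlations per split, and (when cluster labels are given)
    per-cluster average normalised profiles for every condition."""
    genes_by_id = {g.gene_id: g for g in ds.genes}
    track_map = {sp: ts.tracks for sp, ts in norm.items()}
    profiles = {}
    for gid in sorted(regulated.genes):
        g = genes_by_id.get(gid)
        if g is not None:
            profiles[gid] = profile_promoter(
                track_map, g, window, bin_width, policy, ds.chrom_sizes
            )
    peaks = []
    deltas: dict[str, dict[str, float]] = {sp: {} for sp in species}
    for gid, prof in profiles.items():
        for sp in species:
            pk_b = promoter_peak(prof, sp, "B")
            pk_a = promoter_peak(prof, sp, "A")
            if pk_b is not None:
                peaks.append(
                    {"gene_id": gid, "species": sp, "condition": "B",
                     "peak_offset": pk_b.peak_offset, "peak_value": pk_b.peak_value}
                )
            if pk_a is not None and pk_b is not None:
                deltas[sp][gid] = pk_b.peak_value - pk_a.peak_value
    fc_b = fc["B"].to_dict()
    corr_rows = []
    for sp in species:
        for split in ("all", "up_only", "down_only"):
            try:
                c = regulation_correlation(fc_b, deltas[sp], split=split)
                corr_rows.append(
                    {"species": sp, "split": split, "rs": c.rs, "p": c.p_value,
                     "n": c.n}
                )
            except ValueError:
                corr_rows.append(
                    {"species": sp, "split": split, "rs": np.nan, "p": np.nan,
                     "n": 0}
                )
    cluster_profiles = None
    if clusters:
        cluster_profiles = {}
        for sp in species:
            for cond in next(iter(norm.values())).conditions:
                cluster_profiles[(sp, cond)] = cluster_promoter_averages(
                    profiles, clusters, sp, cond, policy
                )
    return {
        "profiles": profiles,
        "peaks": pd.DataFrame(peaks),
        "deltas": deltas,
        "correlations": pd.DataFrame(corr_rows),
        "cluster_profiles": cluster_profiles,
    }
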