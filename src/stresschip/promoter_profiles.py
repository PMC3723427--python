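"""ATG-anchored promoter profiling and promoter-peak extraction.

Promoter windows are expressed in bp relative to the annotated start codon
(upstream negative), default [-500, +100) in 25 bp bins, and are strand
oriented: offset -100 is 100 bp 5' of the ATG along transcription whichever
genomic strand the gene is on.  Raw per-species/condition bin values are
kept alongside H3-normalised ones; the promoter peak of a profile is the
maximal H3-normalised bin at strictly negative offset, ties broken toward
the start codon.  A fixed-window upstream mean is exported as well, since
"peak level" can reasonably be read either way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .annotations import GeneAnnotation
from .chromatin_norm import NormalizationPolicy, normalize_bins
from .metagene import GroupProfile
from .signal_io import SignalTrack

__all__ = [
    "PromoterProfile",
    "PromoterPeak",
    "DEFAULT_WINDOW",
    "DEFAULT_BIN_WIDTH",
    "profile_promoter",
    "promoter_window_bins",
    "promoter_peak",
    "upstream_mean",
    "cluster_promoter_averages",
]

DEFAULT_WINDOW = (-500, 100)
DEFAULT_BIN_WIDTH = 25
H3_SPECIES = "H3"


@dataclass
class PromoterProfile:
    gene_id: str
    offsets: np.ndarray                       # bin start offsets, bp rel. ATG
    bin_width: int
    raw: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    normalized: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)


@dataclass(frozen=True)
class PromoterPeak:
    gene_id: str
    peak_offset: float                        # bin start offset, always < 0
    peak_value: float
    species: str
    condition: str


def promoter_window_bins(
    window: tuple[int, int] = DEFAULT_WINDOW, bin_width: int = DEFAULT_BIN_WIDTH
) -> np.ndarray:
    lo, hi = window
    if not lo < 0 <= hi:
        raise ValueError("window must span the start codon")
    if (hi - lo) % bin_width:
        raise ValueError("bin_width must divide the window length")
    return np.arange(lo, hi, bin_width)


def _bin_interval(
    gene: GeneAnnotation, offset: int, width: int
) -> tuple[int, int]:
    """Genomic half-open interval of the bin [offset, offset+width) in
    transcription coordinates anchored at the ATG."""
    if gene.strand == "+":
        return gene.start + offset, gene.start + offset + width
    return gene.end - offset - width, gene.end - offset


def bin_promoter(
    track: SignalTrack,
    gene: GeneAnnotation,
    window: tuple[int, int] = DEFAULT_WINDOW,
    bin_width: int = DEFAULT_BIN_WIDTH,
    chrom_size: int | None = None,
) -> np.ndarray:
    """Mean probe signal per fixed-width promoter bin; NaN where empty or
    where the window runs off the chromosome."""
    offsets = promoter_window_bins(window, bin_width)
    out = np.full(offsets.size, np.nan)
    limit = chrom_size if chrom_size is not None else np.inf
    for i, off in enumerate(offsets):
        s, e = _bin_interval(gene, int(off), bin_width)
        if s < 0 or e > limit:
            continue
        _, vals = track.probes_in(gene.chrom, s, e)
        if vals.size:
            out[i] = float(np.mean(vals))
    return out


def profile_promoter(
    tracksets: Mapping[str, Mapping[str, SignalTrack]],
    gene: GeneAnnotation,
    window: tuple[int, int] = DEFAULT_WINDOW,
    bin_width: int = DEFAULT_BIN_WIDTH,
    policy: NormalizationPolicy = NormalizationPolicy(),
    chrom_sizes: Mapping[str, int] | None = None,
) -> PromoterProfile:
    """Raw and H3-normalised promoter bins for every species x condition.

    ``tracksets`` maps species -> condition -> track and must include the
    ``"H3"`` species for normalisation; the H3 profile of each condition is
    the denominator for every other species in that condition.
    """
    offsets = promoter_window_bins(window, bin_width)
    limit = chrom_sizes.get(gene.chrom) if chrom_sizes else None
    prof = PromoterProfile(gene.gene_id, offsets, bin_width)
    for species, conds in tracksets.items():
        for cond, track in conds.items():
            prof.raw[(species, cond)] = bin_promoter(
                track, gene, window, bin_width, limit
            )
    for (species, cond), bins in prof.raw.items():
        if species == H3_SPECIES:
            continue
        h3 = prof.raw.get((H3_SPECIES, cond))
        if h3 is not None:
            prof.normalized[(species, cond)] = normalize_bins(bins, h3, policy)
    return prof


def promoter_peak(
    profile: PromoterProfile, species: str, condition: str
) -> PromoterPeak | None:
    """Maximal H3-normalised upstream bin; ties go to the bin nearest the ATG.

    Only bins wholly upstream of the start codon (offset + width <= 0)
    compete.  Returns None when every upstream bin is missing.
    """
    key = (species, condition)
    if key not in profile.normalized:
        raise KeyError(f"no normalised values for {key}")
    vals = profile.normalized[key]
    upstream = profile.offsets + profile.bin_width <= 0
    cand = np.where(upstream & ~np.isnan(vals))[0]
    if cand.size == 0:
        return None
    m = np.max(vals[cand])
    best = cand[vals[cand] == m][-1]  # tie -> bin nearest the start codon
    return PromoterPeak(
        profile.gene_id, float(profile.offsets[best]), float(vals[best]),
        species, condition,
    )


def upstream_mean(
    profile: PromoterProfile, species: str, condition: str
) -> float:
    """Mean H3-normalised signal over all wholly upstream bins (the
    fixed-window alternative to the max-based peak)."""
    vals = profile.normalized[(species, condition)]
    upstream = profile.offsets + profile.bin_width <= 0
    sel = vals[upstream]
    sel = sel[~np.isnan(sel)]
    return float(np.mean(sel)) if sel.size else float("nan")


def cluster_promoter_averages(
    profiles: Mapping[str, PromoterProfile],
    clusters: Mapping[str, int],
    species: str,
    condition: str,
    policy: NormalizationPolicy = NormalizationPolicy(),
) -> dict[int, tuple[GroupProfile, GroupProfile]]:
    """Per-cluster mean promoter profile, raw and H3-normalised.

    Averaging precedes normalisation: the cluster-average target profile is
    divided by (or log-subtracted from) the cluster-average H3 profile.
    Returns cluster -> (raw GroupProfile, normalised GroupProfile).
    """
    ids = [g for g in clusters if g in profiles]
    if not ids:
        raise ValueError("no profiled genes carry a cluster label")
    out: dict[int, tuple[GroupProfile, GroupProfile]] = {}
    for cl in sorted(set(clusters[g] for g in ids)):
        members = [g for g in ids if clusters[g] == cl]
        if not members:
            raise ValueError(f"empty cluster {cl}")
        raw_mat = np.vstack([profiles[g].raw[(species, condition)] for g in members])
        h3_mat = np.vstack([profiles[g].raw[(H3_SPECIES, condition)] for g in members])
        n = np.sum(~np.isnan(raw_mat), axis=0)
        raw_mean = _nanmean_cols(raw_mat)
        h3_mean = _nanmean_cols(h3_mat)
        norm = normalize_bins(raw_mean, h3_mean, policy)
        labels = ["promoter"] * raw_mean.size
        out[cl] = (
            GroupProfile(f"cluster{cl}", raw_mean, n, labels),
            GroupProfile(f"cluster{cl}:H3norm", norm, n, labels),
        )
    return out


def _nanmean_cols(mat: np.ndarray) -> np.ndarray:
    n = np.sum(~np.isnan(mat), axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(n > 0, np.nansum(mat, axis=0) / np.maximum(n, 1), np.nan)
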