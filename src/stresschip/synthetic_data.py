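"""Synthetic yeast-like dataset generator with planted ground truth.

The generator emits everything the pipeline consumes — a multi-chromosome
ORF annotation with a log-normal gene-length spread, probe-resolution
log-scale signal tracks for four species (Gcn5, H3K18ac, H4K16ac, H3) in
five conditions A-E, and a log2 expression matrix — together with a
ground-truth table recording every planted effect:

* baseline ORF Gcn5 decreasing in log gene length, H3 increasing;
* a condition-B-only Gcn5 shift: down on <1 kb ORFs, up on >3 kb ORFs,
  with A, C, D and E left untouched (the transient relocalisation); the
  long-gene gain is rescaled so the genome-wide median of track B stays at
  track A's — a redistribution of Gcn5, not a net gain — which keeps
  cross-sample median equalisation from planting offsets on untouched genes;
* an H3-depleted (nucleosome-free) promoter region upstream of every ATG;
* H3K18ac coupled to the deterministic Gcn5 signal, H4K16ac uncoupled;
* three expression clusters — up in B, down in B, up in B and D — assigned
  independently of gene length, each with per-gene amplitude spread;
* condition-B promoter coupling: H3K18ac follows the fold change of all
  regulated genes, Gcn5 follows up-regulated genes only, and H3 moves
  opposite to the fold change (histone eviction on activation).

Identical seeds give bit-identical datasets.  ``null_config()`` zeroes
every effect for calibration runs; ``default_config()`` is the documented
effect-bearing configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .annotations import (
    GeneAnnotation,
    assign_length_groups,
    read_annotations,
    read_chrom_sizes,
    write_annotations,
)
from .expression import ExpressionMatrix, read_expression
from .signal_io import SignalTrack, TrackSet, read_track, write_track

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate",
    "write_dataset",
    "load_dataset",
    "default_config",
    "null_config",
]

SPECIES = ("Gcn5", "H3K18ac", "H4K16ac", "H3")
CONDITIONS = ("A", "B", "C", "D", "E")


@dataclass
class SimulationConfig:
    """All distributions and effect sizes, in one serialisable record.

    Signal values are log2-scale arbitrary units throughout; effect sizes
    are additive on that scale.
    """

    seed: int = 20130716
    n_genes: int = 3000
    n_chromosomes: int = 4
    species: tuple[str, ...] = SPECIES
    conditions: tuple[str, ...] = CONDITIONS

    # gene geometry
    length_median_bp: float = 1400.0     # log-normal median ORF length
    length_sigma: float = 0.7            # log-normal shape (natural log)
    min_length_bp: int = 200
    gap_median_bp: float = 400.0
    gap_sigma: float = 0.5
    min_gap_bp: int = 150
    probe_spacing_bp: int = 5

    # noise (per-probe Gaussian sd, log2 units)
    noise_sigma: dict = field(
        default_factory=lambda: {s: 0.3 for s in SPECIES}
    )

    # chromatin effects
    gcn5_orf_level: float = 0.5
    length_occupancy_slope: float = 0.3   # Gcn5 per log2(L/median), subtracted
    acetyl_length_slope: float = 0.25     # K18/K4 decline per log2(L/median)
    h3_orf_level: float = 0.3
    h3_length_slope: float = 0.2          # H3 rise per log2(L/median)
    relocalization_short: float = -0.5    # B-only Gcn5 shift, <1 kb ORFs
    relocalization_long: float = 0.5      # B-only Gcn5 shift, >3 kb ORFs
    length_boundaries: tuple[int, ...] = (1000, 2000, 3000)
    promoter_dip_depth: float = 1.0       # H3 NDR depth
    promoter_dip_center: float = -100.0   # bp rel. ATG
    promoter_dip_sigma: float = 60.0
    k18_gcn5_coupling: float = 0.8
    promoter_window_bp: int = 200         # upstream span carrying B-coupling

    # expression
    expr_base_mean: float = 8.0
    expr_base_sigma: float = 1.0
    expr_noise_sigma: float = 0.15
    cluster_fractions: tuple[float, ...] = (0.05, 0.05, 0.04)
    cluster_b_fc: tuple[float, ...] = (2.0, -2.0, 1.5)     # log2 FC in B
    cluster_c_fc: tuple[float, ...] = (0.5, -0.5, 0.4)     # residual adaptation
    cluster_d_fc: tuple[float, ...] = (0.0, 0.0, 1.5)      # log2 FC in D
    amplitude_sigma: float = 0.25         # per-gene log-normal FC multiplier
    promoter_fc_coupling: float = 0.4     # K18 promoter delta per FC unit
    gcn5_fc_coupling: float = 0.4         # Gcn5, up-regulated genes only
    h3_fc_coupling: float = -0.2          # H3 moves against regulation
    promoter_coupling_noise: float = 0.1  # per-gene jitter on the deltas

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_chromosomes < 1:
            raise ValueError("n_genes and n_chromosomes must be positive")
        if self.length_median_bp <= 0 or self.length_sigma < 0:
            raise ValueError("invalid gene-length distribution")
        if self.gap_median_bp < 0 or self.gap_sigma < 0 or self.min_gap_bp < 0:
            raise ValueError("invalid intergenic-gap distribution")
        if self.probe_spacing_bp < 1:
            raise ValueError("probe spacing must be >= 1 bp")
        if any(v < 0 for v in self.noise_sigma.values()):
            raise ValueError("noise sigma must be non-negative")
        if not 0 <= sum(self.cluster_fractions) <= 1:
            raise ValueError("cluster fractions must sum to at most 1")
        if len(self.cluster_fractions) != 3:
            raise ValueError("exactly three expression clusters are modelled")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(dataclasses.asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                v = raw[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def default_config(**overrides) -> SimulationConfig:
    return dataclasses.replace(SimulationConfig(), **overrides)


def null_config(**overrides) -> SimulationConfig:
    """Every planted effect zeroed: flat tracks + unstructured expression."""
    cfg = SimulationConfig(
        gcn5_orf_level=0.0,
        length_occupancy_slope=0.0,
        acetyl_length_slope=0.0,
        h3_orf_level=0.0,
        h3_length_slope=0.0,
        relocalization_short=0.0,
        relocalization_long=0.0,
        promoter_dip_depth=0.0,
        k18_gcn5_coupling=0.0,
        cluster_fractions=(0.0, 0.0, 0.0),
        cluster_b_fc=(0.0, 0.0, 0.0),
        cluster_c_fc=(0.0, 0.0, 0.0),
        cluster_d_fc=(0.0, 0.0, 0.0),
        promoter_fc_coupling=0.0,
        gcn5_fc_coupling=0.0,
        h3_fc_coupling=0.0,
        promoter_coupling_noise=0.0,
    )
    return dataclasses.replace(cfg, **overrides)


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genes: list[GeneAnnotation]
    chrom_sizes: dict[str, int]
    tracksets: dict[str, TrackSet]          # species -> TrackSet
    expression: ExpressionMatrix
    truth: pd.DataFrame                     # one row per gene


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Generate the full dataset in memory (see module docstring)."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes, chrom_sizes = _place_genes(config, rng)
    n = len(genes)
    lengths = np.array([g.length for g in genes])
    log_l = np.log2(lengths / config.length_median_bp)
    groups = assign_length_groups(genes, config.length_boundaries)
    labels = [groups[g.gene_id] for g in genes]
    short_label = f"<{config.length_boundaries[0] / 1000:g}kb"
    long_label = f">{config.length_boundaries[-1] / 1000:g}kb"
    gcn5_shift = np.where(
        [l == short_label for l in labels],
        config.relocalization_short,
        np.where([l == long_label for l in labels], config.relocalization_long, 0.0),
    )

    # expression clusters, assigned independently of gene length
    cluster = np.zeros(n, dtype=int)
    order = rng.permutation(n)
    offset = 0
    for ci, frac in enumerate(config.cluster_fractions, start=1):
        size = int(round(frac * n))
        cluster[order[offset : offset + size]] = ci
        offset += size
    amp = np.exp(rng.normal(0.0, config.amplitude_sigma, size=n))
    fc = {c: np.zeros(n) for c in config.conditions if c != "A"}
    for ci in (1, 2, 3):
        sel = cluster == ci
        fc["B"][sel] = config.cluster_b_fc[ci - 1] * amp[sel]
        fc["C"][sel] = config.cluster_c_fc[ci - 1] * amp[sel]
        fc["D"][sel] = config.cluster_d_fc[ci - 1] * amp[sel]

    # per-gene promoter deltas in condition B
    jitter = rng.normal(0.0, config.promoter_coupling_noise, size=(3, n))
    regulated = cluster > 0
    k18_prom = np.where(regulated, config.promoter_fc_coupling * fc["B"] + jitter[0], 0.0)
    gcn5_prom = np.where(
        regulated & (fc["B"] > 0), config.gcn5_fc_coupling * fc["B"] + jitter[1], 0.0
    )
    h3_prom = np.where(regulated, config.h3_fc_coupling * fc["B"] + jitter[2], 0.0)

    # expression matrix
    base = rng.normal(config.expr_base_mean, config.expr_base_sigma, size=n)
    expr = {}
    for c in config.conditions:
        noise = rng.normal(0.0, config.expr_noise_sigma, size=n)
        expr[c] = base + fc.get(c, np.zeros(n)) + noise
    expression = ExpressionMatrix(
        pd.DataFrame(expr, index=[g.gene_id for g in genes]), reference="A"
    )

    tracksets, long_scale = _build_tracks(
        config, rng, genes, chrom_sizes, log_l, gcn5_shift, k18_prom, gcn5_prom, h3_prom
    )
    gcn5_shift = np.where(gcn5_shift > 0, long_scale * gcn5_shift, gcn5_shift)

    truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "strand": [g.strand for g in genes],
            "length": lengths,
            "length_group": labels,
            "gcn5_shift": gcn5_shift,
            "cluster": cluster,
            "fc_B": fc["B"],
            "fc_D": fc["D"],
            "k18_promoter_delta_B": k18_prom,
            "gcn5_promoter_delta_B": gcn5_prom,
            "h3_promoter_delta_B": h3_prom,
        }
    ).set_index("gene_id", drop=False)
    return SimulatedDataset(config, genes, chrom_sizes, tracksets, expression, truth)


def _place_genes(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[GeneAnnotation], dict[str, int]]:
    n = config.n_genes
    mu_l = np.log(config.length_median_bp)
    mu_g = np.log(max(config.gap_median_bp, 1.0))
    lengths = np.maximum(
        rng.lognormal(mu_l, config.length_sigma, size=n).astype(int),
        config.min_length_bp,
    )
    gaps = np.maximum(
        rng.lognormal(mu_g, config.gap_sigma, size=n + config.n_chromosomes).astype(int),
        config.min_gap_bp,
    )
    strands = rng.choice(["+", "-"], size=n)
    per_chrom = np.array_split(np.arange(n), config.n_chromosomes)
    genes: list[GeneAnnotation] = []
    chrom_sizes: dict[str, int] = {}
    gi = 0
    for ci, idxs in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        pos = int(gaps[n + ci])
        for i in idxs:
            start = pos
            end = start + int(lengths[i])
            genes.append(
                GeneAnnotation(f"g{i:05d}", chrom, start, end, str(strands[i]))
            )
            pos = end + int(gaps[i])
            gi += 1
        chrom_sizes[chrom] = pos
    return genes, chrom_sizes


def _promoter_offsets(gene: GeneAnnotation, positions: np.ndarray) -> np.ndarray:
    """Transcription offset of each probe relative to the ATG (upstream < 0)."""
    if gene.strand == "+":
        return positions - gene.start
    return (gene.end - 1) - positions


def _build_tracks(
    config, rng, genes, chrom_sizes, log_l, gcn5_shift, k18_prom, gcn5_prom, h3_prom
):
    """Assemble deterministic signal + condition-B extras + noise.

    The condition-B Gcn5 relocalisation is a *redistribution*: the long-gene
    gain is rescaled (factor solved by bisection, noise included) so that
    track B's genome-wide median matches track A's.  Without this the
    cross-sample median equalisation downstream would convert the planted
    net signal gain into a spurious genome-wide offset on untouched genes.
    Returns (tracksets, long_shift_scale).
    """
    spacing = config.probe_spacing_bp
    probe_pos = {
        chrom: np.arange(spacing // 2, size, spacing, dtype=np.int64)
        for chrom, size in chrom_sizes.items()
    }
    chroms = sorted(probe_pos)
    genes_by_chrom: dict[str, list[int]] = {}
    for i, g in enumerate(genes):
        genes_by_chrom.setdefault(g.chrom, []).append(i)

    def zeros():
        return {c: np.zeros(probe_pos[c].size) for c in chroms}

    # deterministic per-species signal, shared by all conditions...
    det: dict[str, dict[str, np.ndarray]] = {s: zeros() for s in config.species}
    # ...condition-B-only extras, with the Gcn5 relocalisation split so the
    # long-gene component can be rescaled for median neutrality
    prom_extra: dict[str, dict[str, np.ndarray]] = {s: zeros() for s in config.species}
    reloc_short = zeros()
    reloc_long = zeros()
    w = config.promoter_window_bp

    for chrom in chroms:
        pos = probe_pos[chrom]
        for i in genes_by_chrom.get(chrom, ()):
            g = genes[i]
            lo = np.searchsorted(pos, g.start)
            hi = np.searchsorted(pos, g.end)
            orf = slice(lo, hi)
            if "Gcn5" in det:
                det["Gcn5"][chrom][orf] += (
                    config.gcn5_orf_level - config.length_occupancy_slope * log_l[i]
                )
                if gcn5_shift[i] < 0:
                    reloc_short[chrom][orf] += gcn5_shift[i]
                elif gcn5_shift[i] > 0:
                    reloc_long[chrom][orf] += gcn5_shift[i]
            if "H3" in det:
                det["H3"][chrom][orf] += (
                    config.h3_orf_level + config.h3_length_slope * log_l[i]
                )
            if "H4K16ac" in det:
                det["H4K16ac"][chrom][orf] += -config.acetyl_length_slope * log_l[i]

            # promoter neighbourhood, strand-oriented
            if g.strand == "+":
                plo = np.searchsorted(pos, g.start - 3 * w)
                phi = np.searchsorted(pos, g.start)
            else:
                plo = np.searchsorted(pos, g.end)
                phi = np.searchsorted(pos, g.end + 3 * w)
            if phi <= plo:
                continue
            prom = slice(plo, phi)
            t = _promoter_offsets(g, pos[prom])
            if "H3" in det and config.promoter_dip_depth:
                dip = config.promoter_dip_depth * np.exp(
                    -((t - config.promoter_dip_center) ** 2)
                    / (2 * config.promoter_dip_sigma**2)
                )
                det["H3"][chrom][prom] -= dip
            in_window = (t >= -w) & (t < 0)
            if np.any(in_window):
                sel = np.flatnonzero(in_window) + plo
                if "H3K18ac" in det and k18_prom[i]:
                    prom_extra["H3K18ac"][chrom][sel] += k18_prom[i]
                if "Gcn5" in det and gcn5_prom[i]:
                    prom_extra["Gcn5"][chrom][sel] += gcn5_prom[i]
                if "H3" in det and h3_prom[i]:
                    prom_extra["H3"][chrom][sel] += h3_prom[i]

    # per-(species, condition, chromosome) noise, drawn in fixed order
    noise: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for species in config.species:
        sigma = config.noise_sigma.get(species, 0.0)
        for cond in config.conditions:
            noise[(species, cond)] = {
                chrom: (
                    rng.normal(0.0, sigma, size=probe_pos[chrom].size)
                    if sigma
                    else np.zeros(probe_pos[chrom].size)
                )
                for chrom in chroms
            }

    long_scale = 1.0
    if "Gcn5" in det and any(np.any(reloc_long[c]) for c in chroms):
        cat = lambda d: np.concatenate([d[c] for c in chroms])
        base = cat(det["Gcn5"])
        fixed_b = base + cat(noise[("Gcn5", "B")]) + cat(reloc_short) + cat(
            prom_extra["Gcn5"]
        )
        long_unit = cat(reloc_long)
        target = float(np.median(base + cat(noise[("Gcn5", "A")])))
        lo_c, hi_c = 0.0, 10.0
        for _ in range(60):
            mid_c = (lo_c + hi_c) / 2
            if np.median(fixed_b + mid_c * long_unit) < target:
                lo_c = mid_c
            else:
                hi_c = mid_c
        long_scale = (lo_c + hi_c) / 2

    extra_b: dict[str, dict[str, np.ndarray]] = {s: zeros() for s in config.species}
    for chrom in chroms:
        if "Gcn5" in det:
            extra_b["Gcn5"][chrom] = (
                reloc_short[chrom]
                + long_scale * reloc_long[chrom]
                + prom_extra["Gcn5"][chrom]
            )
        if "H3K18ac" in det:
            coupled = (
                config.k18_gcn5_coupling
                * (reloc_short[chrom] + long_scale * reloc_long[chrom])
                if "Gcn5" in det
                else 0.0
            )
            extra_b["H3K18ac"][chrom] = coupled + prom_extra["H3K18ac"][chrom]
        if "H3" in det:
            extra_b["H3"][chrom] = prom_extra["H3"][chrom]

    if "H3K18ac" in det and "Gcn5" in det:
        for chrom in chroms:
            det["H3K18ac"][chrom] += config.k18_gcn5_coupling * det["Gcn5"][chrom]

    tracksets: dict[str, TrackSet] = {}
    for species in config.species:
        ts = TrackSet(species)
        for cond in config.conditions:
            track = SignalTrack(species, cond)
            for chrom in chroms:
                signal = det[species][chrom] + noise[(species, cond)][chrom]
                if cond == "B":
                    signal = signal + extra_b[species][chrom]
                track.data[chrom] = (probe_pos[chrom], signal)
            ts.tracks[cond] = track
        tracksets[species] = ts
    return tracksets, long_scale


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Emit the dataset as GFF3 + chrom sizes + bedGraph + TSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["annotation"] = outdir / "genes.gff3"
    write_annotations(ds.genes, paths["annotation"])
    paths["chrom_sizes"] = outdir / "chrom.sizes"
    with open(paths["chrom_sizes"], "w") as fh:
        for chrom, size in ds.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    trackdir = outdir / "tracks"
    trackdir.mkdir(exist_ok=True)
    for species, ts in ds.tracksets.items():
        for cond, track in ts.tracks.items():
            p = trackdir / f"{species}_{cond}.bedgraph"
            write_track(track, p, probe_width=ds.config.probe_spacing_bp)
            paths[f"track:{species}:{cond}"] = p
    paths["expression"] = outdir / "expression.tsv"
    ds.expression.to_tsv(paths["expression"])
    paths["truth"] = outdir / "ground_truth.tsv"
    ds.truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["config"] = outdir / "config.yaml"
    ds.config.to_yaml(paths["config"])
    return paths


def load_dataset(outdir: str | Path) -> SimulatedDataset:
    """Re-read an emitted dataset through the pipeline's own readers."""
    outdir = Path(outdir)
    config = SimulationConfig.from_yaml(outdir / "config.yaml")
    genes = read_annotations(outdir / "genes.gff3", dialect="gff3")
    chrom_sizes = read_chrom_sizes(outdir / "chrom.sizes")
    tracksets: dict[str, TrackSet] = {}
    for species in config.species:
        ts = TrackSet(species)
        for cond in config.conditions:
            p = outdir / "tracks" / f"{species}_{cond}.bedgraph"
            track = read_track(p, dialect="bedgraph")
            track.species, track.condition = species, cond
            ts.tracks[cond] = track
        tracksets[species] = ts
    expression = read_expression(outdir / "expression.tsv")
    truth = pd.read_csv(outdir / "ground_truth.tsv", sep="\t").set_index(
        "gene_id", drop=False
    )
    return SimulatedDataset(config, genes, chrom_sizes, tracksets, expression, truth)
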