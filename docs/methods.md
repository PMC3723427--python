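# Methods

`stresschip` implements a genome-wide analysis of chromatin occupancy and
gene expression across a five-point stress-adaptation time course in budding
yeast: A (exponential growth), B (1 h after salt stress), C (adapted to
stress), D (1 h after stress removal), E (fully recovered).  Four ChIP
species are modelled — the Gcn5 histone acetyltransferase, the acetylation
marks H3K18ac and H4K16ac, and total histone H3 as a nucleosome-density
reference — each as a probe-resolution log2 signal track per condition,
together with a genes × conditions log2 expression matrix.

## Coordinates and average-gene profiling

All internal coordinates are 0-based half-open; GFF3 (1-based inclusive) and
BED are converted at the file boundary.  Each gene's neighbourhood is split
into a 5′ intergenic region (from the midpoint of the upstream gap to the
base before the start codon), the ORF, and a 3′ intergenic region (from the
base after the stop codon to the downstream gap midpoint).  Neighbours are
the nearest ORFs on either strand; chromosome ends stand in for missing
neighbours, and overlapping or book-ended ORFs yield empty flanks.  Integer
midpoints floor, so strand-reflection symmetry of the flanks is exact up to
one base on odd-width gaps.

The average-gene profile bins each segment into a fixed number of
equal-measure bins — 9 per IGR and 20 per ORF by default — using real-valued
bin edges (bin *k* of a length-*L* segment covers
`[start + kL/n, start + (k+1)L/n)`); this guarantees exactly *n* bins for
any segment length at the cost of the same one-base flooring caveat when
probes sit on fractional edges.  A bin with no probes is missing, never
zero, and group averages are unweighted per-gene means over non-missing
bins.  Per-gene scalar summaries use the central 40 % of the ORF
(`[start + 0.3 L, start + 0.7 L)`), which keeps intergenic signal out of the
ORF statistic; the probe values inside the window are retained as the
observational unit for testing.

## Normalisation

Tracks of one species are equalised across conditions by shifting each track
additively (they are log-scale) so every per-track median equals the grand
median of the input medians; a multiplicative mode exists for linear inputs.
Histone-density correction divides a factor or mark profile by the matching
H3 profile — log-difference by default, ratio for linearised data.  Because
a vanishing H3 denominator makes the ratio meaningless, the policy object
carries a floor (default: the 1st percentile of genome-wide H3 in ratio
mode) below which bins become missing (or are clamped, by choice).  The
pipeline averages profiles per cluster and condition first and then
normalises the averages; per-gene normalisation is available and the two
orders genuinely differ, which a test pins down.

## Statistics

* **Per-gene change across conditions**: Kruskal–Wallis on the central-ORF
  probe values, one group per condition, chi-squared p with k−1 df; an exact
  permutation p (full enumeration of group assignments) is available for
  total n ≤ 12.  Genes with p < 0.05 (uncorrected, matching the analysis
  convention; Benjamini–Hochberg by flag) form the changed set.  Probes are
  the only replicated measurement once culture replicates are merged, which
  is why they serve as the test unit; a bin-level alternative would behave
  similarly but with coarser granularity.
* **Length-group condition pair test**: paired two-sided Wilcoxon
  signed-rank on per-gene central-ORF values (Welch's t by flag), per
  gene-length group (<1 kb, 1–2 kb, 2–3 kb, >3 kb; half-open boundaries).
* **Set overlaps**: one-sided hypergeometric upper tail, with the universe
  defined as all profiled genes (a conservative choice; the alternative —
  all annotated genes — would only inflate significance).
* **Correlations**: Spearman with average ranks on ties; two-sided
  t-approximation p, exact permutation p for n ≤ 8.
* **Expression**: log2 fold changes against condition A; a gene is regulated
  when |FC| strictly exceeds 1.8-fold in at least one of B–E; Euclidean
  k-means (k = 3, best of 20 restarts) on the B–E FC vectors, clusters
  relabelled by descending mean FC in B so labels are seed-stable; condition
  dendrogram by average-linkage clustering of 1 − Pearson distances over the
  regulated genes, serialised as Newick.
* **Promoters**: fixed 25 bp bins over [−500, +100) bp around the start
  codon, strand-oriented.  The promoter peak is the maximal H3-normalised
  bin wholly upstream of the ATG, ties resolved toward the ATG; a
  fixed-window upstream mean is exported alongside since "peak level" admits
  either reading.  Peak-level B−A deltas feed the regulation correlations,
  split into all/up-/down-regulated genes.

## The synthetic genome

The generator emulates the statistical structure the analysis assumes, with
recorded ground truth.  Defaults (one number per effect, log2 units):

| parameter | default | meaning |
| --- | --- | --- |
| n_genes / chromosomes | 3000 / 4 | yeast-scale desk run |
| ORF length | log-normal, median 1.4 kb, σ=0.7 | realistic spread: ~1/3 of genes <1 kb, ~1/7 >3 kb |
| intergenic gap | log-normal, median 400 bp, min 150 | keeps flanks non-empty |
| probe spacing | 5 bp | tiling-array resolution |
| probe noise σ | 0.3 per species | log-scale Gaussian |
| Gcn5 ORF level / length slope | 0.5 / −0.3·log2(L/1.4 kb) | occupancy decreasing with length |
| H3 ORF level / length slope | 0.3 / +0.2 | histone density rising with length |
| acetyl length slope | −0.25 | both marks decline with length |
| B-only relocalisation | −0.5 on <1 kb ORFs; up on >3 kb ORFs, magnitude solved at run time | see below |
| promoter H3 dip | depth 1.0, centre −100 bp, σ 60 bp | nucleosome-depleted region |
| H3K18ac coupling | 0.8 × Gcn5 signal | correlated mark |
| expression clusters | 5 %, 5 %, 4 % of genes | up-in-B (FC +2), down-in-B (−2), up-in-B-and-D (+1.5/+1.5) with per-gene log-normal amplitude (σ 0.25); small residuals in C (+0.5/−0.5/+0.4) reflect the adapted state |
| promoter coupling in B | K18 +0.4·FC (all regulated), Gcn5 +0.4·FC (up only), H3 −0.2·FC | histone eviction on activation |

Cluster membership is assigned uniformly at random, so fold change is
independent of gene length by construction (the null the scatter analysis
should report).

The B-condition relocalisation is a **redistribution, not a net gain**: the
long-gene shift is rescaled by bisection until track B's genome-wide median
(noise included) equals track A's.  Without this the cross-sample median
equalisation would convert the net planted signal into a spurious uniform
offset on every untouched gene — at a thousand genes per length group the
Wilcoxon test detects offsets of a few thousandths of a log2 unit, so median
neutrality is part of the planted condition, and the effective long-gene
shift is recorded in the ground truth (≈ +0.12 under defaults, against
−0.5 on short genes; long ORFs carry several times the probe mass of short
ones).

What the generator does **not** emulate: probe-level cross-hybridisation and
GC effects, replicate cultures (tracks are pre-merged by construction),
sequence content, overlapping transcription, and condition-dependent
nucleosome positioning beyond the planted promoter moves.  Recovery results
on this genome therefore demonstrate that the pipeline's statistics respond
to the planted structure at realistic noise and scale — not that real
tiling-array data are this well behaved.

One consequence worth knowing: the H3-normalised promoter delta of the
*uncoupled* mark H4K16ac still correlates with regulation, because the
denominator (H3) moves with regulation while the mark does not.  This is the
histone-density phenomenon the normalisation exists to expose, and it is the
reason raw and normalised profiles are always reported side by side.

## Numerical and design choices

* Probe membership is by point position (bedGraph intervals collapse to
  their floored midpoint), not footprint overlap.
* Median equalisation is per species across conditions (global equalisation
  across species would mix scales that are never compared directly).
* Kruskal–Wallis with all observations identical returns H = 0, p = 1;
  Wilcoxon with all-zero differences returns p = 1; length groups with fewer
  than 5 genes report a missing p with a warning.
* Exact tests: permutation p-values count the observed statistic within a
  1e-12 tolerance to absorb rank-arithmetic round-off.
* Cluster relabelling by descending mean FC in B means the down-regulated
  cluster carries the last label; tests match clusters to planted truth by
  trajectory (assignment matching), never by label index.
* The length-group recovery check treats the untouched 1–2 kb group as
  clean when p > 0.01: under the planted null that p is uniform, and 0.01
  keeps the single-run check's false-alarm rate at 1 %.
* Stage caching in the pipeline is keyed on a hash of the analysis
  parameters plus all input bytes; the output directory and log level do not
  participate, so the same inputs give the same run key anywhere.
* Problem sizes used by the shipped checks — 3000-gene default genome,
  5000-gene null genome, 20 expression-only null replicates — are desk-scale
  choices that keep a full recovery run around a minute while leaving every
  length group and cluster with hundreds of members.

## Known limitations

* Yeast ORF-centric annotation only: no introns, UTRs or overlapping
  transcript disambiguation; dubious ORF filtering is left to a caller-side
  filter on the annotation list.
* The per-gene test treats probes within the central window as exchangeable
  replicates; spatial autocorrelation along the ORF would make the test
  anti-conservative on real data.
* Promoter windows are anchored at the annotated start codon, not a mapped
  TSS; the defaults ([−500, +100), 25 bp) are conventions, not measurements.
* The hypergeometric universe excludes genes dropped during profiling; with
  non-random dropout the enrichment p-values remain conservative but the
  fold enrichments shift.
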