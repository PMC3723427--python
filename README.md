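# stresschip

Strand-aware "average gene" analysis of ChIP occupancy and gene expression
across a stress-adaptation time course in budding yeast.

During adaptation to an osmotic stress, the Gcn5 histone acetyltransferase
transiently redistributes across the genome: it leaves the ORFs of short
genes and accumulates on the ORFs of long genes, while at promoters its
histone-relative level tracks the activation or repression of individual
genes.  Detecting these effects in tiling-array ChIP data requires a
specific chain of operations — cross-sample median normalisation, binned
metagene profiles oriented by transcription, histone-H3-relative correction
of factor and acetylation signal, non-parametric per-gene testing across
conditions, overlap and enrichment statistics, and expression clustering.
`stresschip` packages that chain for epigenomics analysts, together with a
synthetic-genome generator that plants every effect with known ground truth
so the whole pipeline is testable end to end.

## The analysis in brief

For each gene with ORF `[start, end)` the signal is summarised as a
38-bin profile in transcription order: 9 bins over the 5′ intergenic
half-region, 20 over the ORF, 9 over the 3′ half-region, where bin *k* of a
length-*L* segment covers `[start + kL/n, start + (k+1)L/n)` and each bin
holds the mean probe signal (missing when empty).  Per-gene change across
the five conditions A–E is tested by Kruskal–Wallis on the probe values in
the central 40 % of the ORF,

&nbsp;&nbsp;&nbsp;&nbsp;H = 12/(N(N+1)) · Σᵢ nᵢ (r̄ᵢ − r̄)² / tie-correction,&nbsp;&nbsp;p from χ²(k−1),

and genes with p < 0.05 form per-species changed sets whose intersections
are scored with the one-sided hypergeometric tail
P[X ≥ |A∩B|], X ~ Hypergeom(N, |A|, |B|).  Expression fold changes (log2,
versus condition A) define regulated genes (|FC| > log2 1.8 somewhere in
B–E), k-means (k = 3) trajectory clusters, and a condition dendrogram
(average linkage on 1 − Pearson).  Promoter profiles are 25 bp bins over
[−500, +100) bp around the ATG; H3-relative levels (log-difference or
ratio with a denominator floor) expose promoter peaks whose B−A change is
correlated (Spearman) with the direction and size of gene regulation.

## Worked example

Generate a 400-gene synthetic genome with planted effects and run every
stage:

```sh
stresschip simulate --n-genes 400 --seed 5 --out demo/data
stresschip run-all --data demo/data --out demo/results
```

`demo/results/lengthgroup_AB_test.tsv` holds the paired Wilcoxon test of
central-ORF Gcn5 between the pre-stress sample A and the adapting sample B,
per gene-length group:

```
group    n    statistic  p
1kb-2kb  156  5520.0     0.286000437845808
2kb-3kb  61   814.0      0.3448963248348048
<1kb     133  0.0        1.4317759392997278e-23
>3kb     50   0.0        1.7763568394002505e-15
```

— the planted relocalisation is detected on short and long genes and absent
on the untouched middle groups.  `overlaps.tsv` shows the changed-set
structure:

```
set_a  set_b    n_a  n_b  intersection  universe  overlap_p     ...  short_gene_p
Gcn5   H3K18ac  193  191  182           400       6.100194e-87  ...  3.377925e-62
Gcn5   H4K16ac  193  21   11            400       4.338464e-01  ...  3.603531e-02
```

— the Gcn5-coupled mark H3K18ac shares essentially the whole changed set
(hypergeometric p ≈ 6e-87) and the intersection is strongly enriched for
sub-kilobase genes, while the uncoupled H4K16ac changed set stays at the
false-positive level with no significant overlap.  The condition dendrogram
(`sample_dendrogram.nwk`)

```
(B:0.44,(D:0.23,(C:0.15,(A:0.027,E:0.027):0.12):0.082):0.22);
```

isolates the stress-adaptation sample B first and pairs the two steady-state
samples A and E, and `expression_stats.json` reports 56 regulated genes with
no fold-change–versus–length correlation (rs = −0.05, p = 0.31).

Each stage is also available as its own subcommand (`profile`, `detect`,
`overlap`, `express`, `promoter`) and as plain library functions
(`stresschip.analysis`) for in-memory use.  Re-running `run-all` with
unchanged inputs and parameters is a cache hit recorded in
`results/manifest.json`.

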