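"""Gene annotations, intergenic flank derivation and gene-length groups.

Coordinates are 0-based half-open everywhere inside the package; the GFF3
reader converts from 1-based inclusive at the file boundary.  A gene here is
a yeast-style ORF: a single interval from start codon to stop codon on one
strand, no introns or UTRs.

The 5'IGR of a gene runs from the midpoint of the upstream intergenic gap to
the base preceding the start codon; the 3'IGR runs from the base after the
stop codon to the midpoint of the downstream gap.  "Upstream" and
"downstream" follow transcription, so for a minus-strand gene the 5'IGR lies
genomically to the right of the ORF.  Neighbours for the gap computation are
the nearest ORFs on *either* strand.  A gene at a chromosome end uses the
chromosome boundary as the far gap edge; overlapping or book-ended ORFs
(gap <= 0) get an empty flank on that side.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GeneAnnotation",
    "FlankRegions",
    "AnnotationError",
    "read_annotations",
    "read_chrom_sizes",
    "write_annotations",
    "derive_flanks",
    "assign_length_groups",
    "length_group_labels",
]

_STRANDS = {"+", "-"}


class AnnotationError(ValueError):
    """Raised on malformed annotation input (carries the offending line number)."""


@dataclass(frozen=True)
class GeneAnnotation:
    """One ORF: ``[start, end)`` on ``chrom``, transcribed on ``strand``."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise AnnotationError(
                f"{self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in _STRANDS:
            raise AnnotationError(f"{self.gene_id}: unknown strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def atg(self) -> int:
        """Genomic position of the first transcribed base (the A of ATG)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class FlankRegions:
    """5'/3' intergenic half-regions of one gene, as genomic intervals or None."""

    gene_id: str
    igr5: tuple[int, int] | None
    igr3: tuple[int, int] | None


def read_annotations(
    path: str | Path,
    dialect: str = "gff3",
    feature_type: str = "gene",
) -> list[GeneAnnotation]:
    """Read gene annotations from GFF3 (1-based inclusive) or BED6 (0-based).

    Parameters
    ----------
    dialect:
        ``"gff3"`` or ``"bed"``.
    feature_type:
        GFF3 only: keep records whose third column equals this value.

    Raises
    ------
    AnnotationError
        On malformed lines (with line number), unknown strand symbols, or
        duplicated gene identifiers.
    """
    dialect = dialect.lower()
    if dialect not in {"gff3", "bed"}:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "gff3":
                    if len(fields) < 9:
                        raise ValueError("expected 9 tab-separated columns")
                    if fields[2] != feature_type:
                        continue
                    chrom = fields[0]
                    start = int(fields[3]) - 1  # 1-based inclusive -> 0-based
                    end = int(fields[4])
                    strand = fields[6]
                    gene_id = _gff3_id(fields[8])
                else:
                    if len(fields) < 6:
                        raise ValueError("expected >= 6 BED columns")
                    chrom = fields[0]
                    start = int(fields[1])
                    end = int(fields[2])
                    gene_id = fields[3]
                    strand = fields[5]
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            if strand not in _STRANDS:
                raise AnnotationError(f"{path}:{lineno}: unknown strand {strand!r}")
            if gene_id in seen:
                raise AnnotationError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            try:
                genes.append(GeneAnnotation(gene_id, chrom, start, end, strand))
            except AnnotationError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
    return genes


def _gff3_id(attributes: str) -> str:
    for part in attributes.split(";"):
        part = part.strip()
        if part.startswith("ID="):
            return part[3:]
        if part.startswith("Name=") :
            name = part[5:]
    try:
        return name
    except UnboundLocalError:
        raise ValueError(f"no ID= or Name= attribute in {attributes!r}") from None


def write_annotations(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    """Write genes as GFF3 ``gene`` features (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tstresschip\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV ``chrom<TAB>size`` -> dict."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise AnnotationError(f"{path}:{lineno}: expected 2 columns")
            sizes[fields[0]] = int(fields[1])
    return sizes


def derive_flanks(
    genes: Sequence[GeneAnnotation],
    chrom_sizes: Mapping[str, int],
) -> dict[str, FlankRegions]:
    """Split each intergenic gap at its midpoint between the two adjacent ORFs.

    Each gene receives, on each genomic side, the half of the gap adjacent to
    itself; strand then decides which half is the 5'IGR and which the 3'IGR.
    Gaps of zero or negative width (book-ended or overlapping ORFs) yield an
    empty flank.
    """
    for g in genes:
        if g.chrom not in chrom_sizes:
            raise AnnotationError(f"{g.gene_id}: chromosome {g.chrom!r} has no size")
        if g.end > chrom_sizes[g.chrom]:
            raise AnnotationError(
                f"{g.gene_id}: extends beyond {g.chrom} size {chrom_sizes[g.chrom]}"
            )
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out: dict[str, FlankRegions] = {}
    for chrom, glist in by_chrom.items():
        glist = sorted(glist, key=lambda g: (g.start, g.end))
        n = len(glist)
        # nearest occupied edge on each side, strand-agnostic, overlap-safe
        left_edge = [0] * n
        running = 0
        for i, g in enumerate(glist):
            left_edge[i] = running
            running = max(running, g.end)
        right_edge = [chrom_sizes[chrom]] * n
        running = chrom_sizes[chrom]
        for i in range(n - 1, -1, -1):
            right_edge[i] = running
            running = min(running, glist[i].start)
        for i, g in enumerate(glist):
            left = _gap_half(left_edge[i], g.start, keep="right")
            right = _gap_half(g.end, right_edge[i], keep="left")
            if g.strand == "+":
                igr5, igr3 = left, right
            else:
                igr5, igr3 = right, left
            out[g.gene_id] = FlankRegions(g.gene_id, igr5, igr3)
    return out


def _gap_half(a: int, b: int, keep: str) -> tuple[int, int] | None:
    if b <= a:
        return None
    mid = (a + b) // 2
    interval = (mid, b) if keep == "right" else (a, mid)
    return interval if interval[0] < interval[1] else None


def length_group_labels(boundaries: Sequence[int]) -> list[str]:
    """Human-readable labels for the half-open length bins, e.g. ``1-2kb``."""
    if not boundaries:
        return ["all"]
    labels = [f"<{_kb(boundaries[0])}"]
    for lo, hi in zip(boundaries[:-1], boundaries[1:]):
        labels.append(f"{_kb(lo)}-{_kb(hi)}")
    labels.append(f">{_kb(boundaries[-1])}")
    return labels


def _kb(bp: int) -> str:
    return f"{bp / 1000:g}kb"


def assign_length_groups(
    genes: Iterable[GeneAnnotation],
    boundaries: Sequence[int] = (1000, 2000, 3000),
) -> dict[str, str]:
    """Map gene_id -> length-group label.

    Bins are half-open: a gene of length L lands in group i with
    ``boundaries[i-1] <= L < boundaries[i]``; L below the first boundary goes
    to the first group, L at or above the last to the last.  An empty
    boundary list puts every gene in a single ``"all"`` group.
    """
    boundaries = list(boundaries)
    if any(b <= a for a, b in zip(boundaries, boundaries[1:])):
        raise ValueError("length-group boundaries must be strictly increasing")
    labels = length_group_labels(boundaries)
    out: dict[str, str] = {}
    for g in genes:
        i = sum(g.length >= b for b in boundaries)
        out[g.gene_id] = labels[i]
    return out
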