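"""Transcript and gene models plus the overlap algebra the filters build on.

A :class:`TranscriptModel` is an exon-structured, stranded transcript; a
:class:`GeneModel` groups isoforms under one gene id with a biotype.  The
module also provides the comparisons used throughout the discovery
cascade: exonic overlap length, exonic Jaccard similarity (the isoform
de-redundancy statistic) and nearest-neighbour search between genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .intervals import (
    GenomicInterval,
    gaps_between,
    intersect_length,
    merge_intervals,
    total_length,
    union_length,
)

BIOTYPES = ("protein_coding", "lncRNA_annotated", "lncRNA_novel", "other")


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    provenance: str = "assembled"  # or "reference"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript must have >= 1 exon")
        exs = sorted(self.exons, key=lambda e: e.start)
        for e in exs:
            if e.chrom != self.chrom:
                raise ValueError(f"{self.transcript_id}: exon chrom mismatch")
        for a, b in zip(exs, exs[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        if self.strand == "." and len(exs) > 1:
            raise ValueError(
                f"{self.transcript_id}: unstranded transcripts must be monoexonic"
            )
        self.exons = [
            GenomicInterval(self.chrom, e.start, e.end, self.strand) for e in exs
        ]

    # -- derived geometry ------------------------------------------------
    @property
    def exon_pairs(self) -> list[tuple[int, int]]:
        return [(e.start, e.end) for e in self.exons]

    @property
    def length(self) -> int:
        """Mature transcript length L (sum of exon lengths)."""
        return total_length(self.exon_pairs)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def tss(self) -> int:
        """Strand-aware 5' end (0-based position of the first transcribed base)."""
        return self.exons[0].start if self.strand != "-" else self.exons[-1].end - 1

    @property
    def tes(self) -> int:
        """Strand-aware 3' end."""
        return self.exons[-1].end - 1 if self.strand != "-" else self.exons[0].start

    @property
    def is_monoexonic(self) -> bool:
        return len(self.exons) == 1

    @property
    def introns(self) -> list[tuple[int, int]]:
        return gaps_between(self.exon_pairs)


@dataclass
class GeneModel:
    gene_id: str
    transcripts: list[TranscriptModel] = field(default_factory=list)
    biotype: str = "other"

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"{self.gene_id}: gene must have >= 1 transcript")
        chroms = {t.chrom for t in self.transcripts}
        if len(chroms) > 1:
            raise ValueError(f"{self.gene_id}: transcripts on multiple chroms")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"{self.gene_id}: unknown biotype {self.biotype!r}")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def span(self) -> GenomicInterval:
        start = min(t.span.start for t in self.transcripts)
        end = max(t.span.end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.longest_isoform().strand)

    def longest_isoform(self) -> TranscriptModel:
        return max(self.transcripts, key=lambda t: (t.length, t.transcript_id))


# -- overlap algebra -----------------------------------------------------


def exonic_overlap_length(
    a: TranscriptModel, b: TranscriptModel, stranded: bool = False
) -> int:
    """Bases shared between the exonic base sets of two transcripts.

    With ``stranded=True`` transcripts on different strands share nothing
    by definition ("overlapped by at least one nucleotide ... on the same
    orientation" is the stranded variant).
    """
    if a.chrom != b.chrom:
        return 0
    if stranded and a.strand != b.strand:
        return 0
    return intersect_length(a.exon_pairs, b.exon_pairs)


def jaccard_similarity(a: TranscriptModel, b: TranscriptModel) -> float:
    """Exonic-base Jaccard index |A∩B| / |A∪B| between two isoforms."""
    if a.chrom != b.chrom or a.strand != b.strand:
        return 0.0
    inter = intersect_length(a.exon_pairs, b.exon_pairs)
    union = union_length(a.exon_pairs, b.exon_pairs)
    return inter / union if union else 0.0


_NO_NEIGHBOR = (None, None)


def gene_distance(a: GeneModel, b: GeneModel) -> int:
    """Gap in bases between the spans of the longest isoforms (0 if overlapping)."""
    sa, sb = a.longest_isoform().span, b.longest_isoform().span
    return max(0, sb.start - sa.end, sa.start - sb.end)


def closest_gene(
    query: GeneModel,
    candidates: Iterable[GeneModel],
    allow_overlap: bool = True,
) -> tuple[GeneModel | None, int | None]:
    """Nearest gene by longest-isoform span gap.

    Returns ``(gene, signed_distance)`` where distance is 0 for overlap,
    positive when the neighbour lies rightward of the query and negative
    leftward.  Ties break to the lower start coordinate, then gene id.
    Returns ``(None, None)`` when no candidate shares the chromosome.
    """
    qspan = query.longest_isoform().span
    best: tuple[int, int, str, GeneModel] | None = None
    for cand in candidates:
        if cand.chrom != query.chrom or cand.gene_id == query.gene_id:
            continue
        cspan = cand.longest_isoform().span
        gap = max(0, cspan.start - qspan.end, qspan.start - cspan.end)
        if gap == 0 and not allow_overlap and qspan.overlaps(cspan):
            continue
        key = (gap, cspan.start, cand.gene_id)
        if best is None or key < (best[0], best[1], best[2]):
            best = (gap, cspan.start, cand.gene_id, cand)
    if best is None:
        return _NO_NEIGHBOR
    gap, cstart, _, gene = best
    sign = -1 if gene.longest_isoform().span.end <= qspan.start else 1
    return gene, sign * gap if gap else 0


def longest_isoforms(genes: Sequence[GeneModel]) -> dict[str, TranscriptModel]:
    return {g.gene_id: g.longest_isoform() for g in genes}


def masked_fraction(
    t: TranscriptModel, mask: Sequence[GenomicInterval]
) -> float:
    """Fraction of exonic bases covered by a (repeat/low-complexity) mask."""
    mask_pairs = merge_intervals(
        [(m.start, m.end) for m in mask if m.chrom == t.chrom]
    )
    if not mask_pairs:
        return 0.0
    return intersect_length(t.exon_pairs, mask_pairs) / t.length
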