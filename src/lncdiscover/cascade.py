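"""The high-quality lncRNA discovery cascade and CAGE-based TSS refinement.

Candidate transcript models pass through an ordered series of filters:

1. same-strand exonic overlap with annotated exons (gene-level drop)
2. exons fully contained in same-strand annotated introns, unless the
   gene also overlaps an annotated antisense exon (pre-mRNA guard)
3. monoexonic rules: unstranded removal, sense-ratio >= 0.8 in at least
   one sample, minimum length 500 nt
4. blacklist chromosomes and minimum mature length 200 nt
5. minimum expression (FPKM >= 2 in at least one non-nuclear condition)
6. repeat/low-complexity coverage (> 90% masked removed)
7. isoform de-redundancy (exonic Jaccard > 0.95 removes the shorter)
8. nuclear/non-nuclear log2 ratio > 1 for intron-embedded monoexonics
9. read-through flagging (flag-only by default)
10. DE partition into the "main" and "constitutive" sets

Every stage reports input/retained/removed with per-id reason codes, and
counts conserve (retained + removed = input) at each stage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .expression import DETable, ExpressionTable
from .intervals import GenomicInterval, intersect_length, merge_intervals
from .models import GeneModel, TranscriptModel, jaccard_similarity, masked_fraction
from .simulate import NON_NUCLEAR_CONDITIONS, NUCLEAR_CONDITIONS

logger = logging.getLogger(__name__)

DEFAULT_BLACKLIST = ("U", "Uextra", "M", "chrM", "dmel_mitochondrion_genome")

#: matched (nuclear, non-nuclear) condition pairs for the log2-ratio filter
NUCLEAR_PAIRS = (("Meso_34_Nuc", "Meso_34"), ("Meso_68_Nuc", "Meso_68"))


@dataclass
class StageResult:
    name: str
    n_input: int
    retained: list[str]
    removed: dict[str, str]  # transcript id -> reason code

    def __post_init__(self) -> None:
        if len(self.retained) + len(self.removed) != self.n_input:
            raise AssertionError(
                f"{self.name}: retained + removed != input "
                f"({len(self.retained)} + {len(self.removed)} != {self.n_input})"
            )


@dataclass
class CascadeReport:
    stages: list[StageResult] = field(default_factory=list)

    def add(self, stage: StageResult) -> None:
        self.stages.append(stage)
        logger.info(
            "stage %-20s in=%4d kept=%4d removed=%4d",
            stage.name, stage.n_input, len(stage.retained), len(stage.removed),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (s.name, s.n_input, len(s.retained), len(s.removed))
                for s in self.stages
            ],
            columns=["stage", "n_input", "n_retained", "n_removed"],
        )

    def removed_frame(self) -> pd.DataFrame:
        rows = [
            (s.name, tid, reason)
            for s in self.stages
            for tid, reason in sorted(s.removed.items())
        ]
        return pd.DataFrame(rows, columns=["stage", "transcript_id", "reason"])


# -- helpers ---------------------------------------------------------------


def _all_transcripts(genes: Sequence[GeneModel]) -> list[TranscriptModel]:
    return [t for g in genes for t in g.transcripts]


def _regroup(
    genes: Sequence[GeneModel], keep_tids: set[str]
) -> list[GeneModel]:
    """Drop removed transcripts; genes with no surviving transcript vanish."""
    out = []
    for g in genes:
        kept = [t for t in g.transcripts if t.transcript_id in keep_tids]
        if kept:
            out.append(GeneModel(g.gene_id, kept, biotype=g.biotype))
    return out


class _ExonIndex:
    """Per-(chrom, strand) merged exon and intron intervals of a gene set."""

    def __init__(self, genes: Sequence[GeneModel]):
        ex: dict[tuple[str, str], list[tuple[int, int]]] = {}
        intr: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for g in genes:
            for t in g.transcripts:
                key = (t.chrom, t.strand)
                ex.setdefault(key, []).extend(t.exon_pairs)
                intr.setdefault(key, []).extend(t.introns)
        self.exons = {k: merge_intervals(v) for k, v in ex.items()}
        self.introns = {k: sorted(v) for k, v in intr.items()}

    def exon_overlap(self, t: TranscriptModel, same_strand: bool) -> int:
        total = 0
        strands = [t.strand] if same_strand else [s for s in "+-" if s != t.strand]
        if not same_strand and t.strand == ".":
            strands = ["+", "-"]
        for s in strands:
            pairs = self.exons.get((t.chrom, s), [])
            total += intersect_length(t.exon_pairs, pairs)
        return total

    def fully_intronic(self, t: TranscriptModel) -> bool:
        """Every exon fully contained in a same-strand annotated intron."""
        introns = self.introns.get((t.chrom, t.strand), [])
        if not introns:
            return False
        return all(
            any(i_s <= s and e <= i_e for i_s, i_e in introns)
            for s, e in t.exon_pairs
        )


# -- individual filters ----------------------------------------------------


def filter_annotated_overlap(
    candidates: list[GeneModel], reference: Sequence[GeneModel]
) -> tuple[list[GeneModel], StageResult]:
    """Drop genes with >= 1 nt same-strand exonic overlap to annotated exons."""
    idx = _ExonIndex(reference)
    txs = _all_transcripts(candidates)
    bad_genes = {
        t.gene_id for t in txs
        if t.strand != "." and idx.exon_overlap(t, same_strand=True) >= 1
    }
    retained, removed = [], {}
    for t in txs:
        if t.gene_id in bad_genes:
            removed[t.transcript_id] = "annotated_same_strand_overlap"
        else:
            retained.append(t.transcript_id)
    stage = StageResult("annotated_overlap", len(txs), retained, removed)
    return _regroup(candidates, set(retained)), stage


def filter_intronic(
    candidates: list[GeneModel], reference: Sequence[GeneModel]
) -> tuple[list[GeneModel], StageResult]:
    """Drop genes whose exons all sit in same-strand annotated introns,
    unless the gene also overlaps an annotated antisense exon."""
    idx = _ExonIndex(reference)
    txs = _all_transcripts(candidates)
    bad_genes = set()
    for g in candidates:
        all_intronic = all(idx.fully_intronic(t) for t in g.transcripts)
        if not all_intronic:
            continue
        antisense = any(
            idx.exon_overlap(t, same_strand=False) >= 1 for t in g.transcripts
        )
        if not antisense:
            bad_genes.add(g.gene_id)
    retained, removed = [], {}
    for t in txs:
        if t.gene_id in bad_genes:
            removed[t.transcript_id] = "intron_embedded_sense"
        else:
            retained.append(t.transcript_id)
    stage = StageResult("intronic", len(txs), retained, removed)
    return _regroup(candidates, set(retained)), stage


def filter_monoexonic(
    candidates: list[GeneModel],
    strand_counts: pd.DataFrame,
    min_ratio: float = 0.8,
    min_length: int = 500,
    samples: Sequence[str] | None = None,
) -> tuple[list[GeneModel], StageResult]:
    """The three monoexonic rules, in order: unstranded removal,
    sense-ratio >= ``min_ratio`` in at least one sample, length >= ``min_length``.

    ``samples`` restricts which conditions count (default: the non-nuclear
    conditions present in the table).
    """
    sc = strand_counts
    if samples is not None:
        sc = sc[sc["condition"].isin(samples)]
    best_ratio: dict[str, float] = {}
    for tid, grp in sc.groupby("feature_id"):
        tot = grp["sense_reads"] + grp["antisense_reads"]
        ok = tot > 0
        if ok.any():
            best_ratio[tid] = float(
                (grp.loc[ok, "sense_reads"] / tot[ok]).max()
            )
    txs = _all_transcripts(candidates)
    retained, removed = [], {}
    for t in txs:
        if not t.is_monoexonic:
            retained.append(t.transcript_id)
            continue
        if t.strand == ".":
            removed[t.transcript_id] = "unstranded"
        elif t.transcript_id not in best_ratio:
            removed[t.transcript_id] = "no_strand_support"
        elif best_ratio[t.transcript_id] < min_ratio:
            removed[t.transcript_id] = "low_sense_ratio"
        elif t.length < min_length:
            removed[t.transcript_id] = "monoexonic_short"
        else:
            retained.append(t.transcript_id)
    stage = StageResult("monoexonic", len(txs), retained, removed)
    return _regroup(candidates, set(retained)), stage


def filter_basic(
    candidates: list[GeneModel],
    blacklist_chroms: Sequence[str] = DEFAULT_BLACKLIST,
    min_length: int = 200,
) -> tuple[list[GeneModel], StageResult]:
    txs = _all_transcripts(candidates)
    blacklist = set(blacklist_chroms)
    retained, removed = [], {}
    for t in txs:
        if t.chrom in blacklist:
            removed[t.transcript_id] = "blacklist_chrom"
        elif t.length < min_length:
            removed[t.transcript_id] = "too_short"
        else:
            retained.append(t.transcript_id)
    stage = StageResult("basic", len(txs), retained, removed)
    return _regroup(candidates, set(retained)), stage


def filter_expression(
    candidates: list[GeneModel],
    expr: ExpressionTable,
    min_fpkm: float = 2.0,
    conditions: Sequence[str] | None = None,
) -> tuple[list[GeneModel], StageResult]:
    """Keep genes with FPKM >= ``min_fpkm`` in at least one condition."""
    conds = [
        c
        for c in (conditions or NON_NUCLEAR_CONDITIONS)
        if c in expr.fpkm.columns
    ]
    sub = expr.fpkm[conds]
    txs = _all_transcripts(candidates)
    retained, removed = [], {}
    for t in txs:
        if t.gene_id not in sub.index:
            removed[t.transcript_id] = "no_expression_record"
        elif float(sub.loc[t.gene_id].max()) >= min_fpkm:
            retained.append(t.transcript_id)
        else:
            removed[t.transcript_id] = "low_expression"
    stage = StageResult("expression", len(txs), retained, removed)
    return _regroup(candidates, set(retained)), stage


def filter_repeats(
    candidates: list[GeneModel],
    mask: Sequence[GenomicInterval],
    max_fraction: float = 0.90,
) -> tuple[list[GeneModel], StageResult]:
    """Remove transcripts with masked exonic fraction strictly above 90%."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for m in mask:
        by_chrom.setdefault(m.chrom, []).append(m)
    txs = _all_transcripts(candidates)
    retained, removed = [], {}
    for t in txs:
        frac = masked_fraction(t, by_chrom.get(t.chrom, []))
        if frac > max_fraction:
            removed[t.transcript_id] = "repeat_masked"
        else:
            retained.append(t.transcript_id)
    stage = StageResult("repeats", len(txs), retained, removed)
    return _regroup(candidates, set(retained)), stage


def dedup_isoforms(
    candidates: list[GeneModel], min_similarity: float = 0.95
) -> tuple[list[GeneModel], StageResult]:
    """Within each gene, drop the shorter of any isoform pair whose exonic
    Jaccard similarity exceeds ``min_similarity`` (strictly)."""
    txs = _all_transcripts(candidates)
    retained, removed = [], {}
    for g in candidates:
        order = sorted(
            g.transcripts, key=lambda t: (-t.length, t.transcript_id)
        )
        kept: list[TranscriptModel] = []
        for t in order:
            if any(jaccard_similarity(t, k) > min_similarity for k in kept):
                removed[t.transcript_id] = "redundant_isoform"
            else:
                kept.append(t)
                retained.append(t.transcript_id)
    stage = StageResult("dedup_isoforms", len(txs), retained, removed)
    return _regroup(candidates, set(retained)), stage


def filter_nuclear_ratio(
    candidates: list[GeneModel],
    expr: ExpressionTable,
    reference: Sequence[GeneModel],
    max_log2: float = 1.0,
    epsilon: float = 0.1,
    pairs: Sequence[tuple[str, str]] = NUCLEAR_PAIRS,
) -> tuple[list[GeneModel], StageResult]:
    """Remove intron-embedded same-strand monoexonics whose nuclear /
    non-nuclear log2 FPKM ratio exceeds ``max_log2`` at either time point."""
    for nuc, whole in pairs:
        if nuc not in expr.fpkm.columns or whole not in expr.fpkm.columns:
            raise ValueError(f"expression table lacks nuclear pair {nuc}/{whole}")
    idx = _ExonIndex(reference)
    txs = _all_transcripts(candidates)
    retained, removed = [], {}
    for t in txs:
        qualifies = t.is_monoexonic and idx.fully_intronic(t)
        if qualifies and t.gene_id in expr.fpkm.index:
            hit = False
            for nuc, whole in pairs:
                num = float(expr.fpkm.loc[t.gene_id, nuc]) + epsilon
                den = float(expr.fpkm.loc[t.gene_id, whole]) + epsilon
                if math.log2(num / den) > max_log2:
                    hit = True
                    break
            if hit:
                removed[t.transcript_id] = "nuclear_enriched_premrna"
                continue
        retained.append(t.transcript_id)
    stage = StageResult("nuclear_ratio", len(txs), retained, removed)
    return _regroup(candidates, set(retained)), stage


def flag_readthrough(
    candidates: list[GeneModel],
    reference: Sequence[GeneModel],
    expr: ExpressionTable,
    max_gap: int = 500,
    min_pcg_fpkm: float = 1.0,
    auto_drop: bool = False,
) -> tuple[list[GeneModel], StageResult, set[str]]:
    """Flag candidates whose 5' end lies within ``max_gap`` nt downstream
    of the 3' end of an expressed same-strand protein-coding gene.

    Flag-only by default (the corresponding step was a manual curation);
    set ``auto_drop`` to remove flagged transcripts.
    """
    pcg_ends: dict[tuple[str, str], list[int]] = {}
    for g in reference:
        if g.biotype != "protein_coding":
            continue
        if g.gene_id in expr.fpkm.index:
            if float(expr.fpkm.loc[g.gene_id].max()) < min_pcg_fpkm:
                continue
        for t in g.transcripts:
            pcg_ends.setdefault((t.chrom, t.strand), []).append(t.tes)
    flagged: set[str] = set()
    txs = _all_transcripts(candidates)
    for t in txs:
        ends = pcg_ends.get((t.chrom, t.strand), [])
        tss = t.tss
        for tes in ends:
            gap = tss - tes if t.strand != "-" else tes - tss
            if 0 < gap <= max_gap:
                flagged.add(t.transcript_id)
                break
    retained, removed = [], {}
    for t in txs:
        if auto_drop and t.transcript_id in flagged:
            removed[t.transcript_id] = "readthrough"
        else:
            retained.append(t.transcript_id)
    stage = StageResult("readthrough", len(txs), retained, removed)
    return _regroup(candidates, set(retained)), stage, flagged


def partition_by_de(
    candidates: list[GeneModel],
    de: DETable,
    reference: Sequence[GeneModel],
    alpha: float = 0.01,
    min_fpkm_const: float = 3.0,
    expr: ExpressionTable | None = None,
) -> tuple[list[GeneModel], list[GeneModel], StageResult]:
    """Split surviving genes into the DE "main" set and the "constitutive"
    set (max FPKM >= 3, not same-strand intron-embedded); the rest drop."""
    sig = de.significant_genes(alpha)
    idx = _ExonIndex(reference)
    txs = _all_transcripts(candidates)
    retained, removed = [], {}
    main, const = [], []
    for g in candidates:
        if g.gene_id in sig:
            main.append(g)
            retained.extend(t.transcript_id for t in g.transcripts)
            continue
        max_fpkm = (
            float(expr.fpkm.loc[g.gene_id].max())
            if expr is not None and g.gene_id in expr.fpkm.index
            else 0.0
        )
        if max_fpkm < min_fpkm_const:
            for t in g.transcripts:
                removed[t.transcript_id] = "not_de_low_fpkm"
            continue
        kept_tx = []
        for t in g.transcripts:
            if idx.fully_intronic(t):
                removed[t.transcript_id] = "constitutive_intronic"
            else:
                kept_tx.append(t)
                retained.append(t.transcript_id)
        if kept_tx:
            const.append(GeneModel(g.gene_id, kept_tx, biotype=g.biotype))
    stage = StageResult("de_partition", len(txs), retained, removed)
    return main, const, stage


# -- TSS refinement --------------------------------------------------------


@dataclass
class TssRefinementRecord:
    transcript_id: str
    original_tss: int
    new_tss: int
    direction: str  # "clipped" | "extended" | "unchanged"
    nt_moved: int


def refine_tss(
    transcript: TranscriptModel,
    cage: pd.DataFrame,
    min_tags: int = 50,
    max_upstream: int = 800,
    max_inward_frac: float = 0.3,
) -> tuple[TranscriptModel, TssRefinementRecord]:
    """Re-anchor a transcript 5' end on the closest sufficiently tall CAGE peak.

    The search window runs ``max_upstream`` nt upstream of the model TSS
    and ``max_inward_frac * L`` nt toward the transcript centre.  Among
    same-strand peaks with at least ``min_tags`` tags, the closest to the
    original TSS wins (upstream wins ties).  A winning peak beyond the
    first exon's interior leaves the model unchanged (the refinement
    never crosses the first intron or empties the first exon).
    """
    t = transcript
    tss = t.tss
    inward = int(max_inward_frac * t.length)
    if t.strand == "-":
        lo, hi = tss - inward, tss + max_upstream
    else:
        lo, hi = tss - max_upstream, tss + inward
    sel = cage[
        (cage["chrom"] == t.chrom)
        & (cage["strand"] == t.strand)
        & (cage["count"] >= min_tags)
        & (cage["pos"] >= lo)
        & (cage["pos"] <= hi)
    ]
    rec_unchanged = TssRefinementRecord(t.transcript_id, tss, tss, "unchanged", 0)
    if sel.empty:
        return t, rec_unchanged
    pos = sel["pos"].to_numpy(int)
    dist = np.abs(pos - tss)
    # upstream wins ties: for '+' upstream means smaller coordinate
    upstream = (pos < tss) if t.strand != "-" else (pos > tss)
    order = np.lexsort((~upstream, dist))
    new_tss = int(pos[order[0]])
    if new_tss == tss:
        return t, rec_unchanged

    first = t.exons[0] if t.strand != "-" else t.exons[-1]
    exons = list(t.exons)
    if t.strand != "-":
        if new_tss > tss and new_tss >= first.end - 1:
            logger.warning(
                "%s: refined TSS would cross the first intron; unchanged",
                t.transcript_id,
            )
            return t, rec_unchanged
        exons[0] = GenomicInterval(t.chrom, new_tss, first.end, t.strand)
        extended = new_tss < tss
    else:
        if new_tss < tss and new_tss <= first.start:
            logger.warning(
                "%s: refined TSS would cross the first intron; unchanged",
                t.transcript_id,
            )
            return t, rec_unchanged
        exons[-1] = GenomicInterval(t.chrom, first.start, new_tss + 1, t.strand)
        extended = new_tss > tss
    refined = TranscriptModel(
        t.transcript_id, t.gene_id, t.chrom, t.strand, exons, t.provenance
    )
    rec = TssRefinementRecord(
        t.transcript_id, tss, new_tss,
        "extended" if extended else "clipped", abs(new_tss - tss),
    )
    return refined, rec


# -- orchestration ---------------------------------------------------------


@dataclass
class CascadeResult:
    hq: list[GeneModel]
    main: list[GeneModel]
    constitutive: list[GeneModel]
    report: CascadeReport
    readthrough_flags: set[str]
    tss_records: list[TssRefinementRecord]


def run_cascade(
    candidates: Sequence[GeneModel],
    reference: Sequence[GeneModel],
    expr: ExpressionTable,
    strand_counts: pd.DataFrame,
    de: DETable,
    repeats: Sequence[GenomicInterval],
    cage: pd.DataFrame | None = None,
    *,
    blacklist_chroms: Sequence[str] = DEFAULT_BLACKLIST,
    min_fpkm: float = 2.0,
    auto_drop_readthrough: bool = False,
    refine: bool = True,
) -> CascadeResult:
    """Apply the full filtering cascade in order and refine HQ TSSs."""
    report = CascadeReport()
    genes = list(candidates)

    genes, st = filter_annotated_overlap(genes, reference)
    report.add(st)
    genes, st = filter_intronic(genes, reference)
    report.add(st)
    genes, st = filter_monoexonic(
        genes, strand_counts, samples=list(NON_NUCLEAR_CONDITIONS)
    )
    report.add(st)
    genes, st = filter_basic(genes, blacklist_chroms)
    report.add(st)
    genes, st = filter_expression(genes, expr, min_fpkm=min_fpkm)
    report.add(st)
    genes, st = filter_repeats(genes, repeats)
    report.add(st)
    genes, st = dedup_isoforms(genes)
    report.add(st)
    genes, st = filter_nuclear_ratio(genes, expr, reference)
    report.add(st)
    genes, st, flags = flag_readthrough(
        genes, reference, expr, auto_drop=auto_drop_readthrough
    )
    report.add(st)
    main, const, st = partition_by_de(genes, de, reference, expr=expr)
    report.add(st)

    hq = main + const
    records: list[TssRefinementRecord] = []
    if refine and cage is not None:
        refined_genes = []
        for g in hq:
            new_tx = []
            for t in g.transcripts:
                rt, rec = refine_tss(t, cage)
                new_tx.append(rt)
                records.append(rec)
            refined_genes.append(GeneModel(g.gene_id, new_tx, biotype=g.biotype))
        hq = refined_genes
    return CascadeResult(hq, main, const, report, flags, records)
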