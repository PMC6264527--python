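"""Genomic-context classification, TSS de-duplication, lncRNA-PCG pair
sets and correlation-versus-random-background analysis.

Each lncRNA gene receives exactly one context class by walking the
hierarchy TSS > TES > exon > intron > promoter > enhancer > intergenic
against the expressed protein-coding annotation (overlap is tested
strand-blind; the promoter is the 1 kb window upstream of an annotated
TSS).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionTable
from .intervals import GenomicInterval, intersect_length
from .models import GeneModel, TranscriptModel, closest_gene, longest_isoforms
from .stats import rank_sum_test

CONTEXT_HIERARCHY = (
    "TSS", "TES", "exon", "intron", "promoter", "enhancer", "intergenic",
)

PAIR_CATEGORIES = (
    "closest_any", "closest_nonoverlap", "antisense_TSS",
    "antisense_exon", "promoter_overlap", "random",
)


def expressed_genes(
    genes: Sequence[GeneModel], expr: ExpressionTable, min_fpkm: float = 1.0
) -> list[GeneModel]:
    """Genes reaching ``min_fpkm`` in at least one condition."""
    out = []
    for g in genes:
        if g.gene_id in expr.fpkm.index and expr.max_fpkm(g.gene_id) >= min_fpkm:
            out.append(g)
    return out


def _promoter(t: TranscriptModel, promoter_len: int) -> GenomicInterval | None:
    if t.strand == "-":
        s, e = t.tss + 1, t.tss + 1 + promoter_len
    else:
        s, e = t.tss - promoter_len, t.tss
    if e <= max(s, 0):
        return None
    return GenomicInterval(t.chrom, max(s, 0), e)


def _overlaps_point(pairs: list[tuple[int, int]], pos: int) -> bool:
    return any(s <= pos < e for s, e in pairs)


def classify_context(
    lnc: GeneModel,
    reference_pcgs: Sequence[GeneModel],
    enhancers: Sequence[GenomicInterval] = (),
    promoter_len: int = 1000,
    use_exonic: bool = True,
) -> str:
    """First matching class in the hierarchy, strand-blind.

    ``use_exonic`` tests the lncRNA's exonic bases against each feature;
    switching it off uses the gene span instead.
    """
    iso = lnc.longest_isoform()
    pairs = iso.exon_pairs if use_exonic else [(iso.span.start, iso.span.end)]
    chrom = lnc.chrom

    tss_hit = tes_hit = exon_hit = intron_hit = promoter_hit = False
    for pcg in reference_pcgs:
        if pcg.chrom != chrom:
            continue
        for t in pcg.transcripts:
            if _overlaps_point(pairs, t.tss):
                tss_hit = True
            if _overlaps_point(pairs, t.tes):
                tes_hit = True
            if intersect_length(pairs, t.exon_pairs) > 0:
                exon_hit = True
            if intersect_length(pairs, sorted(t.introns)) > 0:
                intron_hit = True
            prom = _promoter(t, promoter_len)
            if prom is not None and intersect_length(
                pairs, [(prom.start, prom.end)]
            ) > 0:
                promoter_hit = True
    if tss_hit:
        return "TSS"
    if tes_hit:
        return "TES"
    if exon_hit:
        return "exon"
    if intron_hit:
        return "intron"
    if promoter_hit:
        return "promoter"
    for enh in enhancers:
        if enh.chrom == chrom and intersect_length(
            pairs, [(enh.start, enh.end)]
        ) > 0:
            return "enhancer"
    return "intergenic"


def classify_all(
    lncs: Sequence[GeneModel],
    reference_pcgs: Sequence[GeneModel],
    enhancers: Sequence[GenomicInterval] = (),
    **kw,
) -> pd.Series:
    return pd.Series(
        {g.gene_id: classify_context(g, reference_pcgs, enhancers, **kw)
         for g in lncs},
        name="context",
    )


def dedup_tss(
    gene: GeneModel, expr: ExpressionTable, window: int = 50
) -> list[tuple[str, int]]:
    """Collapse isoform TSSs within +/- ``window`` nt to the TSS of the
    highest-FPKM isoform; returns (transcript_id, tss) representatives."""
    if expr.level != "transcript":
        raise ValueError("dedup_tss needs a transcript-level expression table")

    def fpkm(t: TranscriptModel) -> float:
        if t.transcript_id in expr.fpkm.index:
            return float(expr.fpkm.loc[t.transcript_id].max())
        return 0.0

    order = sorted(gene.transcripts, key=lambda t: (-fpkm(t), t.transcript_id))
    reps: list[tuple[str, int]] = []
    for t in order:
        if all(abs(t.tss - pos) > window for _, pos in reps):
            reps.append((t.transcript_id, t.tss))
    return reps


# -- pair sets -------------------------------------------------------------


@dataclass(frozen=True)
class PairRecord:
    lnc_id: str
    pcg_id: str
    category: str
    distance: int | None = None

    def __post_init__(self) -> None:
        if self.category not in PAIR_CATEGORIES:
            raise ValueError(f"unknown pair category {self.category!r}")


def build_pair_sets(
    lncs: Sequence[GeneModel], pcgs: Sequence[GeneModel],
    promoter_len: int = 1000,
) -> list[PairRecord]:
    """The five real lncRNA-PCG pair sets with longest-isoform
    de-redundancy; every lncRNA appears at most once per category."""
    if not lncs or not pcgs:
        raise ValueError("both gene sets must be non-empty")
    pairs: list[PairRecord] = []
    lnc_iso = longest_isoforms(lncs)
    pcg_iso = longest_isoforms(pcgs)
    pcg_by_id = {g.gene_id: g for g in pcgs}

    # 1-2: closest neighbour, with and without overlapping partners
    for lnc in lncs:
        near, dist = closest_gene(lnc, pcgs, allow_overlap=True)
        if near is not None:
            pairs.append(PairRecord(lnc.gene_id, near.gene_id, "closest_any", dist))
        near, dist = closest_gene(lnc, pcgs, allow_overlap=False)
        if near is not None:
            pairs.append(
                PairRecord(lnc.gene_id, near.gene_id, "closest_nonoverlap", dist)
            )

    # 3: antisense to a PCG TSS
    tss_claims: dict[str, list[str]] = {}   # lnc -> pcg ids whose TSS it covers
    lnc_of_tss: dict[str, list[str]] = {}   # pcg -> lncs covering its TSS
    for lid, liso in lnc_iso.items():
        for pid, piso in pcg_iso.items():
            if piso.chrom != liso.chrom or piso.strand == liso.strand:
                continue
            if _overlaps_point(liso.exon_pairs, piso.tss):
                tss_claims.setdefault(lid, []).append(pid)
                lnc_of_tss.setdefault(pid, []).append(lid)
    in_tss_set: set[str] = set()
    for lid, pids in tss_claims.items():
        # multiple TSSs in one lncRNA: the longest mRNA's TSS counts
        best = max(pids, key=lambda p: (pcg_iso[p].length, p))
        # multiple lncRNAs embedding one TSS: only the longest lncRNA
        rivals = lnc_of_tss[best]
        chosen = max(rivals, key=lambda l: (lnc_iso[l].length, l))
        if chosen == lid:
            pairs.append(PairRecord(lid, best, "antisense_TSS"))
            in_tss_set.add(lid)

    # 4: antisense to PCG exons (not its TSS)
    exon_claims: dict[str, list[str]] = {}
    lnc_of_exon: dict[str, list[str]] = {}
    for lid, liso in lnc_iso.items():
        if lid in in_tss_set:
            continue
        for pid, piso in pcg_iso.items():
            if piso.chrom != liso.chrom or piso.strand == liso.strand:
                continue
            if intersect_length(liso.exon_pairs, piso.exon_pairs) > 0:
                exon_claims.setdefault(lid, []).append(pid)
                lnc_of_exon.setdefault(pid, []).append(lid)
    in_exon_set: set[str] = set()
    for lid, pids in exon_claims.items():
        best = max(pids, key=lambda p: (pcg_iso[p].length, p))
        chosen = max(lnc_of_exon[best], key=lambda l: (lnc_iso[l].length, l))
        if chosen == lid:
            pairs.append(PairRecord(lid, best, "antisense_exon"))
            in_exon_set.add(lid)

    # 5: overlapping a PCG promoter without touching the PCG itself
    prom_claims: dict[str, list[str]] = {}
    lnc_of_prom: dict[str, list[str]] = {}
    for lid, liso in lnc_iso.items():
        if lid in in_tss_set or lid in in_exon_set:
            continue
        for pid, piso in pcg_iso.items():
            if piso.chrom != liso.chrom:
                continue
            span = piso.span
            if intersect_length(liso.exon_pairs, [(span.start, span.end)]) > 0:
                continue  # promoter-proximal class excludes PCG-overlapping lncs
            prom = _promoter(piso, promoter_len)
            if prom is not None and intersect_length(
                liso.exon_pairs, [(prom.start, prom.end)]
            ) > 0:
                prom_claims.setdefault(lid, []).append(pid)
                lnc_of_prom.setdefault(pid, []).append(lid)
    for lid, pids in prom_claims.items():
        best = max(pids, key=lambda p: (pcg_iso[p].length, p))
        chosen = max(lnc_of_prom[best], key=lambda l: (lnc_iso[l].length, l))
        if chosen == lid:
            pairs.append(PairRecord(lid, best, "promoter_overlap"))
    return pairs


def random_pairs(
    lncs: Sequence[GeneModel],
    pcgs: Sequence[GeneModel],
    n_sets: int = 1000,
    seed: int = 0,
) -> list[PairRecord]:
    """``n_sets`` uniform random lncRNA -> PCG assignments, concatenated
    (size = n_sets * len(lncs))."""
    rng = np.random.default_rng(seed)
    pcg_ids = [g.gene_id for g in pcgs]
    out: list[PairRecord] = []
    for _ in range(n_sets):
        draws = rng.integers(0, len(pcg_ids), size=len(lncs))
        out.extend(
            PairRecord(l.gene_id, pcg_ids[j], "random")
            for l, j in zip(lncs, draws)
        )
    return out


def pair_correlations(
    pairs: Iterable[PairRecord],
    expr: ExpressionTable,
    conditions: Sequence[str],
) -> tuple[pd.DataFrame, int]:
    """Pearson r per pair over the named condition vector.

    Pairs with a zero-variance member (or a member missing from the
    table) are excluded; their count is returned alongside.
    """
    conds = list(conditions)
    if len(conds) < 3:
        raise ValueError("need >= 3 conditions for a correlation")
    missing = [c for c in conds if c not in expr.fpkm.columns]
    if missing:
        raise KeyError(f"unknown condition(s): {missing}")
    mat = expr.fpkm[conds]
    x = mat.to_numpy(float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    ok = sd[:, 0] > 0
    z = np.zeros_like(x)
    z[ok] = (x[ok] - mu[ok]) / sd[ok]
    row = {f: i for i, f in enumerate(mat.index)}
    rows, excluded = [], 0
    for p in pairs:
        i, j = row.get(p.lnc_id), row.get(p.pcg_id)
        if i is None or j is None or not (ok[i] and ok[j]):
            excluded += 1
            continue
        r = float(np.dot(z[i], z[j]) / len(conds))
        rows.append((p.lnc_id, p.pcg_id, p.category, r))
    return (
        pd.DataFrame(rows, columns=["lnc_id", "pcg_id", "category", "r"]),
        excluded,
    )


def compare_category_to_background(
    category_r: Sequence[float], random_r: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum of a pair category against the random
    background; returns (statistic, p)."""
    if len(category_r) < 5 or len(random_r) < 5:
        raise ValueError("need >= 5 correlations per sample")
    return rank_sum_test(category_r, random_r)
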