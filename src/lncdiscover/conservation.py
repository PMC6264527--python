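"""Per-transcript conservation scoring against conserved-element tracks
and the early/constitutive/late temporal-group comparison.

The score is s = sum_i(O_i * P_i) / L, where O_i is the exonic overlap
in nucleotides with conserved element i, P_i the element's score (e.g. a
phastCons-element score) and L the mature transcript length.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .expression import DETable, ExpressionTable
from .intervals import GenomicInterval, intersect_length
from .models import GeneModel, TranscriptModel
from .stats import rank_sum_test

TEMPORAL_GROUPS = ("early", "constitutive", "late")


def conservation_score(
    t: TranscriptModel,
    elements: Sequence[tuple[GenomicInterval, float]],
    use_exonic: bool = True,
) -> float:
    """Overlap-weighted element-score sum over the transcript length."""
    pairs = t.exon_pairs if use_exonic else [(t.span.start, t.span.end)]
    length = t.length if use_exonic else t.span.length
    total = 0.0
    for iv, score in elements:
        if iv.chrom != t.chrom:
            continue
        o = intersect_length(pairs, [(iv.start, iv.end)])
        total += o * score
    return total / length


def temporal_groups(
    de: DETable,
    expr: ExpressionTable,
    genes: Sequence[str],
    alpha: float = 0.01,
    comparison: str = "Time34_VS_Time68",
    early_cond: str = "WE_34",
    late_cond: str = "WE_68",
) -> pd.Series:
    """early / constitutive / late by the 3-4h vs 6-8h contrast.

    Not significantly changing -> constitutive; significant genes are
    early when whole-embryo 3-4h expression exceeds 6-8h, late otherwise.
    """
    for c in (early_cond, late_cond):
        if c not in expr.fpkm.columns:
            raise ValueError(f"expression table lacks condition {c!r}")
    tab = de.for_comparison(comparison).set_index("gene_id")
    out = {}
    for g in genes:
        padj = float(tab.loc[g, "padj"]) if g in tab.index else 1.0
        if padj >= alpha:
            out[g] = "constitutive"
        elif g in expr.fpkm.index and (
            float(expr.fpkm.loc[g, early_cond]) > float(expr.fpkm.loc[g, late_cond])
        ):
            out[g] = "early"
        else:
            out[g] = "late"
    return pd.Series(out, name="temporal_group")


def compare_conservation(
    groups: pd.Series,
    genes: Sequence[GeneModel],
    elements: Sequence[tuple[GenomicInterval, float]],
    isoform_rule: str = "longest",
    expr: ExpressionTable | None = None,
) -> pd.DataFrame:
    """Per-group conservation medians and pairwise two-sided Mann-Whitney
    p-values of the early group against the other two.

    ``isoform_rule`` selects the per-gene representative transcript:
    "longest" (default), or "highest_expressed" when an expression table
    is supplied.
    """
    by_id = {g.gene_id: g for g in genes}
    scores: dict[str, float] = {}
    for gid in groups.index:
        gene = by_id.get(gid)
        if gene is None:
            continue
        if isoform_rule == "longest":
            iso = gene.longest_isoform()
        elif isoform_rule == "highest_expressed":
            if expr is None or expr.level != "transcript":
                raise ValueError(
                    "highest_expressed rule needs a transcript-level table"
                )
            iso = max(
                gene.transcripts,
                key=lambda t: (
                    float(expr.fpkm.loc[t.transcript_id].max())
                    if t.transcript_id in expr.fpkm.index else 0.0
                ),
            )
        else:
            raise ValueError(f"unknown isoform rule {isoform_rule!r}")
        scores[gid] = conservation_score(iso, elements)

    per_group = {
        grp: [scores[g] for g in groups[groups == grp].index if g in scores]
        for grp in TEMPORAL_GROUPS
    }
    rows = []
    for grp in TEMPORAL_GROUPS:
        vals = per_group[grp]
        rows.append((grp, len(vals), float(np.median(vals)) if vals else np.nan))
    summary = pd.DataFrame(rows, columns=["group", "n", "median_score"])
    for other in ("constitutive", "late"):
        a, b = per_group["early"], per_group[other]
        if len(a) >= 2 and len(b) >= 2:
            _, p = rank_sum_test(a, b)
        else:
            p = np.nan
        summary[f"p_early_vs_{other}"] = p
    return summary
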