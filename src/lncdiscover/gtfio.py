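"""Standard-format I/O: GTF gene models, BED intervals, TSV tables, FASTA.

GTF coordinates are 1-based inclusive on disk and converted to the
internal 0-based half-open convention on read (and back on write).
Writers emit deterministic column and record order so outputs are
byte-reproducible.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .expression import COMPARISON_REGISTRY, DETable, ExpressionTable
from .intervals import GenomicInterval
from .models import GeneModel, TranscriptModel


class GtfParseError(ValueError):
    pass


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def read_gtf(path: str | Path, provenance: str = "assembled") -> list[GeneModel]:
    """Read exon features from a GTF file into GeneModels.

    Only ``exon`` records are material; gene/transcript container lines
    are tolerated and ignored.  Raises :class:`GtfParseError` naming the
    offending line on malformed input, and a validation error when a
    transcript's exons mix strands.
    """
    path = Path(path)
    exons: dict[str, list[GenomicInterval]] = {}
    tx_meta: dict[str, tuple[str, str]] = {}  # tid -> (gene_id, biotype)
    tx_order: list[str] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path.name}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = (
                fields
            )
            if feature != "exon":
                continue
            try:
                start = int(start_s)
                end = int(end_s)
            except ValueError as exc:
                raise GtfParseError(
                    f"{path.name}:{lineno}: non-integer coordinates"
                ) from exc
            if start < 1 or end < start:
                raise GtfParseError(f"{path.name}:{lineno}: bad coordinates")
            if strand not in ("+", "-", "."):
                raise GtfParseError(f"{path.name}:{lineno}: bad strand {strand!r}")
            a = _parse_attributes(attrs)
            if "gene_id" not in a or "transcript_id" not in a:
                raise GtfParseError(
                    f"{path.name}:{lineno}: missing gene_id/transcript_id attribute"
                )
            tid = a["transcript_id"]
            iv = GenomicInterval(chrom, start - 1, end, strand)
            if tid in tx_meta:
                prev = exons[tid][0]
                if prev.chrom != chrom:
                    raise GtfParseError(
                        f"{path.name}:{lineno}: transcript {tid} spans chromosomes"
                    )
                if prev.strand != strand:
                    raise GtfParseError(
                        f"{path.name}:{lineno}: transcript {tid} has exons on "
                        "mixed strands"
                    )
            else:
                tx_meta[tid] = (a["gene_id"], a.get("gene_biotype", "other"))
                tx_order.append(tid)
                exons[tid] = []
            exons[tid].append(iv)

    genes: dict[str, GeneModel] = {}
    gene_order: list[str] = []
    for tid in tx_order:
        gid, biotype = tx_meta[tid]
        first = exons[tid][0]
        tx = TranscriptModel(
            transcript_id=tid,
            gene_id=gid,
            chrom=first.chrom,
            strand=first.strand,
            exons=exons[tid],
            provenance=provenance,
        )
        if gid not in genes:
            bt = biotype if biotype in ("protein_coding", "lncRNA_annotated",
                                        "lncRNA_novel", "other") else "other"
            genes[gid] = GeneModel(gene_id=gid, transcripts=[tx], biotype=bt)
            gene_order.append(gid)
        else:
            genes[gid].transcripts.append(tx)
    return [genes[g] for g in gene_order]


def write_gtf(genes: Sequence[GeneModel], path: str | Path, source: str = "lncdiscover") -> None:
    path = Path(path)
    with path.open("w") as fh:
        for gene in sorted(genes, key=lambda g: g.gene_id):
            for tx in sorted(gene.transcripts, key=lambda t: t.transcript_id):
                for i, ex in enumerate(tx.exons, start=1):
                    attrs = (
                        f'gene_id "{gene.gene_id}"; '
                        f'transcript_id "{tx.transcript_id}"; '
                        f'exon_number "{i}"; '
                        f'gene_biotype "{gene.biotype}";'
                    )
                    fh.write(
                        "\t".join(
                            [
                                tx.chrom,
                                source,
                                "exon",
                                str(ex.start + 1),
                                str(ex.end),
                                ".",
                                tx.strand,
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )


# -- BED -----------------------------------------------------------------


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """BED3/5/6; score column (if any) is ignored here — see read_scored_bed."""
    out = []
    with Path(path).open() as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            strand = f[5] if len(f) > 5 else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def read_scored_bed(path: str | Path) -> list[tuple[GenomicInterval, float]]:
    """BED5 with the score column carrying a real-valued element score."""
    out = []
    with Path(path).open() as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            score = float(f[4]) if len(f) > 4 else 0.0
            out.append((GenomicInterval(f[0], int(f[1]), int(f[2])), score))
    return out


def write_bed(
    records: Iterable[tuple[GenomicInterval, str, float]], path: str | Path
) -> None:
    """Write (interval, name, score) triples as BED6."""
    with Path(path).open("w") as fh:
        for iv, name, score in sorted(
            records, key=lambda r: (r[0].chrom, r[0].start, r[0].end)
        ):
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n"
            )


# -- tables --------------------------------------------------------------


def read_expression_tsv(path: str | Path, level: str = "gene") -> ExpressionTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionTable(df, level=level)


def write_expression_tsv(expr: ExpressionTable, path: str | Path) -> None:
    expr.fpkm.sort_index().to_csv(path, sep="\t", index_label="feature_id")


def read_strand_counts_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"feature_id", "condition", "sense_reads", "antisense_reads"}
    if not required.issubset(df.columns):
        raise ValueError(f"strand-count table needs columns {sorted(required)}")
    return df


def read_de_tsv(path: str | Path, registry: tuple[str, ...] = COMPARISON_REGISTRY) -> DETable:
    return DETable(pd.read_csv(path, sep="\t"), registry=registry)


def read_cage_tsv(path: str | Path) -> pd.DataFrame:
    """CAGE 5'-tag counts: columns chrom, pos (0-based), strand, count."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "strand", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"CAGE table needs columns {sorted(required)}")
    return df


# -- FASTA ---------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sorted(seqs.items())
    ]
    SeqIO.write(records, str(path), "fasta")
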