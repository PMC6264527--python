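"""Synthetic embryo transcriptome with planted ground truth.

Generates a miniature genome annotation (reference protein-coding genes
and annotated lncRNAs plus assembled candidate models), staged expression
over mesoderm/whole-embryo time courses with nuclear fractions, stranded
locus read counts, a DE table, CAGE 5'-tag counts, repeat/conservation/
enhancer tracks, transcript sequences and knockout-cross progeny counts —
each candidate artifact class constructed to violate exactly one filter
of the discovery cascade, so the cascade's behaviour can be verified
against a truth table without any sequencing data.

Planted artifact classes
------------------------
* ``planted_novel_lncRNA`` — clean candidates that must survive to the
  high-quality set (staged "main" profiles or flat "constitutive" ones).
* ``dna_contamination`` — stranded monoexonic loci whose sense ratio
  stays below 0.8 in every sample.
* ``pre_mRNA_leftover`` — monoexonic transcripts inside same-strand
  annotated introns; one sub-cohort is caught by the intronic filter,
  the other also overlaps an annotated antisense exon (so it survives
  that filter) and is instead nuclear-enriched beyond the log2 > 1 cut.
* ``repeat_decoy`` — transcripts with > 90% of exonic bases masked.
* ``coding_orf`` — candidates whose sequences carry a long ORF and whose
  evidence table gives them a second coding vote.
* ``readthrough`` — candidates starting just downstream of an expressed
  protein-coding gene's 3' end on the same strand.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats as _st

from .expression import (
    COMPARISON_REGISTRY,
    DETable,
    ExpressionTable,
)
from .gtfio import (
    read_bed,
    read_cage_tsv,
    read_de_tsv,
    read_expression_tsv,
    read_fasta,
    read_gtf,
    read_scored_bed,
    read_strand_counts_tsv,
    write_bed,
    write_expression_tsv,
    write_fasta,
    write_gtf,
)
from .intervals import GenomicInterval
from .models import GeneModel, TranscriptModel
from .stats import bh_adjust

# condition naming ---------------------------------------------------------

NON_NUCLEAR_CONDITIONS = (
    "Meso_34", "Meso_46", "Meso_68", "WE_34", "WE_46", "WE_68",
)
NUCLEAR_CONDITIONS = ("Meso_34_Nuc", "Meso_68_Nuc")

#: condition groups behind each comparison code
COMPARISON_GROUPS: dict[str, tuple[str, ...]] = {
    "S34": ("Meso_34",),
    "S46": ("Meso_46",),
    "S68": ("Meso_68",),
    "U34": ("WE_34",),
    "U46": ("WE_46",),
    "U68": ("WE_68",),
    "Nuclear34S": ("Meso_34_Nuc",),
    "Nuclear68S": ("Meso_68_Nuc",),
    "FacsSorted": ("Meso_34", "Meso_46", "Meso_68"),
    "facsUnsorted": ("WE_34", "WE_46", "WE_68"),
    "Time34": ("Meso_34", "WE_34"),
    "Time46": ("Meso_46", "WE_46"),
    "Time68": ("Meso_68", "WE_68"),
}

#: staged expression archetypes (log2 FPKM means over the six
#: non-nuclear conditions), mirroring the robust cluster shapes:
#: early-declining, late-rising, mid-peak, mesoderm-specific, WE-specific.
CLUSTER_ARCHETYPES = np.array(
    [
        [4.5, 3.0, 1.0, 4.5, 3.0, 1.0],
        [0.0, 2.0, 4.5, 0.0, 2.0, 4.5],
        [0.5, 4.5, 0.5, 0.5, 4.5, 0.5],
        [4.5, 4.5, 4.5, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 4.5, 4.5, 4.5],
    ]
)


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic bundle (defaults = toy scale)."""

    seed: int = 0
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr2L": 2_000_000, "chr2R": 2_000_000}
    )
    n_pcg: int = 300
    n_annotated_lnc: int = 60
    # candidate classes
    n_clean_de: int = 25
    n_clean_constitutive: int = 15
    n_dna_contamination: int = 8
    n_premrna_intronic: int = 4
    n_premrna_nuclear: int = 4
    n_repeat_decoy: int = 8
    n_coding_decoy: int = 8
    n_readthrough: int = 4
    n_dup_isoform_genes: int = 3     # clean genes given a near-identical isoform
    n_divergent_clean: int = 6       # clean candidates placed divergent to a PCG
    n_nuclear_enriched: int = 8      # clean subset elevated in nuclear fractions
    n_strain_specific: int = 6       # clean subset silent in the second strain
    n_divergent_high_pcg: int = 100  # PCG promoters with divergent transcription
    # noise / effects
    replicates: int = 4
    log2_sigma: float = 0.3          # log-normal FPKM dispersion (log2 scale)
    nuclear_shift: float = 3.0       # log2 boost of nuclear-enriched genes
    premrna_nuclear_shift: float = 2.5
    coexpression_frac: float = 0.7   # clean DE genes sharing profile with closest PCG
    divergent_fpkm_boost: float = 1.0  # log2, for divergent-high PCGs
    # CAGE
    cage_supported_height: tuple[int, int] = (60, 150)
    cage_unsupported_height: tuple[int, int] = (10, 49)
    cage_unsupported_frac: float = 0.15
    tss_jitter_frac: float = 0.6
    tss_jitter_range: tuple[int, int] = (50, 300)
    # tracks
    repeat_decoy_masked_frac: float = 0.95
    n_random_repeats: int = 100
    n_conserved_elements: int = 250
    conserved_score_range: tuple[float, float] = (50.0, 600.0)
    n_enhancers: int = 50
    # viability
    viability_lines: int = 5
    viability_progeny: tuple[int, int] = (60, 110)
    hom_probability: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        counts = [
            self.n_pcg, self.n_annotated_lnc, self.n_clean_de,
            self.n_clean_constitutive, self.n_dna_contamination,
            self.n_premrna_intronic, self.n_premrna_nuclear,
            self.n_repeat_decoy, self.n_coding_decoy, self.n_readthrough,
        ]
        if any(c < 0 for c in counts):
            raise ConfigError("all class counts must be >= 0")
        if self.seed is None:
            raise ConfigError("seed is mandatory")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cage_supported_height"] = list(self.cage_supported_height)
        d["cage_unsupported_height"] = list(self.cage_unsupported_height)
        d["tss_jitter_range"] = list(self.tss_jitter_range)
        d["conserved_score_range"] = list(self.conserved_score_range)
        d["viability_progeny"] = list(self.viability_progeny)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for k in ("cage_supported_height", "cage_unsupported_height",
                  "tss_jitter_range", "conserved_score_range",
                  "viability_progeny"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class TruthTable:
    """Planted ground-truth labels and true TSS positions."""

    labels: dict[str, set[str]] = field(default_factory=dict)
    true_tss: dict[str, int] = field(default_factory=dict)
    coexpressed_pairs: list[tuple[str, str]] = field(default_factory=list)

    def add(self, gene_id: str, *labels: str) -> None:
        self.labels.setdefault(gene_id, set()).update(labels)

    def genes_with(self, label: str) -> set[str]:
        return {g for g, ls in self.labels.items() if label in ls}

    def has(self, gene_id: str, label: str) -> bool:
        return label in self.labels.get(gene_id, set())

    def validate(self, candidates: Sequence[GeneModel]) -> None:
        """Internal label-consistency checks, run at generation time."""
        by_id = {g.gene_id: g for g in candidates}
        for gid in self.genes_with("dna_contamination"):
            gene = by_id[gid]
            if any(not t.is_monoexonic for t in gene.transcripts):
                raise ConfigError(f"{gid}: dna_contamination must be monoexonic")
        for gid in self.genes_with("planted_novel_lncRNA"):
            for t in by_id[gid].transcripts:
                if t.transcript_id not in self.true_tss:
                    raise ConfigError(f"{t.transcript_id}: missing true TSS")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(g, ",".join(sorted(ls))) for g, ls in sorted(self.labels.items())],
            columns=["feature_id", "labels"],
        )

    def tss_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.true_tss.items()), columns=["transcript_id", "true_tss"]
        )

    @classmethod
    def from_frames(cls, labels: pd.DataFrame, tss: pd.DataFrame) -> "TruthTable":
        t = cls()
        for _, row in labels.iterrows():
            t.labels[row["feature_id"]] = set(
                s for s in str(row["labels"]).split(",") if s
            )
        for _, row in tss.iterrows():
            t.true_tss[row["transcript_id"]] = int(row["true_tss"])
        return t


# -- placement helpers -----------------------------------------------------


class _Cursor:
    """Sequential left-to-right placement over the synthetic chromosomes."""

    def __init__(self, chrom_sizes: dict[str, int], rng: np.random.Generator):
        self.chroms = list(chrom_sizes)
        self.sizes = chrom_sizes
        self.pos = {c: 10_000 for c in self.chroms}
        self.idx = 0
        self.rng = rng

    def place(self, span: int, margin: int = 400) -> tuple[str, int]:
        """Reserve ``span`` bases (plus a random gap) and return (chrom, start)."""
        for _ in range(len(self.chroms)):
            chrom = self.chroms[self.idx % len(self.chroms)]
            self.idx += 1
            start = self.pos[chrom] + margin
            gap = int(self.rng.integers(2_000, 6_000))
            if start + span + gap < self.sizes[chrom] - 10_000:
                self.pos[chrom] = start + span + gap
                return chrom, start
        raise ConfigError("genome too small for the requested gene counts")


def _make_transcript(
    tid: str, gid: str, chrom: str, strand: str, start: int,
    exon_lens: Sequence[int], intron_lens: Sequence[int],
    provenance: str = "assembled",
) -> TranscriptModel:
    exons = []
    pos = start
    for i, el in enumerate(exon_lens):
        exons.append(GenomicInterval(chrom, pos, pos + el, strand))
        pos += el
        if i < len(intron_lens):
            pos += intron_lens[i]
    return TranscriptModel(tid, gid, chrom, strand, exons, provenance)


def _random_structure(rng, n_exons_range, exon_range, intron_range):
    n = int(rng.integers(n_exons_range[0], n_exons_range[1] + 1))
    exon_lens = [int(rng.integers(*exon_range)) for _ in range(n)]
    intron_lens = [int(rng.integers(*intron_range)) for _ in range(n - 1)]
    return exon_lens, intron_lens


# -- annotation ------------------------------------------------------------


@dataclass
class Annotation:
    reference: list[GeneModel]
    candidates: list[GeneModel]
    truth: TruthTable


def generate_annotation(config: SimConfig) -> Annotation:
    """Plant reference genes and candidate transcript models.

    Gene ids are assigned per class up front, but the *placements* are
    executed in a shuffled order so that reference genes and candidates
    interleave along the chromosomes the way a real annotation does
    (closest-neighbour analyses would be meaningless if each class
    occupied its own contiguous block).  Deterministic given
    ``config.seed``: the same config yields a byte-identical GTF bundle.
    """
    rng = np.random.default_rng(config.seed)
    cursor = _Cursor(config.chrom_sizes, rng)
    truth = TruthTable()
    reference: list[GeneModel] = []
    candidates: list[GeneModel] = []

    def strand() -> str:
        return "+" if rng.random() < 0.5 else "-"

    n_compound = (
        config.n_premrna_intronic + config.n_premrna_nuclear
        + config.n_readthrough + config.n_divergent_clean
    )
    n_plain_pcg = config.n_pcg - n_compound
    if n_plain_pcg < 0:
        raise ConfigError("n_pcg too small for the compound constructs")

    # placement requests with pre-assigned ids: labels only depend on the
    # id sequence, never on the shuffled execution order
    pcg_seq = 0
    lnca_seq = 0
    cand_seq = 0

    def next_pcg_id() -> str:
        nonlocal pcg_seq
        pcg_seq += 1
        return f"PCG_{pcg_seq:04d}"

    def next_lnca_id() -> str:
        nonlocal lnca_seq
        lnca_seq += 1
        return f"LNCA_{lnca_seq:04d}"

    def next_cand_id() -> str:
        nonlocal cand_seq
        cand_seq += 1
        return f"XLOC_{cand_seq:04d}"

    requests: list[tuple] = []
    plain_pcg_ids = [next_pcg_id() for _ in range(n_plain_pcg)]
    requests += [("pcg", gid) for gid in plain_pcg_ids]
    requests += [("lnca", next_lnca_id())
                 for _ in range(config.n_annotated_lnc)]
    n_clean = config.n_clean_de + config.n_clean_constitutive
    clean_ids: list[str] = []
    for j in range(n_clean):
        gid = next_cand_id()
        clean_ids.append(gid)
        if j < config.n_divergent_clean:
            requests.append(("clean_divergent", gid, next_pcg_id()))
        else:
            requests.append(("clean", gid))
    requests += [("contamination", next_cand_id())
                 for _ in range(config.n_dna_contamination)]
    requests += [("premrna_intronic", next_cand_id(), next_pcg_id())
                 for _ in range(config.n_premrna_intronic)]
    requests += [("premrna_nuclear", next_cand_id(), next_pcg_id(),
                  next_lnca_id())
                 for _ in range(config.n_premrna_nuclear)]
    requests += [("repeat", next_cand_id())
                 for _ in range(config.n_repeat_decoy)]
    requests += [("coding", next_cand_id())
                 for _ in range(config.n_coding_decoy)]
    requests += [("readthrough", next_cand_id(), next_pcg_id())
                 for _ in range(config.n_readthrough)]

    # ---- geometry builders -------------------------------------------

    def add_pcg(gid, exon_lens=None, intron_lens=None, chrom_start=None,
                st=None) -> GeneModel:
        if exon_lens is None:
            exon_lens, intron_lens = _random_structure(
                rng, (3, 5), (200, 500), (200, 800)
            )
        span = sum(exon_lens) + sum(intron_lens)
        if chrom_start is None:
            chrom, start = cursor.place(span)
        else:
            chrom, start = chrom_start
        st = st or strand()
        tx = _make_transcript(
            f"{gid}.t1", gid, chrom, st, start, exon_lens, intron_lens,
            provenance="reference",
        )
        gene = GeneModel(gid, [tx], biotype="protein_coding")
        reference.append(gene)
        return gene

    def add_candidate(gid: str, transcripts: list[TranscriptModel],
                      *labels: str) -> GeneModel:
        gene = GeneModel(gid, transcripts, biotype="lncRNA_novel")
        candidates.append(gene)
        truth.add(gid, *labels)
        return gene

    def clean_structure():
        if rng.random() < 0.7:
            return _random_structure(rng, (2, 3), (300, 600), (300, 1000))
        return [int(rng.integers(600, 1500))], []

    def place_clean(gid: str, divergent_host: str | None) -> None:
        exon_lens, intron_lens = clean_structure()
        span = sum(exon_lens) + sum(intron_lens)
        if divergent_host is not None:
            # divergent configuration: lncRNA antisense, 5' end just
            # upstream of a fresh PCG's TSS
            p_ex, p_in = _random_structure(rng, (3, 4), (200, 500), (200, 700))
            p_span = sum(p_ex) + sum(p_in)
            chrom, start = cursor.place(span + 200 + p_span)
            tx = _make_transcript(
                f"{gid}.t1", gid, chrom, "-", start, exon_lens, intron_lens
            )
            add_pcg(divergent_host, p_ex, p_in,
                    chrom_start=(chrom, start + span + 200), st="+")
        else:
            chrom, start = cursor.place(span)
            tx = _make_transcript(
                f"{gid}.t1", gid, chrom, strand(), start, exon_lens, intron_lens
            )
        add_candidate(gid, [tx], "planted_novel_lncRNA")
        truth.true_tss[tx.transcript_id] = tx.tss

    def place_contamination(gid: str) -> None:
        length = int(rng.integers(600, 1200))
        chrom, start = cursor.place(length)
        tx = _make_transcript(f"{gid}.t1", gid, chrom, strand(), start,
                              [length], [])
        add_candidate(gid, [tx], "dna_contamination")

    def big_intron_pcg(host_id: str, anti_id: str | None):
        exon_lens, intron_lens = [600, 600], [3000]
        chrom, start = cursor.place(4200)
        st = strand()
        add_pcg(host_id, exon_lens, intron_lens, chrom_start=(chrom, start),
                st=st)
        cand_start = start + 600 + 1200  # centred in the 3 kb intron
        if anti_id is not None:
            anti_st = "+" if st == "-" else "-"
            anti_tx = _make_transcript(
                f"{anti_id}.t1", anti_id, chrom, anti_st, cand_start - 100,
                [800], [], provenance="reference",
            )
            reference.append(
                GeneModel(anti_id, [anti_tx], biotype="lncRNA_annotated")
            )
        return chrom, st, cand_start

    def place_premrna(gid: str, host_id: str, anti_id: str | None) -> None:
        chrom, st, cand_start = big_intron_pcg(host_id, anti_id)
        tx = _make_transcript(f"{gid}.t1", gid, chrom, st, cand_start,
                              [600], [])
        sub = "premrna_nuclear" if anti_id is not None else "premrna_intronic"
        add_candidate(gid, [tx], "pre_mRNA_leftover", sub)

    def place_repeat(gid: str) -> None:
        # >= 600 nt exons so the monoexonic length rule never fires first
        exon_lens, intron_lens = _random_structure(
            rng, (1, 2), (600, 900), (300, 800)
        )
        span = sum(exon_lens) + sum(intron_lens)
        chrom, start = cursor.place(span)
        tx = _make_transcript(f"{gid}.t1", gid, chrom, strand(), start,
                              exon_lens, intron_lens)
        add_candidate(gid, [tx], "repeat_decoy")

    def place_coding(gid: str) -> None:
        length = int(rng.integers(800, 1400))
        chrom, start = cursor.place(length)
        tx = _make_transcript(f"{gid}.t1", gid, chrom, strand(), start,
                              [length], [])
        add_candidate(gid, [tx], "coding_orf")

    def place_readthrough(gid: str, host_id: str) -> None:
        p_ex, p_in = _random_structure(rng, (3, 4), (200, 500), (200, 700))
        p_span = sum(p_ex) + sum(p_in)
        length = int(rng.integers(600, 1000))
        chrom, start = cursor.place(p_span + 150 + length)
        host = add_pcg(host_id, p_ex, p_in, chrom_start=(chrom, start), st="+")
        cand_start = host.transcripts[0].exons[-1].end + 150
        tx = _make_transcript(f"{gid}.t1", gid, chrom, "+", cand_start,
                              [length], [])
        add_candidate(gid, [tx], "readthrough")
        truth.add(gid, "readthrough_host:" + host_id)

    def place_lnca(gid: str) -> None:
        exon_lens, intron_lens = _random_structure(
            rng, (1, 3), (250, 700), (200, 700)
        )
        span = sum(exon_lens) + sum(intron_lens)
        chrom, start = cursor.place(span)
        tx = _make_transcript(f"{gid}.t1", gid, chrom, strand(), start,
                              exon_lens, intron_lens, provenance="reference")
        reference.append(GeneModel(gid, [tx], biotype="lncRNA_annotated"))

    # ---- execute in shuffled order ------------------------------------
    for i in rng.permutation(len(requests)):
        req = requests[i]
        kind = req[0]
        if kind == "pcg":
            add_pcg(req[1])
        elif kind == "lnca":
            place_lnca(req[1])
        elif kind == "clean":
            place_clean(req[1], None)
        elif kind == "clean_divergent":
            place_clean(req[1], req[2])
        elif kind == "contamination":
            place_contamination(req[1])
        elif kind == "premrna_intronic":
            place_premrna(req[1], req[2], None)
        elif kind == "premrna_nuclear":
            place_premrna(req[1], req[2], req[3])
        elif kind == "repeat":
            place_repeat(req[1])
        elif kind == "coding":
            place_coding(req[1])
        elif kind == "readthrough":
            place_readthrough(req[1], req[2])

    # near-identical duplicate isoforms on a few clean genes
    by_id = {g.gene_id: g for g in candidates}
    for gid in clean_ids[: config.n_dup_isoform_genes]:
        gene = by_id[gid]
        t = gene.transcripts[0]
        # trim a sliver off the 3' end: same TSS, Jaccard > 0.95
        trim = max(1, min(int(0.04 * t.length), t.exons[-1].length - 50,
                          t.exons[0].length - 50))
        if t.strand == "-":
            first = t.exons[0]
            exons = [GenomicInterval(t.chrom, first.start + trim, first.end,
                                     t.strand)]
            exons += t.exons[1:]
        else:
            exons = t.exons[:-1]
            last = t.exons[-1]
            exons += [GenomicInterval(t.chrom, last.start, last.end - trim,
                                      t.strand)]
        dup = TranscriptModel(f"{gid}.t2", gid, t.chrom, t.strand, exons)
        gene.transcripts.append(dup)
        truth.true_tss[dup.transcript_id] = dup.tss

    # cross-cutting labels on the clean set ---------------------------------
    de_ids = clean_ids[: config.n_clean_de]
    const_ids = clean_ids[config.n_clean_de:]
    for k, gid in enumerate(de_ids):
        truth.add(gid, f"cluster_{k % len(CLUSTER_ARCHETYPES) + 1}", "de_main")
    for gid in const_ids:
        truth.add(gid, "constitutive")
    for gid in clean_ids[: config.n_nuclear_enriched]:
        truth.add(gid, "nuclear_enriched")
    if config.n_strain_specific:
        for gid in clean_ids[-config.n_strain_specific:]:
            truth.add(gid, "strain_specific")

    # divergent-high PCG promoters (for the bidirectional-transcription sim)
    chosen = list(
        rng.choice(plain_pcg_ids,
                   size=min(config.n_divergent_high_pcg, len(plain_pcg_ids)),
                   replace=False)
    )
    for gid in sorted(chosen):
        truth.add(gid, "divergent_high")

    # TSS jitter: move candidate model 5' ends away from the true TSS,
    # within the window the CAGE refinement is allowed to search
    supported: list[str] = []
    for gid in clean_ids:
        gene = by_id[gid]
        if len(gene.transcripts) > 1:
            continue  # keep duplicate-isoform genes geometrically simple
        supported.append(gid)
    n_unsup = int(round(config.cage_unsupported_frac * len(supported)))
    unsupported = set(supported[-n_unsup:]) if n_unsup else set()
    for gid in supported:
        truth.add(gid, "cage_unsupported" if gid in unsupported
                  else "cage_supported")
    jittered = [g for g in supported if g not in unsupported]
    n_jit = int(round(config.tss_jitter_frac * len(jittered)))
    for gid in jittered[:n_jit]:
        gene = by_id[gid]
        t = gene.transcripts[0]
        lo, hi = config.tss_jitter_range
        first = t.exons[0] if t.strand != "-" else t.exons[-1]
        # never shrink a model below the monoexonic length threshold
        shrink_cap = min(hi, first.length - 60, t.length - 520)
        if rng.random() < 0.5 and shrink_cap >= lo:
            # shrink the model: true TSS lies upstream -> refinement extends
            d = int(rng.integers(lo, shrink_cap + 1))
            if t.strand != "-":
                t.exons[0] = GenomicInterval(t.chrom, first.start + d,
                                             first.end, t.strand)
            else:
                t.exons[-1] = GenomicInterval(t.chrom, first.start,
                                              first.end - d, t.strand)
        else:
            # stretch the model past the true TSS -> refinement clips
            d_max = min(hi, int(0.25 * t.length))
            d = int(rng.integers(lo, max(lo + 1, d_max + 1)))
            if t.strand != "-":
                t.exons[0] = GenomicInterval(t.chrom, first.start - d,
                                             first.end, t.strand)
            else:
                t.exons[-1] = GenomicInterval(t.chrom, first.start,
                                              first.end + d, t.strand)
        truth.add(gid, "tss_jittered")

    truth.validate(candidates)
    return Annotation(reference, candidates, truth)

# -- expression ------------------------------------------------------------


@dataclass
class SimExpression:
    expr: ExpressionTable              # per-condition mean FPKM, gene level
    replicate_log2: pd.DataFrame       # genes x (condition, replicate) log2 FPKM
    strand_counts: pd.DataFrame
    de: DETable


def _gene_profiles(
    annotation: Annotation, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-gene log2 FPKM means over all conditions."""
    truth = annotation.truth
    conditions = list(NON_NUCLEAR_CONDITIONS) + list(NUCLEAR_CONDITIONS)
    rows = {}
    cluster_of = {}
    for gid in truth.labels:
        for lab in truth.labels[gid]:
            if lab.startswith("cluster_"):
                cluster_of[gid] = int(lab.split("_")[1]) - 1

    # closest-PCG co-expression partners for a fraction of DE clean genes
    from .models import closest_gene  # local import to avoid cycle at module load

    # nuclear-enriched genes are excluded: their nuclear-fraction boost
    # would decouple them from a whole-cell partner profile
    de_ids = sorted(truth.genes_with("de_main") - truth.genes_with("nuclear_enriched"))
    n_co = int(round(config.coexpression_frac * len(de_ids)))
    co_ids = de_ids[:n_co]
    pcgs = [g for g in annotation.reference if g.biotype == "protein_coding"]
    cand_by_id = {g.gene_id: g for g in annotation.candidates}
    partner: dict[str, str] = {}
    for gid in co_ids:
        near, _ = closest_gene(cand_by_id[gid], pcgs)
        if near is not None and near.gene_id not in partner:
            partner[near.gene_id] = gid
            annotation.truth.coexpressed_pairs.append((gid, near.gene_id))

    for gene in annotation.reference + annotation.candidates:
        gid = gene.gene_id
        labels = truth.labels.get(gid, set())
        if gid in cluster_of:
            base = CLUSTER_ARCHETYPES[cluster_of[gid]].copy()
        elif "constitutive" in labels or "readthrough_flag" in labels:
            base = np.full(6, 3.0)
        elif ("dna_contamination" in labels or "pre_mRNA_leftover" in labels
              or "repeat_decoy" in labels):
            base = np.full(6, 2.5)
        elif "coding_orf" in labels or "readthrough" in labels:
            base = CLUSTER_ARCHETYPES[int(rng.integers(5))].copy()
        elif gid in partner:
            src = partner[gid]
            base = CLUSTER_ARCHETYPES[cluster_of[src]] + rng.normal(0, 0.15, 6)
        elif gene.biotype == "protein_coding":
            base = np.full(6, float(rng.normal(2.5, 0.8)))
            if "divergent_high" in labels:
                base += config.divergent_fpkm_boost
        else:  # annotated lncRNA
            if rng.random() < 0.5:
                base = CLUSTER_ARCHETYPES[int(rng.integers(5))] * 0.8
            else:
                base = np.full(6, float(rng.normal(2.0, 0.7)))
        # nuclear conditions mirror the matching mesoderm time points
        nuc = np.array([base[0], base[2]])
        if "nuclear_enriched" in labels:
            nuc = nuc + config.nuclear_shift
        if "premrna_nuclear" in labels:
            nuc = nuc + config.premrna_nuclear_shift
        rows[gid] = np.concatenate([base, nuc])
    return pd.DataFrame.from_dict(rows, orient="index", columns=conditions)


def generate_expression(annotation: Annotation, config: SimConfig) -> SimExpression:
    """Log-normal FPKM with planted condition effects, strand counts and DE."""
    rng = np.random.default_rng(config.seed + 1)
    truth = annotation.truth
    means = _gene_profiles(annotation, config, rng)
    conditions = list(means.columns)
    reps = config.replicates
    cols = pd.MultiIndex.from_product([conditions, range(reps)],
                                      names=["condition", "replicate"])
    noise = rng.normal(0.0, config.log2_sigma, size=(means.shape[0], len(cols)))
    rep_log2 = pd.DataFrame(
        np.repeat(means.values, reps, axis=1) + noise,
        index=means.index, columns=cols,
    )
    fpkm = (2.0 ** rep_log2).T.groupby(level="condition").mean().T[conditions]
    expr = ExpressionTable(fpkm, level="gene")

    # stranded read counts for monoexonic candidates
    sc_rows = []
    for gene in annotation.candidates:
        labels = truth.labels.get(gene.gene_id, set())
        contaminated = "dna_contamination" in labels
        for t in gene.transcripts:
            if not t.is_monoexonic:
                continue
            for cond in NON_NUCLEAR_CONDITIONS:
                total = int(rng.poisson(200)) + 20
                r = (rng.uniform(0.35, 0.70) if contaminated
                     else rng.uniform(0.90, 0.99))
                sense = int(round(total * r))
                sc_rows.append((t.transcript_id, cond, sense, total - sense))
    strand_counts = pd.DataFrame(
        sc_rows, columns=["feature_id", "condition", "sense_reads", "antisense_reads"]
    )

    # DE table over the comparison registry (Welch t on log2 replicates, BH)
    de_genes = [g.gene_id for g in annotation.candidates] + [
        g.gene_id for g in annotation.reference if g.biotype == "lncRNA_annotated"
    ]
    de_rows = []
    for comp in COMPARISON_REGISTRY:
        a_code, b_code = comp.split("_VS_")
        ca = [c for c in COMPARISON_GROUPS[a_code]]
        cb = [c for c in COMPARISON_GROUPS[b_code]]
        xa = rep_log2.loc[de_genes, ca].to_numpy(float)
        xb = rep_log2.loc[de_genes, cb].to_numpy(float)
        lfc = xa.mean(axis=1) - xb.mean(axis=1)
        p = _st.ttest_ind(xa, xb, axis=1, equal_var=False).pvalue
        p = np.nan_to_num(p, nan=1.0)
        padj = bh_adjust(p)
        for g, f, q in zip(de_genes, lfc, padj):
            de_rows.append((comp, g, float(f), float(q)))
    de = DETable(pd.DataFrame(
        de_rows, columns=["comparison", "gene_id", "log2fc", "padj"]
    ))
    return SimExpression(expr, rep_log2, strand_counts, de)


def generate_strain_table(
    expr: ExpressionTable, truth: TruthTable, config: SimConfig,
    condition: str = "WE_68",
) -> pd.Series:
    """Mean FPKM of a second wild-type strain at one condition.

    Strain-specific genes are silenced (FPKM ~ 0.02-0.05); everything
    else tracks the first strain with modest noise.
    """
    rng = np.random.default_rng(config.seed + 2)
    a = expr.fpkm[condition]
    log2b = np.log2(a.to_numpy() + 0.1) + rng.normal(0, 0.25, len(a))
    b = pd.Series(2.0 ** log2b, index=a.index)
    silent = truth.genes_with("strain_specific")
    for gid in silent:
        if gid in b.index:
            b.loc[gid] = float(rng.uniform(0.02, 0.05))
    return b.clip(lower=0.0)


# -- tracks ----------------------------------------------------------------


@dataclass
class SimTracks:
    cage: pd.DataFrame                   # chrom, pos, strand, count
    repeats: list[GenomicInterval]
    conserved: list[tuple[GenomicInterval, float]]
    enhancers: list[GenomicInterval]
    sequences: dict[str, str]
    coding_evidence: pd.DataFrame        # transcript_id, method, value


_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length, p=[0.29, 0.21, 0.21, 0.29]))


def _orf_sequence(rng: np.random.Generator, length: int, orf_frac: float = 0.8) -> str:
    """Random sequence carrying one long stop-free ORF (~orf_frac of length)."""
    n_codons = max(20, int(length * orf_frac) // 3 - 2)
    codons = []
    while len(codons) < n_codons:
        c = "".join(rng.choice(_BASES, size=3))
        if c not in _STOPS:
            codons.append(c)
    orf = "ATG" + "".join(codons) + "TAA"
    flank = length - len(orf)
    left = flank // 2
    return _random_seq(rng, left) + orf + _random_seq(rng, flank - left)


def generate_tracks(annotation: Annotation, config: SimConfig) -> SimTracks:
    rng = np.random.default_rng(config.seed + 3)
    truth = annotation.truth
    cage_rows = []

    # peaks at the TRUE TSS of every clean candidate; designated
    # "unsupported" genes get sub-threshold peak heights
    for gene in annotation.candidates:
        labels = truth.labels.get(gene.gene_id, set())
        if "planted_novel_lncRNA" not in labels:
            continue
        for t in gene.transcripts:
            pos = truth.true_tss[t.transcript_id]
            if "cage_unsupported" in labels:
                lo, hi = config.cage_unsupported_height
            else:
                lo, hi = config.cage_supported_height
            cage_rows.append((t.chrom, pos, t.strand, int(rng.integers(lo, hi + 1))))
    # strong peaks at reference PCG TSSs
    for gene in annotation.reference:
        if gene.biotype != "protein_coding":
            continue
        t = gene.transcripts[0]
        cage_rows.append((t.chrom, t.tss, t.strand, int(rng.integers(100, 300))))
    # low scattered background tags
    for _ in range(200):
        chrom = list(config.chrom_sizes)[int(rng.integers(len(config.chrom_sizes)))]
        pos = int(rng.integers(10_000, config.chrom_sizes[chrom] - 10_000))
        st = "+" if rng.random() < 0.5 else "-"
        cage_rows.append((chrom, pos, st, int(rng.integers(1, 30))))
    cage = pd.DataFrame(cage_rows, columns=["chrom", "pos", "strand", "count"])
    cage = (
        cage.groupby(["chrom", "pos", "strand"], as_index=False)["count"].max()
    )

    # repeat mask: > 90% of each repeat decoy's exonic bases, plus random
    # intergenic repeats kept clear of all candidate exons
    repeats: list[GenomicInterval] = []
    cand_exons: list[GenomicInterval] = [
        e for g in annotation.candidates for t in g.transcripts for e in t.exons
    ]
    for gid in sorted(truth.genes_with("repeat_decoy")):
        gene = next(g for g in annotation.candidates if g.gene_id == gid)
        for t in gene.transcripts:
            for e in t.exons:
                cov = int(np.ceil(config.repeat_decoy_masked_frac * e.length))
                repeats.append(GenomicInterval(e.chrom, e.start, e.start + cov))
    placed = 0
    while placed < config.n_random_repeats:
        chrom = list(config.chrom_sizes)[int(rng.integers(len(config.chrom_sizes)))]
        start = int(rng.integers(10_000, config.chrom_sizes[chrom] - 10_000))
        iv = GenomicInterval(chrom, start, start + int(rng.integers(100, 500)))
        if any(iv.overlaps(e) for e in cand_exons):
            continue
        repeats.append(iv)
        placed += 1

    # conserved elements: random placement over gene bodies and intergenic
    lo, hi = config.conserved_score_range
    conserved = []
    all_exons = cand_exons + [
        e for g in annotation.reference for t in g.transcripts for e in t.exons
    ]
    for _ in range(config.n_conserved_elements):
        if rng.random() < 0.6 and all_exons:
            e = all_exons[int(rng.integers(len(all_exons)))]
            width = int(rng.integers(30, max(31, e.length)))
            start = e.start + int(rng.integers(0, max(1, e.length - width + 1)))
            iv = GenomicInterval(e.chrom, start, start + width)
        else:
            chrom = list(config.chrom_sizes)[int(rng.integers(len(config.chrom_sizes)))]
            start = int(rng.integers(10_000, config.chrom_sizes[chrom] - 10_000))
            iv = GenomicInterval(chrom, start, start + int(rng.integers(50, 400)))
        conserved.append((iv, float(rng.uniform(lo, hi))))

    # enhancers: intergenic intervals
    enhancers = []
    for _ in range(config.n_enhancers):
        chrom = list(config.chrom_sizes)[int(rng.integers(len(config.chrom_sizes)))]
        start = int(rng.integers(10_000, config.chrom_sizes[chrom] - 10_000))
        enhancers.append(GenomicInterval(chrom, start, start + int(rng.integers(300, 1500))))

    # transcript sequences (coding decoys carry a long planted ORF) and a
    # coding-evidence table emulating sequence-similarity search output
    sequences: dict[str, str] = {}
    ev_rows = []
    for gene in annotation.candidates:
        coding = truth.has(gene.gene_id, "coding_orf")
        for t in gene.transcripts:
            if coding:
                sequences[t.transcript_id] = _orf_sequence(rng, t.length)
                ev_rows.append((t.transcript_id, "blast",
                                float(10.0 ** -rng.uniform(6, 20))))
                if rng.random() < 0.5:
                    ev_rows.append((t.transcript_id, "phylocsf",
                                    float(rng.uniform(25, 120))))
            else:
                sequences[t.transcript_id] = _random_seq(rng, t.length)
    coding_evidence = pd.DataFrame(
        ev_rows, columns=["transcript_id", "method", "value"]
    )
    return SimTracks(cage, repeats, conserved, enhancers, sequences, coding_evidence)


# -- coverage (bidirectional promoter transcription) -----------------------


def generate_coverage(
    annotation: Annotation, config: SimConfig, condition: str = "Meso_34"
) -> pd.DataFrame:
    """Stranded 5'-read positions around PCG promoters for one condition.

    Divergent-high promoters receive strong antisense signal initiating
    within 500 nt upstream of the TSS; every expressed gene receives
    sense signal downstream proportional to its expression.
    """
    rng = np.random.default_rng(config.seed + 4)
    truth = annotation.truth
    rows = []
    for gene in annotation.reference:
        if gene.biotype != "protein_coding":
            continue
        t = gene.transcripts[0]
        tss = t.tss
        sign = 1 if t.strand != "-" else -1
        anti_strand = "-" if t.strand != "-" else "+"
        n_sense = int(rng.poisson(40))
        for _ in range(n_sense):
            off = int(rng.integers(0, 1000))
            rows.append((t.chrom, tss + sign * off, t.strand, 1))
        if truth.has(gene.gene_id, "divergent_high"):
            n_anti = int(rng.poisson(150)) + 50
            for _ in range(n_anti):
                off = int(rng.integers(1, 500))
                rows.append((t.chrom, tss - sign * off, anti_strand, 1))
        else:
            for _ in range(int(rng.poisson(0.3))):
                off = int(rng.integers(1, 1000))
                rows.append((t.chrom, tss - sign * off, anti_strand, 1))
    cov = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "count"])
    return cov.groupby(["chrom", "pos", "strand"], as_index=False)["count"].sum()


# -- viability -------------------------------------------------------------


def generate_viability(
    config: SimConfig, hom_probability: float | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Knockout-cross progeny counts under a binomial homozygote model.

    ``hom_probability`` 1/3 is the viable (Mendelian, 2:1 Het/Hom)
    scenario; pass a reduced value to emulate a lethal knockout.
    """
    p = config.hom_probability if hom_probability is None else hom_probability
    rng = np.random.default_rng(config.seed + 5 if seed is None else seed)
    rows = []
    lo, hi = config.viability_progeny
    for i in range(1, config.viability_lines + 1):
        for temp in (25, 29):
            n = int(rng.integers(lo, hi + 1))
            hom = int(rng.binomial(n, p)) if p > 0 else 0
            rows.append((f"KO_{i:03d}", temp, hom, n - hom))
    return pd.DataFrame(rows, columns=["line", "temperature", "n_hom", "n_het"])


# -- bundle ----------------------------------------------------------------


@dataclass
class Bundle:
    config: SimConfig
    reference: list[GeneModel]
    candidates: list[GeneModel]
    truth: TruthTable
    expr: ExpressionTable
    strand_counts: pd.DataFrame
    de: DETable
    cage: pd.DataFrame
    repeats: list[GenomicInterval]
    conserved: list[tuple[GenomicInterval, float]]
    enhancers: list[GenomicInterval]
    sequences: dict[str, str]
    coding_evidence: pd.DataFrame
    coverage: pd.DataFrame
    strain_b: pd.Series
    viability: pd.DataFrame


def generate_bundle(config: SimConfig) -> Bundle:
    """Run every generator and assemble the full in-memory input bundle."""
    ann = generate_annotation(config)  # TSS jitter already applied to models
    tracks = generate_tracks(ann, config)  # CAGE peaks go to the TRUE TSSs
    sim = generate_expression(ann, config)
    coverage = generate_coverage(ann, config)
    strain_b = generate_strain_table(sim.expr, ann.truth, config)
    viability = generate_viability(config)
    return Bundle(
        config, ann.reference, ann.candidates, ann.truth, sim.expr,
        sim.strand_counts, sim.de, tracks.cage, tracks.repeats,
        tracks.conserved, tracks.enhancers, tracks.sequences,
        tracks.coding_evidence, coverage, strain_b, viability,
    )


def write_bundle(bundle: Bundle, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_gtf(bundle.reference, out / "reference.gtf")
    write_gtf(bundle.candidates, out / "candidates.gtf")
    write_expression_tsv(bundle.expr, out / "expression_gene.tsv")
    bundle.strand_counts.to_csv(out / "strand_counts.tsv", sep="\t", index=False)
    bundle.de.table.to_csv(out / "de_table.tsv", sep="\t", index=False)
    bundle.cage.sort_values(["chrom", "pos", "strand"]).to_csv(
        out / "cage.tsv", sep="\t", index=False
    )
    write_bed([(iv, f"rep_{i}", 0.0) for i, iv in enumerate(bundle.repeats)],
              out / "repeats.bed")
    write_bed([(iv, f"ce_{i}", sc) for i, (iv, sc) in enumerate(bundle.conserved)],
              out / "conserved.bed")
    write_bed([(iv, f"enh_{i}", 0.0) for i, iv in enumerate(bundle.enhancers)],
              out / "enhancers.bed")
    write_fasta(bundle.sequences, out / "transcripts.fasta")
    bundle.coding_evidence.to_csv(out / "coding_evidence.tsv", sep="\t", index=False)
    bundle.coverage.sort_values(["chrom", "pos", "strand"]).to_csv(
        out / "coverage.tsv", sep="\t", index=False
    )
    bundle.strain_b.rename("fpkm").sort_index().to_csv(
        out / "strain_b_expression.tsv", sep="\t", index_label="feature_id"
    )
    bundle.viability.to_csv(out / "viability.tsv", sep="\t", index=False)
    bundle.truth.to_frame().to_csv(out / "truth_labels.tsv", sep="\t", index=False)
    bundle.truth.tss_frame().to_csv(out / "truth_tss.tsv", sep="\t", index=False)
    with (out / "config.yaml").open("w") as fh:
        yaml.safe_dump(bundle.config.to_dict(), fh, sort_keys=True)


def read_bundle(indir: str | Path) -> Bundle:
    ind = Path(indir)
    with (ind / "config.yaml").open() as fh:
        config = SimConfig.from_dict(yaml.safe_load(fh))
    reference = read_gtf(ind / "reference.gtf", provenance="reference")
    candidates = read_gtf(ind / "candidates.gtf", provenance="assembled")
    truth = TruthTable.from_frames(
        pd.read_csv(ind / "truth_labels.tsv", sep="\t"),
        pd.read_csv(ind / "truth_tss.tsv", sep="\t"),
    )
    expr = read_expression_tsv(ind / "expression_gene.tsv", level="gene")
    strand_counts = read_strand_counts_tsv(ind / "strand_counts.tsv")
    de = read_de_tsv(ind / "de_table.tsv")
    cage = read_cage_tsv(ind / "cage.tsv")
    repeats = read_bed(ind / "repeats.bed")
    conserved = read_scored_bed(ind / "conserved.bed")
    enhancers = read_bed(ind / "enhancers.bed")
    sequences = read_fasta(ind / "transcripts.fasta")
    coding_evidence = pd.read_csv(ind / "coding_evidence.tsv", sep="\t")
    coverage = pd.read_csv(ind / "coverage.tsv", sep="\t")
    strain_b = pd.read_csv(
        ind / "strain_b_expression.tsv", sep="\t", index_col=0
    )["fpkm"]
    viability = pd.read_csv(ind / "viability.tsv", sep="\t")
    return Bundle(
        config, reference, candidates, truth, expr, strand_counts, de, cage,
        repeats, conserved, enhancers, sequences, coding_evidence, coverage,
        strain_b, viability,
    )


# -- focused simulators for single analyses --------------------------------


def simulate_cluster_profiles(
    n_genes: int = 200, sigma: float = 0.2, seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Expression profiles drawn from the five staged archetypes plus noise.

    Returns (FPKM DataFrame over the six non-nuclear conditions, true
    archetype label per gene) for clustering-recovery experiments.
    """
    rng = np.random.default_rng(seed)
    k = len(CLUSTER_ARCHETYPES)
    labels = np.arange(n_genes) % k
    log2 = CLUSTER_ARCHETYPES[labels] + rng.normal(0, sigma, (n_genes, 6))
    idx = [f"G{i:04d}" for i in range(n_genes)]
    fpkm = pd.DataFrame(2.0 ** log2, index=idx,
                        columns=list(NON_NUCLEAR_CONDITIONS))
    return fpkm, pd.Series(labels + 1, index=idx, name="cluster")


def simulate_pair_correlation(
    n_pairs: int = 40,
    n_lnc: int = 60,
    n_pcg: int = 200,
    n_conditions: int = 7,
    coupling: float = 0.8,
    null: bool = False,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expression profiles for lncRNA-PCG correlation experiments.

    The first ``n_pairs`` lncRNAs are paired with dedicated PCGs; unless
    ``null``, the partner's profile is ``coupling * lnc + noise`` so the
    pair is genuinely co-expressed.  Returns (lnc profile matrix, pcg
    profile matrix, partner index per lncRNA).
    """
    rng = np.random.default_rng(seed)
    lnc = rng.normal(0, 1, (n_lnc, n_conditions))
    pcg = rng.normal(0, 1, (n_pcg, n_conditions))
    partners = rng.integers(0, n_pcg, size=n_lnc)
    if not null:
        for i in range(min(n_pairs, n_lnc)):
            j = partners[i]
            pcg[j] = coupling * lnc[i] + np.sqrt(1 - coupling**2) * rng.normal(
                0, 1, n_conditions
            )
    return lnc, pcg, partners
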