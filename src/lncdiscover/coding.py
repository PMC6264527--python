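"""ORF detection and the 2-of-3 coding-evidence voting classifier.

Three method families vote on coding potential: a coding-potential score
(CPAT-style logistic score, threshold 0.39), sequence-similarity search
(best BLAST/domain E-value, threshold 0.01 — one family, one vote), and
phylogenetic codon substitution frequency (PhyloCSF-style decibans,
threshold 20).  A transcript is called coding when at least two families
pass their thresholds.  Real scores are ingested from tables when
available; a documented sequence-composition surrogate supplies the
first family's score on synthetic data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

START = "ATG"
STOPS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class OrfRecord:
    transcript_id: str
    frame: int        # 0, 1 or 2
    start: int        # offset of the A of ATG
    end: int          # offset one past the stop codon
    length: int       # nt, multiple of 3, includes the stop codon

    def __post_init__(self) -> None:
        if self.length % 3 != 0 or self.length != self.end - self.start:
            raise ValueError("inconsistent ORF record")


def find_orfs(sequence: str, transcript_id: str = "") -> list[OrfRecord]:
    """All ATG -> stop ORFs in the three forward frames, longest first.

    For every ATG the first in-frame stop downstream closes the ORF;
    nested ATGs therefore produce their own (shorter) records.  ``N``
    breaks codon matching.  Unterminated ATGs yield nothing.
    """
    seq = sequence.upper()
    n = len(seq)
    orfs: list[OrfRecord] = []
    for frame in range(3):
        stop_after: dict[int, int] = {}
        # scan stops once per frame, then close each ATG on the next stop
        stops = [i for i in range(frame, n - 2, 3) if seq[i:i + 3] in STOPS]
        starts = [i for i in range(frame, n - 2, 3) if seq[i:i + 3] == START]
        si = 0
        for a in starts:
            while si < len(stops) and stops[si] < a:
                si += 1
            # first stop at or after this ATG, in frame
            j = si
            if j < len(stops):
                end = stops[j] + 3
                orfs.append(
                    OrfRecord(transcript_id, frame, a, end, end - a)
                )
    orfs.sort(key=lambda o: (-o.length, o.frame, o.start))
    return orfs


@dataclass
class CodingEvidence:
    transcript_id: str
    cpat_score: float | None = None
    blast_evalue: float | None = None
    domain_evalue: float | None = None
    phylocsf_score: float | None = None

    def __post_init__(self) -> None:
        for v in (self.blast_evalue, self.domain_evalue):
            if v is not None and v < 0:
                raise ValueError("E-values must be >= 0")


def classify_coding(
    evidence: CodingEvidence,
    cpat_thr: float = 0.39,
    evalue_thr: float = 0.01,
    phylocsf_thr: float = 20.0,
    inclusive: bool = False,
) -> tuple[int, str]:
    """Count method-family votes and call the label.

    One vote per family: CPAT score above ``cpat_thr``; best
    similarity E-value (BLAST or domain search, whichever is better)
    below ``evalue_thr``; PhyloCSF score above ``phylocsf_thr``.
    Comparisons are strict by default (``inclusive`` switches the
    boundary behaviour).  Absent scores contribute no vote.  Label is
    ``coding`` with >= 2 votes, else ``noncoding`` (a single vote keeps
    the noncoding label but is visible in the vote count).
    """
    def above(v, thr):
        return v is not None and (v >= thr if inclusive else v > thr)

    def below(v, thr):
        return v is not None and (v <= thr if inclusive else v < thr)

    votes = 0
    if above(evidence.cpat_score, cpat_thr):
        votes += 1
    evals = [e for e in (evidence.blast_evalue, evidence.domain_evalue)
             if e is not None]
    if evals and below(min(evals), evalue_thr):
        votes += 1
    if above(evidence.phylocsf_score, phylocsf_thr):
        votes += 1
    return votes, ("coding" if votes >= 2 else "noncoding")


def surrogate_coding_score(sequence: str) -> float:
    """Sequence-composition coding score in [0, 1].

    A logistic function of the longest-ORF coverage of the transcript
    (ORFs shorter than 60 nt are ignored), calibrated so that planted
    full-length-ORF decoys score far above 0.39 and random non-coding
    sequence falls below it.  Deterministic in the sequence.
    """
    if len(sequence) < 200:
        raise ValueError("surrogate score requires length >= 200")
    orfs = find_orfs(sequence)
    longest = next((o.length for o in orfs if o.length >= 60), 0)
    coverage = longest / len(sequence)
    return 1.0 / (1.0 + math.exp(-(12.0 * coverage - 6.0)))


def evidence_from_tables(
    transcript_id: str,
    sequences: dict[str, str] | None = None,
    scores: pd.DataFrame | None = None,
) -> CodingEvidence:
    """Assemble per-transcript evidence from a long-format score table
    (columns transcript_id, method, value; methods: cpat, blast, domain,
    phylocsf).  When no CPAT score is tabulated and the sequence is
    available, the surrogate supplies it."""
    ev = CodingEvidence(transcript_id)
    if scores is not None and len(scores):
        rows = scores[scores["transcript_id"] == transcript_id]
        for _, r in rows.iterrows():
            m = str(r["method"]).lower()
            v = float(r["value"])
            if m == "cpat":
                ev.cpat_score = v
            elif m == "blast":
                ev.blast_evalue = min(v, ev.blast_evalue or math.inf)
            elif m in ("domain", "rpstblastn"):
                ev.domain_evalue = min(v, ev.domain_evalue or math.inf)
            elif m == "phylocsf":
                ev.phylocsf_score = max(v, ev.phylocsf_score or -math.inf)
    if ev.cpat_score is None and sequences and transcript_id in sequences:
        seq = sequences[transcript_id]
        if len(seq) >= 200:
            ev.cpat_score = surrogate_coding_score(seq)
    return ev


def classify_transcripts(
    sequences: dict[str, str],
    scores: pd.DataFrame | None = None,
    **thresholds,
) -> pd.DataFrame:
    """Vote on every transcript; returns a tidy classification table."""
    rows = []
    for tid in sorted(sequences):
        ev = evidence_from_tables(tid, sequences, scores)
        votes, label = classify_coding(ev, **thresholds)
        rows.append(
            (tid, ev.cpat_score, ev.blast_evalue, ev.domain_evalue,
             ev.phylocsf_score, votes, label)
        )
    return pd.DataFrame(
        rows,
        columns=["transcript_id", "cpat_score", "blast_evalue",
                 "domain_evalue", "phylocsf_score", "votes", "label"],
    )
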