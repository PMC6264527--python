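"""Knockout-cross progeny statistics.

Knockout alleles are kept over a balancer chromosome; balancer
homozygotes die as embryos, so a viable knockout yields 2/3 heterozygous
and 1/3 homozygous adults — a 2:1 Het/Hom ratio.  Each cross is tested
against that Mendelian expectation with a two-sided exact binomial test
on the homozygote count at rate 1/3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .stats import exact_binomial_p

#: Published knockout-cross progeny counts for the three deleted lncRNA
#: loci (two independent alleles each for the first two), at normal and
#: restrictive temperatures: (line, temperature C, n_hom, n_het).
KO_PROGENY: tuple[tuple[str, int, int, int], ...] = (
    ("XLOC_004366 (a)", 25, 22, 47),
    ("XLOC_004366 (a)", 29, 16, 34),
    ("XLOC_004366 (b)", 25, 30, 61),
    ("XLOC_004366 (b)", 29, 25, 45),
    ("XLOC_012225 (a)", 25, 22, 40),
    ("XLOC_012225 (a)", 29, 17, 36),
    ("XLOC_012225 (b)", 25, 36, 65),
    ("XLOC_012225 (b)", 29, 23, 50),
    ("XLOC_012319", 25, 22, 42),
    ("XLOC_012319", 29, 16, 34),
)


@dataclass(frozen=True)
class ViabilityRecord:
    line: str
    temperature: int
    n_hom: int
    n_het: int

    def __post_init__(self) -> None:
        if self.n_hom < 0 or self.n_het < 0:
            raise ValueError("progeny counts must be non-negative")
        if self.n_hom + self.n_het == 0:
            raise ValueError("at least one progeny required")


def het_hom_ratio(rec: ViabilityRecord) -> float:
    """Het/Hom ratio rounded half-up to one decimal (2.174 -> 2.2).

    Returns ``inf`` when there are no homozygotes.
    """
    if rec.n_hom == 0:
        return math.inf
    r = rec.n_het / rec.n_hom
    return math.floor(r * 10 + 0.5) / 10


def mendelian_test(rec: ViabilityRecord, p0: float = 1.0 / 3.0) -> float:
    """Two-sided exact binomial p for the homozygote count at rate ``p0``."""
    n = rec.n_hom + rec.n_het
    return exact_binomial_p(rec.n_hom, n, p0)


def published_records() -> list[ViabilityRecord]:
    return [ViabilityRecord(*row) for row in KO_PROGENY]


def analyse_viability(records: list[ViabilityRecord] | pd.DataFrame) -> pd.DataFrame:
    """Ratio and Mendelian p-value per cross; accepts records or a table
    with columns line, temperature, n_hom, n_het."""
    if isinstance(records, pd.DataFrame):
        records = [
            ViabilityRecord(str(r["line"]), int(r["temperature"]),
                            int(r["n_hom"]), int(r["n_het"]))
            for _, r in records.iterrows()
        ]
    rows = []
    for rec in records:
        rows.append(
            (rec.line, rec.temperature, rec.n_hom, rec.n_het,
             het_hom_ratio(rec), mendelian_test(rec))
        )
    return pd.DataFrame(
        rows,
        columns=["line", "temperature", "n_hom", "n_het",
                 "het_hom_ratio", "mendelian_p"],
    )
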