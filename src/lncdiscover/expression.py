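"""Expression containers: FPKM tables, stranded locus read counts and
differential-expression tables (a consumed interface — DE is computed
upstream, e.g. by DESeq2; the synthetic generator emulates its output).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: The differential-expression comparison registry.  S = FACS-sorted
#: mesoderm, U = unsorted whole embryo, 34/46/68 = hours of development,
#: Nuclear34S/Nuclear68S = nuclear RNA from sorted cells.  The two
#: Nuclear*_VS_S* entries are the nuclear-vs-whole contrasts used for
#: nuclear-enrichment calls.
COMPARISON_REGISTRY: tuple[str, ...] = (
    "S34_VS_S46",
    "S34_VS_S68",
    "S34_VS_U34",
    "S46_VS_S68",
    "S46_VS_U46",
    "S68_VS_U68",
    "U34_VS_U46",
    "U34_VS_U68",
    "U46_VS_U68",
    "Nuclear34S_VS_Nuclear68S",
    "FacsSorted_VS_facsUnsorted",
    "Time34_VS_Time46",
    "Time34_VS_Time68",
    "Time46_VS_Time68",
    "Nuclear34S_VS_S34",
    "Nuclear68S_VS_S68",
)


@dataclass
class ExpressionTable:
    """FPKM matrix (features x named conditions), optionally backed by raw counts.

    ``level`` records whether features are genes or transcripts.
    """

    fpkm: pd.DataFrame
    level: str = "gene"  # "gene" | "transcript"
    counts: pd.DataFrame | None = None
    lengths: pd.Series | None = None
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.fpkm.values < 0).any():
            raise ValueError("FPKM values must be non-negative")
        if self.fpkm.columns.duplicated().any():
            raise ValueError("condition names must be unique")
        if self.level not in ("gene", "transcript"):
            raise ValueError(f"unknown level {self.level!r}")

    @property
    def conditions(self) -> list[str]:
        return list(self.fpkm.columns)

    @property
    def features(self) -> list[str]:
        return list(self.fpkm.index)

    def subset(self, conditions: Sequence[str]) -> "ExpressionTable":
        missing = [c for c in conditions if c not in self.fpkm.columns]
        if missing:
            raise KeyError(f"unknown condition(s): {missing}")
        return ExpressionTable(self.fpkm[list(conditions)], level=self.level)

    def max_fpkm(self, feature: str) -> float:
        return float(self.fpkm.loc[feature].max())


def compute_fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    library_sizes: pd.Series,
    level: str = "gene",
) -> ExpressionTable:
    """FPKM = count * 1e9 / (length * library size), per feature and condition."""
    lengths = lengths.reindex(counts.index)
    library_sizes = library_sizes.reindex(counts.columns)
    if (lengths <= 0).any():
        raise ValueError("feature lengths must be positive")
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    fpkm = counts.mul(1e9).div(lengths, axis=0).div(library_sizes, axis=1)
    return ExpressionTable(
        fpkm, level=level, counts=counts, lengths=lengths, library_sizes=library_sizes
    )


@dataclass(frozen=True)
class StrandReadCounts:
    """Sense/antisense read counts at one locus in one condition."""

    feature_id: str
    condition: str
    sense_reads: int
    antisense_reads: int

    def __post_init__(self) -> None:
        if self.sense_reads < 0 or self.antisense_reads < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def total(self) -> int:
        return self.sense_reads + self.antisense_reads

    @property
    def sense_ratio(self) -> float | None:
        """Reads on the annotated strand over total reads; None if no reads."""
        if self.total == 0:
            return None
        return self.sense_reads / self.total


def strand_counts_frame(records: Iterable[StrandReadCounts]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.feature_id, r.condition, r.sense_reads, r.antisense_reads)
            for r in records
        ],
        columns=["feature_id", "condition", "sense_reads", "antisense_reads"],
    )


@dataclass
class DETable:
    """Per-comparison differential-expression results (log2FC, BH-adjusted p)."""

    table: pd.DataFrame  # columns: comparison, gene_id, log2fc, padj
    registry: tuple[str, ...] = COMPARISON_REGISTRY

    def __post_init__(self) -> None:
        required = {"comparison", "gene_id", "log2fc", "padj"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"DE table needs columns {sorted(required)}")
        bad = ~self.table["comparison"].isin(self.registry)
        if bad.any():
            names = sorted(self.table.loc[bad, "comparison"].unique())
            raise ValueError(f"comparisons not in registry: {names}")
        p = self.table["padj"].to_numpy(float)
        if np.any((p < 0) | (p > 1) | np.isnan(p)):
            raise ValueError("adjusted p-values must lie in [0, 1]")

    def significant_genes(self, alpha: float = 0.01) -> set[str]:
        hit = self.table["padj"] < alpha
        return set(self.table.loc[hit, "gene_id"])

    def for_comparison(self, name: str) -> pd.DataFrame:
        if name not in self.registry:
            raise KeyError(f"comparison {name!r} not in registry")
        return self.table[self.table["comparison"] == name]
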