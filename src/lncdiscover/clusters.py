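"""Expression-pattern analyses: iterative k-means clustering, divergent
bidirectional promoter transcription, nuclear enrichment and
strain-specific expression."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .expression import DETable, ExpressionTable
from .models import GeneModel
from .stats import rank_sum_test


@dataclass
class ClusterResult:
    """Final gene -> cluster assignment with pruning diagnostics."""

    assignments: pd.Series            # gene id -> cluster id (1..k)
    centroids: pd.DataFrame           # cluster id x condition (scaled units)
    diagnostics: pd.DataFrame         # per gene: distance, correlation, stage lost
    unassigned: list[str] = field(default_factory=list)


def _scale(x: np.ndarray, how: str) -> np.ndarray:
    if how == "zscore":
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return (x - mu) / sd
    if how == "none":
        return x.copy()
    raise ValueError(f"unknown scaling {how!r}")


def iterative_kmeans(
    expr: pd.DataFrame,
    k1: int = 9,
    outlier1: float = 20.0,
    k2: int = 5,
    outlier2: float = 1.5,
    min_corr: float = 0.905,
    seed: int = 0,
    scaling: str = "zscore",
    n_init: int = 50,
) -> ClusterResult:
    """Two-round k-means with outlier pruning and a profile-correlation gate.

    Round 1 clusters per-gene scaled profiles into ``k1`` groups and
    drops members farther than ``outlier1`` from their centroid (the
    distance is Euclidean — equivalently, distance in the full
    rotation-only principal-component space) plus singleton clusters.
    Round 2 re-clusters survivors into ``k2`` groups with threshold
    ``outlier2`` and drops clusters below two members.  Finally, genes
    whose Pearson correlation with their cluster's per-condition median
    profile is <= ``min_corr`` are removed.
    """
    if len(expr) < k1:
        raise ValueError(f"need >= {k1} genes, got {len(expr)}")
    expr = expr.sort_index()  # row-order invariance
    genes = np.array(expr.index)
    x = _scale(expr.to_numpy(float), scaling)
    lost: dict[str, str] = {}

    def prune(xm, gm, k, thr, rs):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=rs).fit(xm)
        lab = km.labels_
        dist = np.linalg.norm(xm - km.cluster_centers_[lab], axis=1)
        keep = dist <= thr
        for g in gm[~keep]:
            lost[g] = "centroid_distance"
        lab2 = lab[keep]
        sizes = pd.Series(lab2).value_counts()
        small = set(sizes[sizes < 2].index)
        keep2 = np.array([l not in small for l in lab2])
        for g in gm[keep][~keep2]:
            lost[g] = "singleton_cluster"
        return xm[keep][keep2], gm[keep][keep2], lab2[keep2], dist

    x1, g1, _, _ = prune(x, genes, k1, outlier1, seed)
    x2, g2, lab2, dist2 = prune(x1, g1, min(k2, max(2, len(g1))), outlier2, seed + 1)

    # correlation with the cluster's per-condition median profile
    assignments: dict[str, int] = {}
    rows = []
    centroids = {}
    for cl in sorted(set(lab2)):
        m = lab2 == cl
        median = np.median(x2[m], axis=0)
        centroids[cl + 1] = median
        for g, prof in zip(g2[m], x2[m]):
            sd = prof.std() * median.std()
            r = (
                float(np.corrcoef(prof, median)[0, 1]) if sd > 0 else 0.0
            )
            rows.append((g, cl + 1, r))
            if r > min_corr:
                assignments[g] = cl + 1
            else:
                lost[g] = "low_profile_correlation"
    diag = pd.DataFrame(rows, columns=["gene_id", "cluster", "median_corr"])
    assigned = pd.Series(assignments, dtype=int, name="cluster").sort_index()
    cent = pd.DataFrame(centroids, index=expr.columns).T
    cent.index.name = "cluster"
    return ClusterResult(
        assigned, cent, diag, unassigned=sorted(lost),
    )


# -- divergent transcription ----------------------------------------------


@dataclass
class DivergenceProfile:
    gene_id: str
    sense: np.ndarray       # 200 bins over TSS +/- 1 kb, 5'->3' orientation
    antisense: np.ndarray   # 200 bins, upstream-antisense on the left
    antisense_rank_signal: float = 0.0
    tercile: str = ""       # top | middle | bottom
    edge_padded: bool = False


def _binned(cov: dict[int, int], lo: int, n_bins: int, bin_size: int,
            flip: bool) -> np.ndarray:
    out = np.zeros(n_bins)
    for pos, c in cov.items():
        b = (pos - lo) // bin_size
        if 0 <= b < n_bins:
            out[b] += c
    return out[::-1] if flip else out


def divergent_profiles(
    pcgs: Sequence[GeneModel],
    coverage: pd.DataFrame,
    half_window: int = 1000,
    bin_size: int = 10,
    upstream_rank_window: int = 1000,
    chrom_sizes: dict[str, int] | None = None,
) -> list[DivergenceProfile]:
    """Strand-split 10-nt binned read profiles around each PCG TSS.

    Profiles are orientation-normalised: bin 0 is 1 kb upstream of the
    TSS regardless of gene strand, so upstream-antisense signal always
    sits on the left.  Genes are ranked by summed antisense signal within
    ``upstream_rank_window`` nt upstream and split into terciles.
    """
    n_bins = 2 * half_window // bin_size
    cov: dict[tuple[str, str], dict[int, int]] = {}
    for _, row in coverage.iterrows():
        cov.setdefault((row["chrom"], row["strand"]), {})[int(row["pos"])] = int(
            row["count"]
        )
    profiles = []
    for g in pcgs:
        t = g.longest_isoform()
        tss = t.tss
        lo = tss - half_window
        flip = t.strand == "-"
        padded = lo < 0
        if chrom_sizes and t.chrom in chrom_sizes:
            padded = padded or tss + half_window > chrom_sizes[t.chrom]
        sense_strand = t.strand if t.strand != "." else "+"
        anti_strand = "-" if sense_strand == "+" else "+"
        sense = _binned(cov.get((t.chrom, sense_strand), {}), lo, n_bins,
                        bin_size, flip)
        anti = _binned(cov.get((t.chrom, anti_strand), {}), lo, n_bins,
                       bin_size, flip)
        k = upstream_rank_window // bin_size
        upstream_bins = anti[n_bins // 2 - k: n_bins // 2]
        prof = DivergenceProfile(
            g.gene_id, sense, anti,
            antisense_rank_signal=float(upstream_bins.sum()),
            edge_padded=padded,
        )
        profiles.append(prof)
    ranked = sorted(profiles, key=lambda p: -p.antisense_rank_signal)
    n = len(ranked)
    for i, p in enumerate(ranked):
        if i < n / 3:
            p.tercile = "top"
        elif i < 2 * n / 3:
            p.tercile = "middle"
        else:
            p.tercile = "bottom"
    return profiles


def compare_terciles(
    profiles: Sequence[DivergenceProfile], expr: pd.Series
) -> tuple[float, dict[str, float]]:
    """Top-vs-bottom tercile expression comparison (two-sided rank-sum)."""
    top = [float(expr[p.gene_id]) for p in profiles
           if p.tercile == "top" and p.gene_id in expr.index]
    bottom = [float(expr[p.gene_id]) for p in profiles
              if p.tercile == "bottom" and p.gene_id in expr.index]
    if len(top) < 3 or len(bottom) < 3:
        raise ValueError("terciles too small for a comparison")
    _, p = rank_sum_test(top, bottom)
    return p, {
        "median_top": float(np.median(top)),
        "median_bottom": float(np.median(bottom)),
    }


# -- nuclear enrichment and strain specificity ----------------------------


def nuclear_enriched(
    de: DETable,
    alpha: float = 0.01,
    comparisons: Sequence[str] = ("Nuclear34S_VS_S34", "Nuclear68S_VS_S68"),
) -> set[str]:
    """Genes significantly higher in nuclear fractions than whole cells."""
    tab = de.table
    hit = (
        tab["comparison"].isin(comparisons)
        & (tab["padj"] < alpha)
        & (tab["log2fc"] > 0)
    )
    return set(tab.loc[hit, "gene_id"])


@dataclass
class StrainComparison:
    shared: set[str]
    intermediate: set[str]
    off_in_b: set[str]

    @property
    def selected(self) -> set[str]:
        return self.shared | self.intermediate | self.off_in_b


def strain_specific(
    expr_a: pd.Series,
    expr_b: pd.Series,
    thr_on: float = 1.0,
    thr_off: float = 0.1,
) -> StrainComparison:
    """Partition genes expressed in strain A (FPKM >= ``thr_on``) by their
    level in strain B: shared (>= thr_on), intermediate, or virtually off
    (< ``thr_off``)."""
    common = expr_a.index.intersection(expr_b.index)
    if len(common) == 0:
        raise ValueError("expression tables share no feature ids")
    a = expr_a[common]
    b = expr_b[common]
    on = a[a >= thr_on].index
    shared = set(on[(b[on] >= thr_on)])
    off = set(on[(b[on] < thr_off)])
    intermediate = set(on) - shared - off
    return StrainComparison(shared, intermediate, off)
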