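"""Shared statistics: BH adjustment, rank tests, exact binomial."""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U); returns (statistic, p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    if np.ptp(np.concatenate([x, y])) == 0:
        # all values identical: no evidence of a shift
        return 0.0, 1.0
    res = _st.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def exact_binomial_p(k: int, n: int, p0: float) -> float:
    """Two-sided exact binomial p-value (minlike: sum of outcomes with
    pmf <= pmf(observed))."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(_st.binomtest(k, n, p0, alternative="two-sided").pvalue)
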