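"""Nonparametric test primitives used by several analysis stages.

Friedman and Wilcoxon signed-rank statistics are implemented here with the
tie conventions the pipeline relies on (midranks throughout, normal
approximation with continuity correction for the signed-rank z), rather than
delegating to :mod:`scipy.stats`, whose Friedman implementation returns NaN
for fully tied blocks.  scipy is used as an independent cross-check in the
test suite.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
from scipy import stats


class FriedmanResult(NamedTuple):
    statistic: float
    pvalue: float
    df: int


class SignedRankResult(NamedTuple):
    z: float
    pvalue: float
    n_nonzero: int


def friedman_test(table: np.ndarray) -> FriedmanResult:
    """Friedman rank test on an ``n_blocks × k_treatments`` table.

    Midranks resolve within-block ties; the statistic carries the standard
    tie correction.  A table whose every block is fully tied carries no rank
    information and yields statistic 0 with p = 1.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("table must be 2D (blocks × treatments)")
    n, k = table.shape
    if n < 1 or k < 2:
        raise ValueError("need at least one block and two treatments")

    ranks = stats.rankdata(table, axis=1)
    col_sums = ranks.sum(axis=0)
    uncorrected = 12.0 / (n * k * (k + 1)) * np.sum(col_sums**2) - 3.0 * n * (k + 1)

    # tie correction: per block, sum of (t^3 - t) over tie groups
    tie_term = 0.0
    for row in table:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_term / (n * k * (k**2 - 1))
    if correction <= 0:
        return FriedmanResult(0.0, 1.0, k - 1)
    statistic = max(uncorrected / correction, 0.0)
    pvalue = float(stats.chi2.sf(statistic, k - 1))
    return FriedmanResult(float(statistic), pvalue, k - 1)


def signed_rank_test(
    diffs: np.ndarray,
    exact_below: int = 25,
) -> SignedRankResult:
    """Wilcoxon signed-rank test of paired differences against zero.

    Returns a z statistic from the normal approximation with tie and
    continuity corrections; positive z means differences tend to be positive.
    For fewer than ``exact_below`` nonzero, untied differences the p-value is
    replaced by the exact distribution (the z is still reported).
    """
    diffs = np.asarray(diffs, dtype=float)
    if diffs.ndim != 1:
        raise ValueError("diffs must be 1D")
    nz = diffs[diffs != 0.0]
    n = nz.size
    if n == 0:
        warnings.warn("all differences are zero; signed-rank test degenerate")
        return SignedRankResult(0.0, 1.0, 0)

    ranks = stats.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(nz), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    if var <= 0:
        return SignedRankResult(0.0, 1.0, n)
    delta = w_plus - mu
    z = (delta - 0.5 * np.sign(delta)) / np.sqrt(var)
    pvalue = 2.0 * float(stats.norm.sf(abs(z)))

    has_ties = np.any(tie_counts > 1)
    if n < exact_below and not has_ties:
        pvalue = float(stats.wilcoxon(nz, method="exact").pvalue)
    return SignedRankResult(float(z), min(pvalue, 1.0), n)


def bh_fdr(pvalues: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg rejection flags at level ``q``."""
    pvalues = np.asarray(pvalues, dtype=float)
    m = pvalues.size
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(pvalues, kind="stable")
    ranked = pvalues[order]
    thresh = q * (np.arange(1, m + 1) / m)
    below = ranked <= thresh
    flags = np.zeros(m, dtype=bool)
    if below.any():
        cutoff = np.max(np.nonzero(below)[0])
        flags[order[: cutoff + 1]] = True
    return flags
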