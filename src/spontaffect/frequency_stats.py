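"""Group-level inference on label frequencies.

Occupancy counts are compared across the seven categories with a Friedman
test, against the 1/7 chance rate and pairwise with Wilcoxon signed-rank
tests under Benjamini–Hochberg FDR control, and related to per-subject mood
and trait covariates through single-covariate binomial GLMs whose slopes are
interpretable as odds ratios (e^β per covariate unit).  A subsampling
routine checks that mean frequencies are robust to drawing small healthy
subsamples.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._nonparam import FriedmanResult, SignedRankResult, bh_fdr, friedman_test, signed_rank_test
from .datatypes import EMOTIONS, N_EMOTIONS, FrequencyTable

CHANCE_RATE = 1.0 / N_EMOTIONS


def _counts_matrix(freqs: Sequence[FrequencyTable]) -> np.ndarray:
    return np.stack([ft.counts for ft in freqs])


def friedman_across_categories(freqs: Sequence[FrequencyTable]) -> FriedmanResult:
    """Friedman test of non-uniform occupancy across the 7 categories.

    Subjects are blocks, categories treatments.  Invariant to relabeling
    categories and to subject order; all-uniform counts give statistic 0.
    """
    if len(freqs) < 2:
        raise ValueError("need at least 2 subjects")
    return friedman_test(_counts_matrix(freqs))


def wilcoxon_vs_chance(
    freqs: Sequence[FrequencyTable], emotion: int
) -> SignedRankResult:
    """Signed-rank test of one category's occupancy against the 1/7 chance rate.

    Positive z means the category occurs more often than chance.  At least 6
    subjects are required for the normal approximation to be meaningful.
    """
    if len(freqs) < 6:
        raise ValueError("need at least 6 subjects for the signed-rank z")
    props = np.array([ft.proportions[emotion] for ft in freqs])
    return signed_rank_test(props - CHANCE_RATE)


@dataclass
class RankComparison:
    """One pairwise category comparison of occupancy ranks."""

    emotion_1: int
    emotion_2: int
    estimate: float  # mean rank difference (emotion_1 − emotion_2)
    lower: float
    upper: float
    pvalue: float  # uncorrected signed-rank p on count differences
    z: float
    fdr_pass: bool


def pairwise_rank_comparisons(
    freqs: Sequence[FrequencyTable],
    q: float = 0.05,
    alpha: float = 0.05,
) -> list[RankComparison]:
    """All 21 pairwise occupancy comparisons with FDR control.

    Estimates are mean within-subject rank differences with simultaneous
    bounds from the Friedman post-hoc (Nemenyi) construction: the half-width
    is q_{α,k,∞}/√2 · √(k(k+1)/(6n)) with the studentized-range quantile.
    p-values come from signed-rank tests on the raw count differences and
    are flagged by Benjamini–Hochberg at level ``q``.
    """
    counts = _counts_matrix(freqs)
    n, k = counts.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    ranks = stats.rankdata(counts, axis=1)
    mean_ranks = ranks.mean(axis=0)
    crit = stats.studentized_range.ppf(1 - alpha, k, 1e7) / np.sqrt(2.0)
    half_width = crit * np.sqrt(k * (k + 1) / (6.0 * n))

    results = []
    pvals = []
    for e1, e2 in itertools.combinations(range(k), 2):
        est = float(mean_ranks[e1] - mean_ranks[e2])
        sr = signed_rank_test(counts[:, e1] - counts[:, e2].astype(float))
        results.append(
            RankComparison(
                emotion_1=e1,
                emotion_2=e2,
                estimate=est,
                lower=est - half_width,
                upper=est + half_width,
                pvalue=sr.pvalue,
                z=sr.z,
                fdr_pass=False,
            )
        )
        pvals.append(sr.pvalue)
    flags = bh_fdr(np.asarray(pvals), q=q)
    for rc, flag in zip(results, flags):
        rc.fdr_pass = bool(flag)
    return results


def rank_comparisons_frame(results: Sequence[RankComparison]) -> pd.DataFrame:
    """Tidy table of pairwise comparisons (one row per category pair)."""
    return pd.DataFrame(
        {
            "model_1": [EMOTIONS[rc.emotion_1] for rc in results],
            "model_2": [EMOTIONS[rc.emotion_2] for rc in results],
            "lower": [rc.lower for rc in results],
            "estimate": [rc.estimate for rc in results],
            "upper": [rc.upper for rc in results],
            "p_unc": [rc.pvalue for rc in results],
            "fdr_pass": [rc.fdr_pass for rc in results],
        }
    )


class CovariateGLMResult(NamedTuple):
    emotion: int
    covariate: str
    beta: float  # log-odds per covariate unit
    se: float
    t: float
    df: int
    pvalue: float
    odds_ratio: float
    ci_lower: float  # 95% CI for beta
    ci_upper: float
    converged: bool


def covariate_glm(
    freqs: Sequence[FrequencyTable],
    covariates: pd.DataFrame,
    emotion: int,
    covariate_name: str,
) -> CovariateGLMResult:
    """Binomial GLM of one category's occupancy on a single covariate.

    The response is (count, T − count) per subject with a logit link; the
    slope β is the change in log-odds of occupancy per covariate unit and
    e^β its odds ratio.  Inference uses a t distribution with n − 2 degrees
    of freedom.  Complete separation (every count 0 or T) is flagged as
    non-converged rather than raising.
    """
    cov_map = dict(zip(covariates["subject_id"], covariates[covariate_name]))
    counts = np.array([ft.counts[emotion] for ft in freqs], dtype=float)
    totals = np.array([ft.total for ft in freqs], dtype=float)
    x = np.array([cov_map[ft.subject_id] for ft in freqs], dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("covariate contains non-finite values")
    n = len(freqs)
    df = n - 2
    if df < 1:
        raise ValueError("need at least 3 subjects")

    degenerate = np.all(counts == 0) or np.all(counts == totals)
    exog = sm.add_constant(x)
    endog = np.column_stack([counts, totals - counts])
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
        beta = float(fit.params[1])
        se = float(fit.bse[1])
        converged = bool(fit.converged) and not degenerate and np.isfinite(se)
    except Exception:
        beta, se, converged = float("nan"), float("nan"), False
    if converged and se > 0:
        t = beta / se
        pvalue = 2.0 * float(stats.t.sf(abs(t), df))
        tcrit = float(stats.t.ppf(0.975, df))
        ci = (beta - tcrit * se, beta + tcrit * se)
    else:
        t, pvalue, ci = float("nan"), float("nan"), (float("nan"), float("nan"))
    return CovariateGLMResult(
        emotion=emotion,
        covariate=covariate_name,
        beta=beta,
        se=se,
        t=t,
        df=df,
        pvalue=pvalue,
        odds_ratio=float(np.exp(beta)),
        ci_lower=ci[0],
        ci_upper=ci[1],
        converged=converged,
    )


def covariate_glm_all(
    freqs: Sequence[FrequencyTable],
    covariates: pd.DataFrame,
    covariate_name: str,
) -> pd.DataFrame:
    """One GLM per emotion for a single self-report measure (7 models)."""
    rows = []
    for e in range(N_EMOTIONS):
        res = covariate_glm(freqs, covariates, e, covariate_name)
        rows.append(
            {
                "emotion": EMOTIONS[e],
                "covariate": covariate_name,
                "beta": res.beta,
                "t": res.t,
                "df": res.df,
                "p_unc": res.pvalue,
                "odds_ratio": res.odds_ratio,
                "converged": res.converged,
            }
        )
    return pd.DataFrame(rows)


class SubsampleRobustness(NamedTuple):
    mean_r: float
    sd_r: float
    n_iter: int
    k: int


def subsample_robustness(
    freqs: Sequence[FrequencyTable],
    subset_flags: Sequence[bool] | None = None,
    n_iter: int = 1000,
    k: int = 21,
    seed: int = 0,
) -> SubsampleRobustness:
    """Stability of mean category frequencies under random subsampling.

    Repeatedly draws ``k`` flagged subjects without replacement and
    correlates the subsample's mean category proportions with the full
    sample's; reports the mean and sd of the correlation over iterations.
    ``subset_flags`` marks the eligible (e.g. healthy) subjects.
    """
    props = np.stack([ft.proportions for ft in freqs])
    n = props.shape[0]
    flags = (
        np.ones(n, dtype=bool) if subset_flags is None else np.asarray(subset_flags, bool)
    )
    eligible = np.flatnonzero(flags)
    if k > eligible.size:
        raise ValueError(f"k={k} exceeds the {eligible.size} flagged subjects")
    full_mean = props.mean(axis=0)
    rng = np.random.default_rng(seed)
    rs = np.empty(n_iter)
    for it in range(n_iter):
        pick = rng.choice(eligible, size=k, replace=False)
        rs[it] = stats.pearsonr(props[pick].mean(axis=0), full_mean)[0]
    return SubsampleRobustness(float(rs.mean()), float(rs.std(ddof=1)), n_iter, k)
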