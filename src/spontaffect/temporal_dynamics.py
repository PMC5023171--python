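"""Temporal structure of classifier scores over the scanning period.

Four complementary views: per-subject linear trends with group one-sample t
inference; smoothing-spline time courses whose coherence across subjects is
assessed by a leave-one-subject-out cross-validated correlation; Friedman
tests of a time effect per emotion; and wavelet-resampled ("wavestrapped")
surrogate time series that preserve autocorrelation, used to build a null
distribution for the category-frequency Friedman statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pywt
from scipy import stats
from scipy.interpolate import make_smoothing_spline

from ._nonparam import FriedmanResult, friedman_test
from .datatypes import N_EMOTIONS, ScoreMatrix

DEFAULT_WAVELET = "db4"
_WT_MODE = "periodization"


def _stack_scores(cohort: Sequence[ScoreMatrix]) -> np.ndarray:
    """Cohort scores as an (n_subjects, T, 7) array; T must agree."""
    lengths = {sm.n_timepoints for sm in cohort}
    if len(lengths) != 1:
        raise ValueError(f"subjects have unequal series lengths: {sorted(lengths)}")
    return np.stack([sm.scores for sm in cohort])


@dataclass
class TrendResult:
    """Per-subject OLS slopes of score on centered time, per emotion."""

    slopes: np.ndarray  # (n_subjects, 7), score units per timepoint
    t: np.ndarray  # (7,) group one-sample t
    pvalues: np.ndarray  # (7,)
    df: int
    degenerate: np.ndarray  # (7,) True where slopes had zero variance


def linear_trend(cohort: Sequence[ScoreMatrix]) -> TrendResult:
    """Linear time trends: subject-level OLS slope, group-level t test.

    The regressor is the centered volume index, so slopes are in score units
    per timepoint; an increasing series yields a positive slope.  Group
    inference is a one-sample t test of the slopes against zero with
    ``n_subjects − 1`` degrees of freedom.  Emotions whose slopes are
    identical across subjects have no slope variance and are flagged
    degenerate (t = NaN).
    """
    scores = _stack_scores(cohort)
    n, T, _ = scores.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    time = np.arange(T) - (T - 1) / 2.0
    slopes = np.tensordot(scores, time, axes=([1], [0])) / np.dot(time, time)

    sd = slopes.std(axis=0, ddof=1)
    degenerate = sd == 0.0
    t = np.full(N_EMOTIONS, np.nan)
    p = np.full(N_EMOTIONS, np.nan)
    ok = ~degenerate
    if ok.any():
        res = stats.ttest_1samp(slopes[:, ok], 0.0, axis=0)
        t[ok] = res.statistic
        p[ok] = res.pvalue
    if degenerate.any():
        warnings.warn("zero slope variance for some emotions; t undefined")
    return TrendResult(slopes=slopes, t=t, pvalues=p, df=n - 1, degenerate=degenerate)


@dataclass
class SplineCoherence:
    """Cross-validated coherence of smoothing-spline time courses."""

    fitted: np.ndarray  # (n_subjects, T) per-subject smooth fits
    r_cv: np.ndarray  # (n_subjects,), NaN where excluded
    mean_r_cv: float
    n_excluded: int  # subjects with constant fitted curve


def fit_spline_coherence(
    cohort: Sequence[ScoreMatrix] | np.ndarray,
    emotion: int | None = None,
    lam: float | None = None,
) -> SplineCoherence:
    """Smoothing-spline fits per subject and leave-one-subject-out coherence.

    A cubic smoothing spline is fit to each subject's score series (penalty
    chosen by generalized cross-validation unless ``lam`` is given — the fit
    may therefore use a different effective number of parameters per
    subject).  Subject i's coherence r_cv(i) is the Pearson correlation
    between their fitted curve and the pointwise mean of all other subjects'
    fitted curves; the group value is the mean over subjects.  Subjects whose
    fitted curve is constant have undefined correlation and are excluded
    with a warning.
    """
    if isinstance(cohort, np.ndarray):
        series = np.asarray(cohort, dtype=float)
        if series.ndim != 2:
            raise ValueError("array input must be (n_subjects, T)")
    else:
        if emotion is None:
            raise ValueError("emotion index required with ScoreMatrix input")
        series = _stack_scores(cohort)[:, :, emotion]
    n, T = series.shape
    if n < 3:
        raise ValueError("cross-validated coherence needs at least 3 subjects")
    x = np.arange(T, dtype=float)
    fitted = np.empty_like(series)
    for i in range(n):
        fitted[i] = make_smoothing_spline(x, series[i], lam=lam)(x)

    r_cv = np.full(n, np.nan)
    total = fitted.sum(axis=0)
    n_excluded = 0
    for i in range(n):
        others_mean = (total - fitted[i]) / (n - 1)
        if np.ptp(fitted[i]) == 0 or np.ptp(others_mean) == 0:
            n_excluded += 1
            continue
        r_cv[i] = stats.pearsonr(fitted[i], others_mean)[0]
    if n_excluded:
        warnings.warn(f"{n_excluded} subjects excluded (constant fitted curve)")
    valid = r_cv[~np.isnan(r_cv)]
    if valid.size == 0:
        raise ValueError("no subject produced a defined coherence")
    return SplineCoherence(
        fitted=fitted,
        r_cv=r_cv,
        mean_r_cv=float(valid.mean()),
        n_excluded=n_excluded,
    )


def friedman_over_time(
    cohort: Sequence[ScoreMatrix], emotion: int
) -> FriedmanResult:
    """Friedman test of a time effect on one emotion's scores.

    Subjects are blocks and timepoints are treatments; the statistic is
    invariant to any timepoint permutation applied identically to all
    subjects.
    """
    series = _stack_scores(cohort)[:, :, emotion]
    if series.shape[1] < 2:
        raise ValueError("need at least 2 timepoints")
    return friedman_test(series)


def _permute_within_rows(arr: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute each row of a 2D array along its last axis."""
    keys = rng.random(arr.shape)
    return np.take_along_axis(arr, np.argsort(keys, axis=-1), axis=-1)


def _surrogate_block(X: np.ndarray, rng: np.random.Generator, wavelet: str) -> np.ndarray:
    """Wavelet surrogates of each row of an (n_series, T) block."""
    T = X.shape[-1]
    w = pywt.Wavelet(wavelet)
    level = pywt.dwt_max_level(T, w.dec_len)
    if level < 1:
        raise ValueError("series too short for a wavelet decomposition")
    coeffs = pywt.wavedec(X, w, mode=_WT_MODE, level=level, axis=-1)
    # approximation band kept intact; detail coefficients permuted per level
    shuffled = [coeffs[0]] + [_permute_within_rows(d, rng) for d in coeffs[1:]]
    rec = pywt.waverec(shuffled, w, mode=_WT_MODE, axis=-1)
    return rec[..., :T]


def wavelet_surrogate(
    series: np.ndarray,
    seed: int | np.random.Generator = 0,
    wavelet: str = DEFAULT_WAVELET,
) -> np.ndarray:
    """One wavelet-resampled surrogate of a 1D series.

    The discrete wavelet transform (Daubechies-4 by default, periodic
    boundary handling, maximal dyadic depth) is applied, detail coefficients
    are randomly permuted within each level, the approximation band is left
    intact, and the inverse transform returns the surrogate.  Per-level
    coefficient multisets — hence per-level energy and, approximately, the
    autocorrelation structure — are preserved exactly.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or series.size < 4:
        raise ValueError("series must be 1D with at least 4 samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _surrogate_block(series[None, :], rng, wavelet)[0]


@dataclass
class SurrogateEnsemble:
    """Null distribution of the category-frequency Friedman statistic."""

    observed_chi2: float
    null_chi2: np.ndarray  # (n_iter,)
    pvalue: float  # add-one empirical p
    n_iter: int
    observed_counts: np.ndarray  # (n_subjects, 7)


def _counts_from_scores(scores: np.ndarray) -> np.ndarray:
    """Label counts per subject from an (n_subjects, T, 7) score array."""
    labels = np.argmax(scores, axis=-1)
    n = scores.shape[0]
    counts = np.zeros((n, N_EMOTIONS), dtype=int)
    for i in range(n):
        counts[i] = np.bincount(labels[i], minlength=N_EMOTIONS)
    return counts


def surrogate_null_frequencies(
    cohort: Sequence[ScoreMatrix],
    n_iter: int = 100,
    seed: int = 0,
    wavelet: str = DEFAULT_WAVELET,
) -> SurrogateEnsemble:
    """Surrogate null for the across-category frequency Friedman test.

    Each iteration independently wavestraps every subject's seven score
    series, relabels volumes by argmax, counts category frequencies, and
    computes the Friedman statistic across categories (subjects as blocks).
    The empirical p-value uses the add-one permutation convention
    ``(1 + #{null ≥ observed}) / (n_iter + 1)``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be positive")
    scores = _stack_scores(cohort)  # (n, T, 7)
    n, T, _ = scores.shape
    observed_counts = _counts_from_scores(scores)
    observed = friedman_test(observed_counts).statistic

    rng = np.random.default_rng(seed)
    flat = scores.transpose(0, 2, 1).reshape(n * N_EMOTIONS, T)
    null = np.empty(n_iter)
    for it in range(n_iter):
        sur = _surrogate_block(flat, rng, wavelet)
        sur_scores = sur.reshape(n, N_EMOTIONS, T).transpose(0, 2, 1)
        null[it] = friedman_test(_counts_from_scores(sur_scores)).statistic
    pvalue = (1.0 + np.sum(null >= observed)) / (n_iter + 1.0)
    return SurrogateEnsemble(
        observed_chi2=float(observed),
        null_chi2=null,
        pvalue=float(pvalue),
        n_iter=n_iter,
        observed_counts=observed_counts,
    )
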