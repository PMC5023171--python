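"""Concordance between decoded brain states and experience-sampling reports.

During unconstrained rest, participants periodically rate how they feel by
moving a cursor on a wheel-shaped response screen: 16 emotion terms arranged
radially, four intensity rings per spoke, and a central disk for neutral.
Cursor positions are mapped to the seven decodable emotion categories
(terms outside the model vocabulary are dropped), the classifier scores of
the volumes preceding each rating are averaged, and concordance is assessed
three ways: congruent-versus-incongruent score contrast, trialwise accuracy
against marginal-product chance, and per-subject correlation of report and
decoder frequency distributions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from ._nonparam import SignedRankResult, signed_rank_test
from .datatypes import EMOTIONS, N_EMOTIONS, ScoreMatrix

# Default wheel vocabulary: 16 terms, clockwise from the positive x-axis.
# Only seven map onto decodable categories; the rest are dropped with a flag.
DEFAULT_TERMS: tuple[str, ...] = (
    "relief",
    "joy",
    "satisfaction",
    "love",
    "awe",
    "surprise",
    "interest",
    "fear",
    "shame",
    "anger",
    "contempt",
    "disgust",
    "sadness",
    "guilt",
    "boredom",
    "pride",
)

#: Term-to-category relabeling; terms absent here are outside the model
#: vocabulary and yield no label.
TERM_TO_CATEGORY: dict[str, str] = {
    "relief": "content",
    "joy": "amusement",
    "satisfaction": "amusement",
    "surprise": "surprise",
    "fear": "fear",
    "anger": "anger",
    "sadness": "sad",
}


@dataclass(frozen=True)
class RatingScreenLayout:
    """Radial response-screen geometry: 16 sectors, 4 rings, neutral disk."""

    terms: tuple[str, ...] = DEFAULT_TERMS
    neutral_radius: float = 0.15
    outer_radius: float = 1.0
    n_rings: int = 4

    def __post_init__(self) -> None:
        if len(self.terms) != 16:
            raise ValueError("layout requires exactly 16 terms")
        if not 0 < self.neutral_radius < self.outer_radius:
            raise ValueError("need 0 < neutral_radius < outer_radius")

    @property
    def sector_width_deg(self) -> float:
        return 360.0 / len(self.terms)

    @property
    def ring_width(self) -> float:
        return (self.outer_radius - self.neutral_radius) / self.n_rings


DEFAULT_LAYOUT = RatingScreenLayout()


class CursorReading(NamedTuple):
    label: int | None  # emotion index, or None for off-vocabulary terms
    intensity: int
    flagged: bool  # boundary tie or dropped term


def map_cursor_to_label(
    x: float, y: float, layout: RatingScreenLayout = DEFAULT_LAYOUT
) -> CursorReading:
    """Map a 2D cursor position to a (category, intensity) reading.

    The central disk reads as neutral (intensity 1).  Elsewhere the angular
    sector selects the emotion term (relabeled onto the seven model
    categories; off-vocabulary terms give ``label=None`` with a flag) and the
    ring selects intensity 1–4.  Points exactly on a sector or ring boundary
    resolve to the lower index and are flagged.
    """
    r = math.hypot(x, y)
    if r > layout.outer_radius + 1e-12:
        raise ValueError(
            f"cursor ({x}, {y}) outside screen bounds "
            f"(radius {layout.outer_radius})"
        )
    if r <= layout.neutral_radius:
        flagged = math.isclose(r, layout.neutral_radius, rel_tol=0.0, abs_tol=1e-12)
        return CursorReading(EMOTIONS.index("neutral"), 1, flagged)

    theta = math.degrees(math.atan2(y, x)) % 360.0
    width = layout.sector_width_deg
    frac = theta / width
    on_boundary = math.isclose(frac, round(frac), rel_tol=0.0, abs_tol=1e-9)
    sector = int(math.floor(frac))
    if on_boundary and round(frac) > 0:
        sector = int(round(frac)) - 1  # boundary point joins the lower sector
    sector %= len(layout.terms)

    rfrac = (r - layout.neutral_radius) / layout.ring_width
    ring_boundary = rfrac > 0 and math.isclose(
        rfrac, round(rfrac), rel_tol=0.0, abs_tol=1e-9
    )
    ring = int(math.ceil(rfrac)) if not ring_boundary else int(round(rfrac))
    ring = min(max(ring, 1), layout.n_rings)

    term = layout.terms[sector]
    category = TERM_TO_CATEGORY.get(term)
    if category is None:
        return CursorReading(None, ring, True)
    return CursorReading(EMOTIONS.index(category), ring, on_boundary or ring_boundary)


def cursor_position(
    category: str | int,
    intensity: int,
    rng: np.random.Generator,
    layout: RatingScreenLayout = DEFAULT_LAYOUT,
) -> tuple[float, float]:
    """Sample a cursor position that reads back as (category, intensity).

    Inverse of :func:`map_cursor_to_label` for the seven model categories;
    used by the synthetic experience-sampling generator.
    """
    if isinstance(category, (int, np.integer)):
        category = EMOTIONS[int(category)]
    if category == "neutral":
        r = rng.uniform(0.0, layout.neutral_radius * 0.9)
        theta = rng.uniform(0.0, 2 * math.pi)
        return r * math.cos(theta), r * math.sin(theta)
    terms = [t for t, c in TERM_TO_CATEGORY.items() if c == category]
    if not terms:
        raise ValueError(f"no screen term maps to category {category!r}")
    term = terms[int(rng.integers(len(terms)))]
    sector = layout.terms.index(term)
    width = layout.sector_width_deg
    # stay off sector/ring boundaries so the reading is unambiguous
    theta = math.radians((sector + rng.uniform(0.1, 0.9)) * width)
    if not 1 <= intensity <= layout.n_rings:
        raise ValueError("intensity must lie in 1..4")
    r = layout.neutral_radius + (intensity - rng.uniform(0.1, 0.9)) * layout.ring_width
    return r * math.cos(theta), r * math.sin(theta)


@dataclass
class TrialWindow:
    """Mean pre-rating scores for one experience-sampling trial."""

    event_id: int
    start: int  # first volume in the window (inclusive)
    stop: int  # volume of rating onset (exclusive)
    mean_scores: np.ndarray  # (7,)
    reported: int  # reported emotion index

    @property
    def decoded(self) -> int:
        return int(np.argmax(self.mean_scores))


def window_scores(
    sm: ScoreMatrix,
    events: pd.DataFrame,
    window_s: float = 10.0,
) -> list[TrialWindow]:
    """Average the scores of the window preceding each rating event.

    ``events`` needs columns ``time_s`` and ``label`` (category name or
    index).  The window covers the ⌊window_s/TR⌋ whole volumes ending at the
    volume of rating onset (exclusive); events too early for a full window,
    or with no usable label, are dropped with a warning.
    """
    n_vol = int(math.floor(window_s / sm.tr_seconds + 1e-12))
    if n_vol < 1:
        raise ValueError("window shorter than one TR")
    trials: list[TrialWindow] = []
    n_dropped = 0
    for event_id, row in enumerate(events.itertuples(index=False)):
        label = row.label
        if label is None or (isinstance(label, float) and math.isnan(label)):
            n_dropped += 1
            continue
        reported = int(label) if not isinstance(label, str) else EMOTIONS.index(label)
        onset = int(math.floor(row.time_s / sm.tr_seconds))
        start = onset - n_vol
        if start < 0 or onset > sm.n_timepoints:
            n_dropped += 1
            continue
        mean_scores = sm.scores[start:onset].mean(axis=0)
        trials.append(TrialWindow(event_id, start, onset, mean_scores, reported))
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} events without a full usable window")
    return trials


class CongruenceContrast(NamedTuple):
    congruent_means: np.ndarray  # per subject
    incongruent_means: np.ndarray
    congruent_test: SignedRankResult
    incongruent_test: SignedRankResult
    lilliefors_p: tuple[float, float]
    n_excluded: int


def congruence_contrast(
    trials_by_subject: Sequence[Sequence[TrialWindow]],
) -> CongruenceContrast:
    """Contrast scores congruent vs incongruent with self-report.

    Per subject, the congruent value is the mean (over trials) of the
    reported emotion's score, and the incongruent value the mean of the other
    six models' scores.  Each sample is tested against zero with a Wilcoxon
    signed-rank test; Lilliefors normality p-values are reported alongside
    (the signed-rank test is used regardless).
    """
    cong, incong = [], []
    n_excluded = 0
    for trials in trials_by_subject:
        if not trials:
            n_excluded += 1
            continue
        c_vals, i_vals = [], []
        for tw in trials:
            c_vals.append(tw.mean_scores[tw.reported])
            others = np.delete(tw.mean_scores, tw.reported)
            i_vals.append(others.mean())
        cong.append(np.mean(c_vals))
        incong.append(np.mean(i_vals))
    if n_excluded:
        warnings.warn(f"excluded {n_excluded} subjects with no usable trials")
    cong = np.asarray(cong)
    incong = np.asarray(incong)
    if cong.size < 2:
        raise ValueError("need at least two subjects with usable trials")

    def _lillie(x: np.ndarray) -> float:
        if np.ptp(x) == 0:
            return float("nan")
        return float(lilliefors(x, dist="norm")[1])

    return CongruenceContrast(
        congruent_means=cong,
        incongruent_means=incong,
        congruent_test=signed_rank_test(cong),
        incongruent_test=signed_rank_test(incong),
        lilliefors_p=(_lillie(cong), _lillie(incong)),
        n_excluded=n_excluded,
    )


class AccuracyResult(NamedTuple):
    accuracy: float
    chance: float
    n_trials: int
    pvalue: float
    confusion: np.ndarray  # 7×7 counts, rows=reported, cols=decoded


def trialwise_accuracy(trials: Sequence[TrialWindow]) -> AccuracyResult:
    """Pooled trialwise agreement between decoder and self-report.

    Chance is the marginal-product agreement of two independent labelers,
    Σ_e p_report(e)·p_decoded(e); the observed hit count is tested against a
    binomial with that success probability (one-sided, above chance).
    """
    if not trials:
        raise ValueError("no trials supplied")
    reported = np.array([tw.reported for tw in trials])
    decoded = np.array([tw.decoded for tw in trials])
    n = reported.size
    accuracy = float(np.mean(reported == decoded))
    p_self = np.bincount(reported, minlength=N_EMOTIONS) / n
    p_model = np.bincount(decoded, minlength=N_EMOTIONS) / n
    chance = float(np.dot(p_self, p_model))
    confusion = np.zeros((N_EMOTIONS, N_EMOTIONS), dtype=int)
    np.add.at(confusion, (reported, decoded), 1)
    if chance >= 1.0:
        pvalue = 1.0
    else:
        pvalue = float(
            stats.binomtest(
                int(round(accuracy * n)), n, chance, alternative="greater"
            ).pvalue
        )
    return AccuracyResult(accuracy, chance, n, pvalue, confusion)


_FISHER_CAP = float(np.arctanh(1 - 1e-12))


class FrequencyCorrelation(NamedTuple):
    mean_r: float
    t: float
    df: int
    pvalue: float
    per_subject_r: np.ndarray
    n_excluded: int
    n_clipped: int


def frequency_correlation(
    trials_by_subject: Sequence[Sequence[TrialWindow]],
) -> FrequencyCorrelation:
    """Correlate report and decoder frequency distributions per subject.

    Per subject, the 7-bin frequency vectors of reported and decoded labels
    are Pearson-correlated; correlations are Fisher z-transformed (|r|=1 is
    clipped to a finite cap and counted) and tested against zero with a
    one-sample t test.  The back-transformed mean r is reported.
    """
    rs = []
    n_excluded = 0
    for trials in trials_by_subject:
        if not trials:
            n_excluded += 1
            continue
        reported = np.bincount([tw.reported for tw in trials], minlength=N_EMOTIONS)
        decoded = np.bincount([tw.decoded for tw in trials], minlength=N_EMOTIONS)
        if np.ptp(reported) == 0 or np.ptp(decoded) == 0:
            n_excluded += 1
            continue
        rs.append(float(stats.pearsonr(reported, decoded)[0]))
    if len(rs) < 2:
        raise ValueError("need at least two subjects with correlatable frequencies")
    rs = np.asarray(rs)
    z = np.arctanh(np.clip(rs, -1 + 1e-15, 1 - 1e-15))
    n_clipped = int(np.sum(np.abs(z) > _FISHER_CAP))
    z = np.clip(z, -_FISHER_CAP, _FISHER_CAP)
    tres = stats.ttest_1samp(z, 0.0)
    return FrequencyCorrelation(
        mean_r=float(np.tanh(z.mean())),
        t=float(tres.statistic),
        df=len(rs) - 1,
        pvalue=float(tres.pvalue),
        per_subject_r=rs,
        n_excluded=n_excluded,
        n_clipped=n_clipped,
    )


@dataclass
class ConcordanceResult:
    """Bundle of the three concordance analyses for one cohort."""

    contrast: CongruenceContrast
    accuracy: AccuracyResult
    correlation: FrequencyCorrelation


def concordance_analysis(
    trials_by_subject: Sequence[Sequence[TrialWindow]],
) -> ConcordanceResult:
    pooled = [tw for trials in trials_by_subject for tw in trials]
    return ConcordanceResult(
        contrast=congruence_contrast(trials_by_subject),
        accuracy=trialwise_accuracy(pooled),
        correlation=frequency_correlation(trials_by_subject),
    )
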