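"""Scalar-product decoding of voxel time series into emotion-state scores.

The decoding model is fixed: each emotion e has a spatial coefficient map
w_e; after temporal standardization of the data, the classifier score at
volume t is the inner product s[t, e] = Σ_v z[t, v] · w_e[v].  One-versus-all
classification assigns each volume the emotion with the maximal score, and
occupancy is the count of volumes per category.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datatypes import (
    N_EMOTIONS,
    FrequencyTable,
    LabelSequence,
    ScoreMatrix,
    SubjectTimeSeries,
    WeightMapSet,
)


def standardize_timeseries(ts: SubjectTimeSeries) -> SubjectTimeSeries:
    """Z-score each voxel's time course within each run.

    Per voxel and run the mean is subtracted and the sample standard
    deviation (denominator n−1) divided out.  Voxels constant within a run
    carry no information and are zeroed and flagged in
    ``constant_voxels`` rather than producing NaNs.
    """
    data = ts.data
    out = np.empty_like(data, dtype=float)
    constant = np.zeros(ts.n_voxels, dtype=bool)
    for sl in ts.run_slices():
        block = data[sl]
        mean = block.mean(axis=0)
        sd = block.std(axis=0, ddof=1)
        flat = sd == 0.0
        constant |= flat
        safe_sd = np.where(flat, 1.0, sd)
        out[sl] = (block - mean) / safe_sd
        out[sl][:, flat] = 0.0
    if constant.all():
        warnings.warn(
            f"subject {ts.subject_id}: all voxels constant; standardized "
            "output is identically zero"
        )
    return SubjectTimeSeries(
        data=out,
        tr_seconds=ts.tr_seconds,
        run_boundaries=ts.run_boundaries,
        subject_id=ts.subject_id,
        grid=ts.grid,
        constant_voxels=constant,
    )


def score_timepoints(ts: SubjectTimeSeries, weights: WeightMapSet) -> ScoreMatrix:
    """Classifier scores: scalar product of standardized data and weight maps.

    ``ts`` is expected to be standardized already (see
    :func:`standardize_timeseries`); no further normalization is applied.
    """
    if ts.grid is not None and not ts.grid.matches(weights.grid):
        raise ValueError(
            f"voxel grid mismatch: data grid {ts.grid.shape} "
            f"({ts.grid.n_voxels} voxels) vs weights grid {weights.grid.shape} "
            f"({weights.grid.n_voxels} voxels)"
        )
    if ts.n_voxels != weights.n_voxels:
        raise ValueError(
            f"voxel count mismatch: data has {ts.n_voxels}, "
            f"weights have {weights.n_voxels}"
        )
    scores = ts.data @ weights.coefficients.T
    return ScoreMatrix(
        scores=scores,
        labels=weights.labels,
        tr_seconds=ts.tr_seconds,
        run_boundaries=ts.run_boundaries,
    )


def classify_timepoints(sm: ScoreMatrix) -> LabelSequence:
    """One-versus-all labels: argmax score per volume, ties to lowest index.

    Exact ties are flagged; with continuous scores they have measure zero but
    the rule keeps labeling deterministic.
    """
    scores = sm.scores
    labels = np.argmax(scores, axis=1)
    row_max = scores[np.arange(scores.shape[0]), labels]
    ties = (scores == row_max[:, None]).sum(axis=1) > 1
    return LabelSequence(labels=labels, tie_flags=ties)


def count_frequencies(ls: LabelSequence, subject_id: str = "sub-000") -> FrequencyTable:
    """Occupancy counts per emotion category; counts always sum to T."""
    counts = np.bincount(ls.labels, minlength=N_EMOTIONS)
    return FrequencyTable(counts=counts, subject_id=subject_id)


def decode_subject(
    ts: SubjectTimeSeries,
    weights: WeightMapSet,
    standardize: bool = True,
) -> tuple[ScoreMatrix, LabelSequence, FrequencyTable]:
    """Full per-subject decoding: standardize, score, label, count."""
    if standardize:
        ts = standardize_timeseries(ts)
    sm = score_timepoints(ts, weights)
    ls = classify_timepoints(sm)
    ft = count_frequencies(ls, subject_id=ts.subject_id)
    return sm, ls, ft
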