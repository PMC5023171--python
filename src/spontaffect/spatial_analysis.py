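"""Voxel-space diagnostics for the decoding models.

Importance maps localize what drove classification: the voxelwise product of
a model's coefficients and the mean standardized activity of the volumes
labeled with that emotion.  Group inference is a mass-univariate one-sample
t test with BH-FDR thresholding.  Overlap between thresholded model maps and
network parcels is quantified with an adaptive-threshold Jaccard index, and
ℓ2-norm diagnostics verify that models and data live on comparable scales.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._nonparam import bh_fdr
from .datatypes import (
    EMOTIONS,
    N_EMOTIONS,
    LabelSequence,
    SubjectTimeSeries,
    WeightMapSet,
)


@dataclass
class ImportanceMap:
    """Per-voxel importance of one emotion model for one subject."""

    emotion: int
    values: np.ndarray  # (V,)
    defined: bool
    n_labeled: int
    subject_id: str = "sub-000"


def importance_map(
    ts: SubjectTimeSeries,
    labels: LabelSequence,
    weights: WeightMapSet,
    emotion: int,
) -> ImportanceMap:
    """Voxelwise product of model coefficients and mean labeled activity.

    ``ts`` must already be standardized.  With zero volumes labeled as the
    emotion the map is undefined: it is returned filled with NaN, flagged,
    and the group stage excludes it.
    """
    if ts.n_voxels != weights.n_voxels:
        raise ValueError("voxel count mismatch between data and weights")
    sel = labels.labels == emotion
    n_labeled = int(sel.sum())
    if n_labeled == 0:
        warnings.warn(
            f"no timepoints labeled {EMOTIONS[emotion]!r} for {ts.subject_id}; "
            "importance map undefined"
        )
        return ImportanceMap(
            emotion, np.full(ts.n_voxels, np.nan), False, 0, ts.subject_id
        )
    mean_activity = ts.data[sel].mean(axis=0)
    values = weights.coefficients[emotion] * mean_activity
    return ImportanceMap(emotion, values, True, n_labeled, ts.subject_id)


class GroupImportance(NamedTuple):
    t_map: np.ndarray  # (V,), NaN at excluded voxels
    p_map: np.ndarray
    fdr_mask: np.ndarray  # boolean (V,)
    n_subjects: int
    n_zero_variance: int


def group_importance_inference(
    maps: Sequence[ImportanceMap], q: float = 0.05
) -> GroupImportance:
    """Voxelwise one-sample t test on subject importance maps, BH-FDR at q.

    Undefined subject maps are dropped; voxels with zero between-subject
    variance have no t statistic and are excluded (and counted).
    """
    stack = np.stack([m.values for m in maps if m.defined])
    if stack.shape[0] < 2:
        raise ValueError("need at least 2 subjects with defined maps")
    V = stack.shape[1]
    sd = stack.std(axis=0, ddof=1)
    valid = sd > 0
    n_zero = int(V - valid.sum())
    t_map = np.full(V, np.nan)
    p_map = np.full(V, np.nan)
    if valid.any():
        res = stats.ttest_1samp(stack[:, valid], 0.0, axis=0)
        t_map[valid] = res.statistic
        p_map[valid] = res.pvalue
    fdr_mask = np.zeros(V, dtype=bool)
    fdr_mask[valid] = bh_fdr(p_map[valid], q=q)
    return GroupImportance(t_map, p_map, fdr_mask, stack.shape[0], n_zero)


class OverlapResult(NamedTuple):
    jaccard: float
    model_threshold: float
    n_model: int  # suprathreshold voxels in the model map
    n_network: int
    flagged: bool  # empty union


def jaccard_index(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection-over-union of two boolean masks (0 for empty union)."""
    a = np.asarray(mask_a, bool).ravel()
    b = np.asarray(mask_b, bool).ravel()
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def jaccard_overlap(
    model_map: np.ndarray,
    network_mask: np.ndarray,
    match_fraction: float | None = None,
    signed: bool = False,
) -> OverlapResult:
    """Adaptive-threshold Jaccard overlap of a model map with a parcel.

    The model map is thresholded on absolute value (both signs carry
    classification information; set ``signed=True`` for positive-only) at
    the quantile that selects ``⌈match_fraction·V⌉`` voxels, where
    ``match_fraction`` defaults to the network mask's own fill fraction —
    so both maps commit the same number of voxels before the overlap is
    computed.
    """
    values = np.asarray(model_map, dtype=float).ravel()
    net = np.asarray(network_mask, bool).ravel()
    if values.size != net.size:
        raise ValueError("model map and network mask sizes differ")
    V = values.size
    if match_fraction is None:
        match_fraction = net.sum() / V
    n_select = int(math.ceil(match_fraction * V))
    mag = values if signed else np.abs(values)
    if n_select <= 0:
        model_mask = np.zeros(V, dtype=bool)
        threshold = float("inf")
    else:
        order = np.argsort(mag, kind="stable")[::-1]
        model_mask = np.zeros(V, dtype=bool)
        model_mask[order[:n_select]] = True
        threshold = float(mag[order[n_select - 1]])
    union_empty = not (model_mask.any() or net.any())
    return OverlapResult(
        jaccard=jaccard_index(model_mask, net),
        model_threshold=threshold,
        n_model=int(model_mask.sum()),
        n_network=int(net.sum()),
        flagged=union_empty,
    )


def overlap_matrix(
    weights: WeightMapSet,
    network_masks: Sequence[np.ndarray],
    signed: bool = False,
) -> pd.DataFrame:
    """Jaccard index of every emotion model against every network parcel.

    Network masks are restricted to the in-brain voxel vector before
    thresholding.  Returns a tidy frame plus the per-emotion maximum is
    available as ``frame.groupby("emotion").jaccard.max()``.
    """
    rows = []
    for e in range(N_EMOTIONS):
        for k, net in enumerate(network_masks):
            net_vec = weights.grid.extract(np.asarray(net, float)) > 0.5
            res = jaccard_overlap(weights.coefficients[e], net_vec, signed=signed)
            rows.append(
                {
                    "emotion": EMOTIONS[e],
                    "network": k,
                    "jaccard": res.jaccard,
                    "n_model": res.n_model,
                    "n_network": res.n_network,
                }
            )
    return pd.DataFrame(rows)


def l2_norm_diagnostics(
    weights: WeightMapSet,
    cohort: Sequence[SubjectTimeSeries] | None = None,
) -> dict[str, pd.DataFrame]:
    """ℓ2 norms of the weight maps and, optionally, of the data volumes.

    The model table has one row per emotion.  The data table has one row per
    timepoint with the mean and sd (across subjects) of the per-volume data
    norm √(Σ_v x[t,v]²); for standardized data this hovers near √V.
    """
    model_table = pd.DataFrame(
        {"emotion": list(weights.labels), "l2_norm": weights.norms()}
    )
    out = {"models": model_table}
    if cohort:
        norms = np.stack([np.linalg.norm(ts.data, axis=1) for ts in cohort])
        out["data"] = pd.DataFrame(
            {
                "timepoint": np.arange(norms.shape[1]),
                "mean_norm": norms.mean(axis=0),
                "sd_norm": norms.std(axis=0, ddof=1) if norms.shape[0] > 1 else 0.0,
            }
        )
    return out
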