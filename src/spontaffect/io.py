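"""Readers and writers for the pipeline's on-disk formats.

Real-data mode exchanges NIfTI volumes (via nibabel); synthetic runs use
compressed ``.npz`` archives which round-trip all metadata.  Tabular outputs
are plain CSV:

* covariates — one row per subject, columns ``subject_id, cesd, stai_s,
  neo_anxiety, neo_angry_hostility, neo_depression``;
* rating events — columns ``time_s, x, y, label, intensity``;
* scores — wide, one row per timepoint, one column per emotion;
* frequencies — tidy, columns ``subject_id, category, count``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .datatypes import (
    EMOTIONS,
    FrequencyTable,
    ScoreMatrix,
    SubjectTimeSeries,
    VoxelGrid,
    WeightMapSet,
)

_EYE4 = np.eye(4)


# ---------------------------------------------------------------- NIfTI side


def weight_maps_to_nifti(wms: WeightMapSet) -> tuple[list[nib.Nifti1Image], nib.Nifti1Image]:
    """Seven 3D coefficient volumes plus the in-brain mask volume."""
    imgs = [
        nib.Nifti1Image(wms.grid.embed(row).astype(np.float32), _EYE4)
        for row in wms.coefficients
    ]
    mask_img = nib.Nifti1Image(wms.grid.mask.astype(np.uint8), _EYE4)
    return imgs, mask_img


def weight_maps_from_nifti(
    map_paths: Sequence[str | Path], mask_path: str | Path
) -> WeightMapSet:
    mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    grid = VoxelGrid(shape=mask.shape, mask=mask)
    rows = [grid.extract(np.asarray(nib.load(str(p)).dataobj, dtype=float)) for p in map_paths]
    return WeightMapSet(coefficients=np.stack(rows), grid=grid)


def timeseries_to_nifti(ts: SubjectTimeSeries) -> nib.Nifti1Image:
    """4D volume (x, y, z, t) of the in-mask data; requires a grid."""
    if ts.grid is None:
        raise ValueError("time series carries no voxel grid")
    vol = np.zeros(ts.grid.shape + (ts.n_timepoints,), dtype=np.float32)
    vol[ts.grid.mask] = ts.data.T
    img = nib.Nifti1Image(vol, _EYE4)
    img.header.set_zooms((1.0, 1.0, 1.0, ts.tr_seconds))
    return img


def timeseries_from_nifti(
    img: nib.Nifti1Image | str | Path,
    mask: np.ndarray,
    run_boundaries: tuple[int, ...] = (0,),
    subject_id: str = "sub-000",
) -> SubjectTimeSeries:
    if not isinstance(img, nib.Nifti1Image):
        img = nib.load(str(img))
    vol = np.asarray(img.dataobj, dtype=float)
    mask = np.asarray(mask, bool)
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 2.0
    return SubjectTimeSeries(
        data=vol[mask].T,
        tr_seconds=tr or 2.0,
        run_boundaries=run_boundaries,
        subject_id=subject_id,
        grid=VoxelGrid(shape=mask.shape, mask=mask),
    )


# ------------------------------------------------------------------ npz side


def save_weight_maps(path: str | Path, wms: WeightMapSet) -> None:
    np.savez_compressed(
        path,
        coefficients=wms.coefficients,
        mask=wms.grid.mask,
        labels=np.array(wms.labels),
    )


def load_weight_maps(path: str | Path) -> WeightMapSet:
    with np.load(path, allow_pickle=False) as z:
        mask = z["mask"]
        return WeightMapSet(
            coefficients=z["coefficients"],
            grid=VoxelGrid(shape=mask.shape, mask=mask),
            labels=tuple(str(s) for s in z["labels"]),
        )


def save_timeseries(path: str | Path, ts: SubjectTimeSeries) -> None:
    np.savez_compressed(
        path,
        data=ts.data,
        tr_seconds=ts.tr_seconds,
        run_boundaries=np.array(ts.run_boundaries),
        subject_id=np.array(ts.subject_id),
        mask=ts.grid.mask if ts.grid is not None else np.zeros(0, bool),
    )


def load_timeseries(path: str | Path) -> SubjectTimeSeries:
    with np.load(path, allow_pickle=False) as z:
        mask = z["mask"]
        grid = VoxelGrid(shape=mask.shape, mask=mask) if mask.size else None
        return SubjectTimeSeries(
            data=z["data"],
            tr_seconds=float(z["tr_seconds"]),
            run_boundaries=tuple(int(b) for b in z["run_boundaries"]),
            subject_id=str(z["subject_id"]),
            grid=grid,
        )


# ------------------------------------------------------------------ CSV side


def save_scores(path: str | Path, sm: ScoreMatrix) -> None:
    frame = pd.DataFrame(sm.scores, columns=list(sm.labels))
    frame.insert(0, "timepoint", np.arange(sm.n_timepoints))
    frame.to_csv(path, index=False)


def load_scores(
    path: str | Path,
    tr_seconds: float = 2.0,
    run_boundaries: tuple[int, ...] = (0,),
) -> ScoreMatrix:
    frame = pd.read_csv(path)
    return ScoreMatrix(
        scores=frame[list(EMOTIONS)].to_numpy(),
        tr_seconds=tr_seconds,
        run_boundaries=run_boundaries,
    )


def save_frequencies(path: str | Path, freqs: Sequence[FrequencyTable]) -> None:
    rows = [
        {"subject_id": ft.subject_id, "category": EMOTIONS[e], "count": int(ft.counts[e])}
        for ft in freqs
        for e in range(len(EMOTIONS))
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_frequencies(path: str | Path) -> list[FrequencyTable]:
    frame = pd.read_csv(path)
    freqs = []
    for sid, grp in frame.groupby("subject_id", sort=False):
        counts = grp.set_index("category")["count"].reindex(list(EMOTIONS)).to_numpy()
        freqs.append(FrequencyTable(counts=counts, subject_id=str(sid)))
    return freqs


def load_config(path: str | Path) -> dict[str, str]:
    """Key-value text config: one ``key = value`` pair per line, # comments."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {line!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out
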