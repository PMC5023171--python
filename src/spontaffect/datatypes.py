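"""Core containers shared across the decoding pipeline.

Seven emotion categories are modeled throughout, in a fixed order that every
score matrix, frequency table and weight-map set inherits:

    content, amusement, surprise, fear, anger, sad, neutral

Array-valued bundles are small frozen-ish dataclasses; tabular data
(covariates, rating events) travel as :class:`pandas.DataFrame` with
documented column contracts (see :mod:`spontaffect.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

EMOTIONS: tuple[str, ...] = (
    "content",
    "amusement",
    "surprise",
    "fear",
    "anger",
    "sad",
    "neutral",
)
N_EMOTIONS = len(EMOTIONS)

#: Columns expected of a covariate table (one row per subject).
COVARIATE_COLUMNS = (
    "subject_id",
    "cesd",
    "stai_s",
    "neo_anxiety",
    "neo_angry_hostility",
    "neo_depression",
)

#: Columns expected of a rating-event table (one row per rating probe).
RATING_EVENT_COLUMNS = ("time_s", "x", "y", "label", "intensity")


@dataclass(frozen=True)
class VoxelGrid:
    """A 3D voxel lattice with an in-brain mask.

    ``shape`` is the lattice dimensions; ``mask`` is a boolean array of that
    shape.  Flattened vectors of length ``n_voxels`` index the True entries of
    ``mask`` in C order.
    """

    shape: tuple[int, int, int]
    mask: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != tuple(self.shape):
            raise ValueError(f"mask shape {mask.shape} != grid shape {self.shape}")
        object.__setattr__(self, "mask", mask)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def matches(self, other: "VoxelGrid") -> bool:
        return self.shape == other.shape and bool(np.array_equal(self.mask, other.mask))

    def embed(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Place a length-``n_voxels`` vector back into the 3D volume."""
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_voxels,):
            raise ValueError(f"expected ({self.n_voxels},) vector, got {values.shape}")
        vol = np.full(self.shape, fill, dtype=float)
        vol[self.mask] = values
        return vol

    def extract(self, volume: np.ndarray) -> np.ndarray:
        """Flatten a 3D volume to the in-mask voxel vector."""
        volume = np.asarray(volume, dtype=float)
        if volume.shape != tuple(self.shape):
            raise ValueError(f"volume shape {volume.shape} != grid shape {self.shape}")
        return volume[self.mask]


@dataclass
class WeightMapSet:
    """Seven emotion-labeled spatial coefficient vectors over a common grid.

    ``coefficients`` has shape (7, V) with V the number of in-mask voxels;
    row order follows :data:`EMOTIONS` unless ``labels`` overrides it.
    """

    coefficients: np.ndarray
    grid: VoxelGrid
    labels: tuple[str, ...] = EMOTIONS

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.labels = tuple(self.labels)
        if len(self.labels) != N_EMOTIONS:
            raise ValueError(f"expected {N_EMOTIONS} labels, got {len(self.labels)}")
        if self.coefficients.shape != (N_EMOTIONS, self.grid.n_voxels):
            raise ValueError(
                f"coefficients shape {self.coefficients.shape} != "
                f"({N_EMOTIONS}, {self.grid.n_voxels})"
            )
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients contain non-finite values")

    @property
    def n_voxels(self) -> int:
        return self.grid.n_voxels

    def norms(self) -> np.ndarray:
        """Per-emotion ℓ2 norms of the coefficient rows."""
        return np.linalg.norm(self.coefficients, axis=1)


@dataclass
class HiddenStateSequence:
    """A latent per-volume emotion-state sequence driving synthetic data."""

    states: np.ndarray
    dwell_params: dict | None = None
    trend_spec: dict | None = None

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=int)
        if states.ndim != 1 or states.size == 0:
            raise ValueError("states must be a nonempty 1D integer sequence")
        if states.min() < 0 or states.max() >= N_EMOTIONS:
            raise ValueError("state indices must lie in {0..6}")
        self.states = states

    def __len__(self) -> int:
        return int(self.states.size)


@dataclass
class SubjectTimeSeries:
    """One subject's T×V voxel time series with acquisition metadata."""

    data: np.ndarray
    tr_seconds: float = 2.0
    run_boundaries: tuple[int, ...] = (0,)
    subject_id: str = "sub-000"
    grid: VoxelGrid | None = None
    #: set by standardization: True where a voxel was constant within a run
    constant_voxels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be T×V")
        bounds = tuple(int(b) for b in self.run_boundaries)
        if not bounds or bounds[0] != 0:
            raise ValueError("run_boundaries must start at 0")
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValueError("run_boundaries must be strictly increasing")
        if bounds[-1] >= self.n_timepoints:
            raise ValueError("run boundary beyond series length")
        for start, stop in self._run_ranges(bounds):
            if stop - start < 2:
                raise ValueError("each run must contain at least 2 volumes")
        self.run_boundaries = bounds
        if self.grid is not None and self.grid.n_voxels != self.n_voxels:
            raise ValueError("grid mask size does not match data columns")

    def _run_ranges(self, bounds: Sequence[int]) -> list[tuple[int, int]]:
        stops = list(bounds[1:]) + [self.data.shape[0]]
        return list(zip(bounds, stops))

    @property
    def n_timepoints(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_voxels(self) -> int:
        return int(self.data.shape[1])

    def run_slices(self) -> Iterator[slice]:
        for start, stop in self._run_ranges(self.run_boundaries):
            yield slice(start, stop)


@dataclass
class ScoreMatrix:
    """Per-timepoint classifier scores: T rows, one column per emotion."""

    scores: np.ndarray
    labels: tuple[str, ...] = EMOTIONS
    tr_seconds: float = 2.0
    run_boundaries: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != N_EMOTIONS:
            raise ValueError(f"scores must be T×{N_EMOTIONS}")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores contain non-finite values")
        self.labels = tuple(self.labels)
        self.run_boundaries = tuple(int(b) for b in self.run_boundaries)

    @property
    def n_timepoints(self) -> int:
        return int(self.scores.shape[0])


@dataclass
class LabelSequence:
    """One-versus-all labels per timepoint, with deterministic tie handling."""

    labels: np.ndarray
    tie_flags: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.tie_flags = np.asarray(self.tie_flags, dtype=bool)
        if self.labels.shape != self.tie_flags.shape or self.labels.ndim != 1:
            raise ValueError("labels and tie_flags must be matching 1D arrays")

    def __len__(self) -> int:
        return int(self.labels.size)


@dataclass
class FrequencyTable:
    """Counts of timepoints assigned to each emotion for one subject."""

    counts: np.ndarray
    subject_id: str = "sub-000"

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (N_EMOTIONS,):
            raise ValueError(f"counts must have shape ({N_EMOTIONS},)")
        if np.any(counts < 0) or not np.all(counts == np.round(counts)):
            raise ValueError("counts must be nonnegative integers")
        self.counts = counts.astype(int)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.total
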