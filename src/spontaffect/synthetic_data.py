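"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator is a pure function of its arguments including ``seed``, so
each downstream stage is testable without any imaging download.  The
emulation is deliberately minimal:

* seven sparse spatial weight maps with equal ℓ2 norms on a 3D masked grid;
* a hidden first-order Markov emotion-state sequence (configurable dwell);
* voxel time series = amplitude · active-state map + voxelwise-independent
  AR(1) noise (no spatial correlation, no hemodynamics);
* cohorts whose per-subject state occupancy is tilted on the log-odds scale
  by a mood covariate, matching the binomial-GLM analysis downstream;
* experience-sampling sessions with rating events every ≥30 s whose reports
  agree with the hidden state at a configurable congruence rate.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import expit, logit

from .datatypes import (
    EMOTIONS,
    N_EMOTIONS,
    HiddenStateSequence,
    SubjectTimeSeries,
    VoxelGrid,
    WeightMapSet,
)
from .experience_sampling import DEFAULT_LAYOUT, RatingScreenLayout, cursor_position

__all__ = [
    "default_grid",
    "flat_grid",
    "generate_weight_maps",
    "uniform_transition",
    "dwell_transition",
    "generate_state_sequence",
    "generate_subject_timeseries",
    "generate_cohort",
    "generate_experience_sampling",
    "generate_network_masks",
]


def default_grid(shape: tuple[int, int, int] = (10, 10, 10), radius: float = 5.5) -> VoxelGrid:
    """Desk-scale 3D grid with a centered ball as the in-brain mask.

    The 10×10×10 default with radius 5.5 yields a ~700-voxel mask — small
    enough for fast tests while still exercising 3D mask logic.
    """
    coords = np.indices(shape).reshape(3, -1).T
    center = (np.asarray(shape) - 1) / 2.0
    mask = (np.sum((coords - center) ** 2, axis=1) <= radius**2).reshape(shape)
    return VoxelGrid(shape=tuple(shape), mask=mask)


def flat_grid(n_voxels: int) -> VoxelGrid:
    """Degenerate (V,1,1) grid with a full mask, for purely vectorial tests."""
    if n_voxels < 1:
        raise ValueError("n_voxels must be positive")
    return VoxelGrid(shape=(n_voxels, 1, 1), mask=np.ones((n_voxels, 1, 1), dtype=bool))


def generate_weight_maps(
    n_voxels: int | None = None,
    sparsity: float = 0.1,
    overlap: float = 0.0,
    seed: int = 0,
    grid: VoxelGrid | None = None,
) -> WeightMapSet:
    """Seven sparse coefficient maps with equal ℓ2 norms.

    Each row has ``⌈sparsity·V⌉`` nonzero standard-normal entries; a fraction
    ``overlap`` of each row's support is shared by all rows (pairwise support
    overlap therefore equals ``overlap`` up to rounding), the rest is
    disjoint across rows.  Rows are rescaled to unit ℓ2 norm, mirroring the
    observation that real emotion models carry near-equal norms.
    """
    if grid is None:
        grid = flat_grid(n_voxels) if n_voxels is not None else default_grid()
    V = grid.n_voxels
    if V < N_EMOTIONS:
        raise ValueError(f"need at least {N_EMOTIONS} voxels, got {V}")
    if not 0 < sparsity <= 1:
        raise ValueError("sparsity must lie in (0, 1]")
    if not 0 <= overlap <= 1:
        raise ValueError("overlap must lie in [0, 1]")
    m = int(math.ceil(sparsity * V))
    if m < 1:
        raise ValueError("sparsity·V must be at least 1")
    n_shared = int(round(overlap * m))
    n_private = m - n_shared
    if n_shared + N_EMOTIONS * n_private > V:
        raise ValueError(
            f"support does not fit: {N_EMOTIONS} rows × {n_private} private + "
            f"{n_shared} shared voxels exceed V={V}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(V)
    shared = perm[:n_shared]
    coefficients = np.zeros((N_EMOTIONS, V))
    for e in range(N_EMOTIONS):
        private = perm[n_shared + e * n_private : n_shared + (e + 1) * n_private]
        support = np.concatenate([shared, private]).astype(int)
        values = rng.standard_normal(support.size)
        values[values == 0.0] = 1.0  # keep the stated support size exact
        coefficients[e, support] = values
        coefficients[e] /= np.linalg.norm(coefficients[e])
    return WeightMapSet(coefficients=coefficients, grid=grid, labels=EMOTIONS)


def uniform_transition() -> np.ndarray:
    """Memoryless chain: every row is the uniform distribution."""
    return np.full((N_EMOTIONS, N_EMOTIONS), 1.0 / N_EMOTIONS)


def dwell_transition(
    mean_dwell: float, stationary: np.ndarray | None = None
) -> np.ndarray:
    """Sticky chain P = (1−α)·I + α·1πᵀ with α = 1/mean_dwell.

    Its stationary distribution is π (uniform by default); larger
    ``mean_dwell`` produces longer state runs.  ``mean_dwell=1`` gives
    independent draws from π.
    """
    if mean_dwell < 1:
        raise ValueError("mean_dwell must be ≥ 1")
    pi = (
        np.full(N_EMOTIONS, 1.0 / N_EMOTIONS)
        if stationary is None
        else np.asarray(stationary, dtype=float)
    )
    if pi.shape != (N_EMOTIONS,) or abs(pi.sum() - 1.0) > 1e-9 or np.any(pi < 0):
        raise ValueError("stationary must be a length-7 probability vector")
    alpha = 1.0 / mean_dwell
    return (1 - alpha) * np.eye(N_EMOTIONS) + alpha * np.tile(pi, (N_EMOTIONS, 1))


def generate_state_sequence(
    T: int,
    transition: np.ndarray | None = None,
    seed: int = 0,
    start: int | None = None,
) -> HiddenStateSequence:
    """Sample a hidden emotion-state Markov chain of length ``T``."""
    if T < 1:
        raise ValueError("T must be positive")
    P = uniform_transition() if transition is None else np.asarray(transition, dtype=float)
    if P.shape != (N_EMOTIONS, N_EMOTIONS) or np.any(P < 0):
        raise ValueError("transition must be a nonnegative 7×7 matrix")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError("transition rows must sum to 1")
    rng = np.random.default_rng(seed)
    cum = np.cumsum(P, axis=1)
    states = np.empty(T, dtype=int)
    if start is None:
        # start from the chain's stationary distribution when available
        evals, evecs = np.linalg.eig(P.T)
        idx = int(np.argmin(np.abs(evals - 1.0)))
        pi = np.real(evecs[:, idx])
        pi = np.abs(pi) / np.abs(pi).sum()
        states[0] = rng.choice(N_EMOTIONS, p=pi)
    else:
        states[0] = int(start)
    u = rng.random(T)
    for t in range(1, T):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t], side="right")
    return HiddenStateSequence(states=states)


def _ar1_noise(
    rng: np.random.Generator,
    T: int,
    V: int,
    ar_phi: float,
    noise_sd: float,
) -> np.ndarray:
    """Voxelwise-independent AR(1) noise with innovation sd ``noise_sd``."""
    burn = 100 if ar_phi > 0 else 0
    eps = rng.standard_normal((T + burn, V)) * noise_sd
    if ar_phi == 0:
        return eps[burn:]
    out = lfilter([1.0], [1.0, -ar_phi], eps, axis=0)
    return out[burn:]


def generate_subject_timeseries(
    weights: WeightMapSet,
    states: HiddenStateSequence,
    amplitude: float = 1.0,
    ar_phi: float = 0.3,
    noise_sd: float = 1.0,
    seed: int = 0,
    tr_seconds: float = 2.0,
    run_boundaries: tuple[int, ...] | None = None,
    subject_id: str = "sub-000",
) -> SubjectTimeSeries:
    """Voxel time series driven by a hidden state sequence.

    ``data[t] = amplitude · coefficients[states[t]] + AR(1) noise`` with
    lag-1 coefficient ``ar_phi`` and innovation sd ``noise_sd``, independent
    across voxels.  Two equal runs are assumed by default when T allows.
    """
    if not 0 <= ar_phi < 1:
        raise ValueError("ar_phi must lie in [0, 1)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    T = len(states)
    rng = np.random.default_rng(seed)
    signal = amplitude * weights.coefficients[states.states]
    data = signal + _ar1_noise(rng, T, weights.n_voxels, ar_phi, noise_sd)
    if run_boundaries is None:
        run_boundaries = (0, T // 2) if T >= 4 else (0,)
    return SubjectTimeSeries(
        data=data,
        tr_seconds=tr_seconds,
        run_boundaries=run_boundaries,
        subject_id=subject_id,
        grid=weights.grid,
    )


def _occupancy_probs(beta: np.ndarray, covariate: float) -> np.ndarray:
    """Per-state probabilities with a log-odds tilt on the flagged states.

    States with nonzero ``beta`` get exactly
    ``p_e = expit(logit(1/7) + beta_e · covariate)``; the remaining mass is
    shared equally by the untilted states, so a single-covariate binomial GLM
    of a tilted state's occupancy is correctly specified.
    """
    base = np.full(N_EMOTIONS, 1.0 / N_EMOTIONS)
    tilted = beta != 0.0
    if not tilted.any():
        return base
    p = base.copy()
    p[tilted] = expit(logit(base[tilted]) + beta[tilted] * covariate)
    mass = p[tilted].sum()
    if mass >= 1.0:
        raise ValueError("tilted occupancy probabilities exceed 1; reduce beta")
    if (~tilted).any():
        p[~tilted] = (1.0 - mass) / (~tilted).sum()
    else:
        p /= p.sum()
    return p


def generate_cohort(
    n_subjects: int,
    beta: float | Sequence[float] = 0.0,
    seed: int = 0,
    T: int = 256,
    weights: WeightMapSet | None = None,
    covariate_name: str = "cesd",
    covariate_range: tuple[float, float] = (0.0, 60.0),
    amplitude: float = 10.0,
    ar_phi: float = 0.3,
    noise_sd: float = 1.0,
    tr_seconds: float = 2.0,
) -> tuple[list[SubjectTimeSeries], pd.DataFrame]:
    """Cohort whose state occupancy is tilted by a mood covariate.

    ``beta`` is the per-emotion effect (log-odds per covariate unit) of the
    named covariate on occupancy; a scalar is interpreted as the effect on
    the sad state only.  States are drawn independently per volume from the
    tilted occupancy distribution, so decoded counts follow the binomial GLM
    the frequency-statistics stage fits.  The default amplitude is
    signal-dominated, making decoded occupancy track the planted occupancy.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    beta_vec = np.zeros(N_EMOTIONS)
    if np.isscalar(beta):
        beta_vec[EMOTIONS.index("sad")] = float(beta)
    else:
        beta_vec[:] = np.asarray(beta, dtype=float)
    rng = np.random.default_rng(seed)
    lo, hi = covariate_range

    rows = []
    cohort: list[SubjectTimeSeries] = []
    for i in range(n_subjects):
        cov = {
            "cesd": rng.uniform(0.0, 60.0),
            "stai_s": rng.uniform(20.0, 80.0),
            "neo_anxiety": float(np.clip(rng.normal(16, 5), 0, 32)),
            "neo_angry_hostility": float(np.clip(rng.normal(16, 5), 0, 32)),
            "neo_depression": float(np.clip(rng.normal(16, 5), 0, 32)),
        }
        cov[covariate_name] = rng.uniform(lo, hi)
        p = _occupancy_probs(beta_vec, cov[covariate_name])
        states = HiddenStateSequence(rng.choice(N_EMOTIONS, size=T, p=p))
        ts = generate_subject_timeseries(
            weights if weights is not None else _default_weights(),
            states,
            amplitude=amplitude,
            ar_phi=ar_phi,
            noise_sd=noise_sd,
            seed=int(rng.integers(2**31)),
            tr_seconds=tr_seconds,
            subject_id=f"sub-{i:03d}",
        )
        cohort.append(ts)
        rows.append({"subject_id": ts.subject_id, **cov})
    return cohort, pd.DataFrame(rows)


_DEFAULT_WEIGHTS_CACHE: dict[int, WeightMapSet] = {}


def _default_weights() -> WeightMapSet:
    if 0 not in _DEFAULT_WEIGHTS_CACHE:
        _DEFAULT_WEIGHTS_CACHE[0] = generate_weight_maps(seed=0)
    return _DEFAULT_WEIGHTS_CACHE[0]


def generate_experience_sampling(
    weights: WeightMapSet,
    n_events: int = 40,
    congruence: float = 0.8,
    seed: int = 0,
    isi_s: float = 30.0,
    jitter_lambda_s: float = 4.0,
    tr_seconds: float = 2.0,
    amplitude: float = 1.0,
    ar_phi: float = 0.3,
    noise_sd: float = 1.0,
    layout: RatingScreenLayout = DEFAULT_LAYOUT,
    subject_id: str = "sub-000",
) -> tuple[SubjectTimeSeries, pd.DataFrame]:
    """One experience-sampling session: time series plus rating events.

    Rating probes arrive every ``isi_s`` seconds plus Poisson(λ) jitter, so
    successive events are ≥ 30 s apart by construction.  The hidden emotion
    state is piecewise constant between probes (hence constant throughout
    every pre-rating window); with probability ``congruence`` the report
    matches the hidden state, otherwise a uniformly random other category is
    reported.  Cursor coordinates are placed inside the reported category's
    screen region at a random intensity ring.
    """
    if n_events < 1:
        raise ValueError("n_events must be positive")
    if not 0 <= congruence <= 1:
        raise ValueError("congruence must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    gaps = isi_s + rng.poisson(jitter_lambda_s, size=n_events)
    times = np.cumsum(gaps).astype(float)
    onsets = np.floor(times / tr_seconds).astype(int)
    T = int(onsets[-1]) + 3

    # hidden state: constant within each inter-probe segment
    seg_states = rng.integers(N_EMOTIONS, size=n_events + 1)
    states = np.empty(T, dtype=int)
    prev = 0
    for k, onset in enumerate(onsets):
        states[prev:onset] = seg_states[k]
        prev = onset
    states[prev:] = seg_states[-1]

    rows = []
    for k, (time_s, onset) in enumerate(zip(times, onsets)):
        true_state = int(seg_states[k])
        if rng.random() < congruence:
            reported = true_state
        else:
            others = [e for e in range(N_EMOTIONS) if e != true_state]
            reported = int(rng.choice(others))
        intensity = int(rng.integers(1, layout.n_rings + 1))
        if EMOTIONS[reported] == "neutral":
            intensity = 1
        x, y = cursor_position(reported, intensity, rng, layout)
        rows.append(
            {
                "time_s": float(time_s),
                "x": x,
                "y": y,
                "label": EMOTIONS[reported],
                "intensity": intensity,
            }
        )

    ts = generate_subject_timeseries(
        weights,
        HiddenStateSequence(states),
        amplitude=amplitude,
        ar_phi=ar_phi,
        noise_sd=noise_sd,
        seed=int(rng.integers(2**31)),
        tr_seconds=tr_seconds,
        run_boundaries=(0,),
        subject_id=subject_id,
    )
    return ts, pd.DataFrame(rows)


def generate_network_masks(
    grid: VoxelGrid,
    n_networks: int,
    seed: int = 0,
    voxels_per_network: int | None = None,
) -> list[np.ndarray]:
    """Disjoint random voxel parcels inside the brain mask.

    These stand in for canonical resting-state networks in overlap tests;
    no spatial contiguity is imposed.
    """
    if n_networks < 1:
        raise ValueError("n_networks must be positive")
    V = grid.n_voxels
    if voxels_per_network is None:
        voxels_per_network = max(V // (2 * n_networks), 1)
    if n_networks * voxels_per_network > V:
        raise ValueError("requested parcels exceed the in-mask voxel count")
    rng = np.random.default_rng(seed)
    in_mask = np.flatnonzero(grid.mask.ravel())
    chosen = rng.choice(in_mask, size=n_networks * voxels_per_network, replace=False)
    masks = []
    for k in range(n_networks):
        m = np.zeros(np.prod(grid.shape), dtype=bool)
        m[chosen[k * voxels_per_network : (k + 1) * voxels_per_network]] = True
        masks.append(m.reshape(grid.shape))
    return masks
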