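"""Acquisition design arithmetic for the resting-state protocol.

The emulated protocol acquires two resting-state runs of 4 min 16 s each at a
repetition time (TR) of 2 s, i.e. 128 volumes per run, 256 volumes total,
spanning 8.53 minutes of scanning.  Experience-sampling analyses average the
volumes in a fixed window (10 s by default) preceding each rating probe.
"""

from __future__ import annotations

import math

TR_SECONDS = 2.0
RUN_DURATION_SECONDS = 4 * 60 + 16.0  # 4 min 16 s
N_RUNS = 2
PRERATING_WINDOW_SECONDS = 10.0


def volumes_per_run(
    run_duration_s: float = RUN_DURATION_SECONDS, tr_s: float = TR_SECONDS
) -> int:
    """Number of volumes acquired in one run."""
    n = run_duration_s / tr_s
    if abs(n - round(n)) > 1e-9:
        raise ValueError("run duration must be an integer number of TRs")
    return int(round(n))


def total_scan_minutes(
    n_runs: int = N_RUNS,
    run_duration_s: float = RUN_DURATION_SECONDS,
) -> float:
    """Total resting-state duration in minutes across runs."""
    return n_runs * run_duration_s / 60.0


def total_volumes(
    n_runs: int = N_RUNS,
    run_duration_s: float = RUN_DURATION_SECONDS,
    tr_s: float = TR_SECONDS,
) -> int:
    return n_runs * volumes_per_run(run_duration_s, tr_s)


def prerating_window_volumes(
    window_s: float = PRERATING_WINDOW_SECONDS, tr_s: float = TR_SECONDS
) -> int:
    """Whole volumes fitting in the pre-rating window (partial volumes drop)."""
    if window_s <= 0 or tr_s <= 0:
        raise ValueError("window and TR must be positive")
    return int(math.floor(window_s / tr_s + 1e-12))
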