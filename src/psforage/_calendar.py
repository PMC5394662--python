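"""Experiment calendar arithmetic.

All device timestamps are decimal seconds since the *experiment epoch*:
midnight at the start of the first Monday of the experiment. Puzzle-boxes
operate on weekdays (Monday-Friday) inside the active window (06:00-18:00
by default); open feeders operate on weekend days. Latencies and trajectory
bins are measured in *active time*: the cumulative seconds of puzzle-box
availability elapsed, skipping nights and weekends.
"""

from __future__ import annotations

import numpy as np

SECONDS_PER_DAY = 86_400.0
#: default active window, seconds after local midnight (06:00-18:00)
ACTIVE_START_S = 6 * 3600.0
ACTIVE_END_S = 18 * 3600.0
#: RFID scanner tick (readers poll tags 16 times per second)
TICK_S = 1.0 / 16.0

__all__ = [
    "ACTIVE_START_S",
    "ACTIVE_END_S",
    "TICK_S",
    "SECONDS_PER_DAY",
    "day_index",
    "is_weekday",
    "is_weekend",
    "quantize",
    "active_seconds_elapsed",
]


def day_index(t: np.ndarray | float) -> np.ndarray | int:
    """Calendar day index (0 = first Monday) of epoch-time ``t``."""
    return (np.asarray(t) // SECONDS_PER_DAY).astype(int)


def is_weekday(day: np.ndarray | int) -> np.ndarray | bool:
    return np.asarray(day) % 7 < 5


def is_weekend(day: np.ndarray | int) -> np.ndarray | bool:
    return np.asarray(day) % 7 >= 5


def quantize(t: np.ndarray | float) -> np.ndarray | float:
    """Snap epoch seconds onto the 1/16-s scanner grid."""
    return np.round(np.asarray(t) / TICK_S) * TICK_S


def active_seconds_elapsed(
    t,
    active_start_s: float = ACTIVE_START_S,
    active_end_s: float = ACTIVE_END_S,
    weekdays_only: bool = True,
):
    """Active-time seconds elapsed from the experiment epoch to ``t``.

    Counts only seconds inside the daily active window, and (by default) only
    on weekdays, matching the availability of the puzzle-boxes. ``t`` may be
    a scalar or array of epoch seconds.

    Examples
    --------
    A detection at 08:00 on the first Monday is 7200 active seconds in
    (06:00-08:00); one at 07:00 on Tuesday is 12 h (Monday) + 1 h = 46 800 s.
    """
    t = np.asarray(t, dtype=float)
    if active_end_s <= active_start_s:
        raise ValueError("active window is empty")
    window = active_end_s - active_start_s
    day = t // SECONDS_PER_DAY
    tod = t - day * SECONDS_PER_DAY
    day = day.astype(int)

    # full active days strictly before `day`
    if weekdays_only:
        weeks, rem = np.divmod(day, 7)
        n_active_days = weeks * 5 + np.minimum(rem, 5)
        counts_today = rem < 5
    else:
        n_active_days = day
        counts_today = np.ones_like(day, dtype=bool)

    within = np.clip(tod - active_start_s, 0.0, window)
    out = n_active_days * window + np.where(counts_today, within, 0.0)
    if out.ndim == 0:
        return float(out)
    return out
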