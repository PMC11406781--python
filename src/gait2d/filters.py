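"""Trajectory conditioning shared by the tracker and the event detector."""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, filtfilt

__all__ = ["lowpass", "central_velocity", "fill_short_gaps"]


def lowpass(x: np.ndarray, fps: float = 30.0, cutoff: float = 6.0,
            order: int = 4) -> np.ndarray:
    """Zero-lag low-pass (Butterworth, applied forward and backward).

    Operates along axis 0; NaNs are not allowed (fill gaps first).
    """
    x = np.asarray(x, float)
    if np.isnan(x).any():
        raise ValueError("cannot filter a series containing missing samples")
    b, a = butter(order, cutoff / (fps / 2.0))
    return filtfilt(b, a, x, axis=0)


def central_velocity(x: np.ndarray, fps: float = 30.0) -> np.ndarray:
    """Central-difference derivative along axis 0, one-sided at the ends."""
    x = np.asarray(x, float)
    v = np.empty_like(x)
    v[1:-1] = (x[2:] - x[:-2]) * (fps / 2.0)
    v[0] = (x[1] - x[0]) * fps
    v[-1] = (x[-1] - x[-2]) * fps
    return v


def fill_short_gaps(x: np.ndarray, max_gap: int = 5):
    """Linearly interpolate NaN runs of length <= ``max_gap`` along axis 0.

    Returns (filled array, filled mask, still_missing mask).  Leading and
    trailing NaN runs are extrapolated as constants only if short enough.
    """
    x = np.array(x, float, copy=True)
    n = x.shape[0]
    miss = np.isnan(x if x.ndim == 1 else x[:, 0])
    filled = np.zeros(n, bool)
    if not miss.any():
        return x, filled, miss.copy()
    idx = np.flatnonzero(miss)
    # group into runs
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    good = np.flatnonzero(~miss)
    for run in runs:
        if len(run) == 0 or len(run) > max_gap or len(good) == 0:
            continue
        lo, hi = run[0] - 1, run[-1] + 1
        cols = x[:, None] if x.ndim == 1 else x
        if lo < 0 and hi < n:
            cols[run] = cols[hi]
        elif hi >= n and lo >= 0:
            cols[run] = cols[lo]
        elif lo >= 0 and hi < n:
            w = (run - lo) / (hi - lo)
            cols[run] = (1 - w[:, None]) * cols[lo] + w[:, None] * cols[hi]
        else:
            continue
        if x.ndim == 1:
            x[run] = cols[run, 0]
        filled[run] = True
    still = np.isnan(x if x.ndim == 1 else x[:, 0])
    return x, filled, still
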