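"""Gait speed, step length and cohort-level aggregation.

Step length follows the foreground/background definition of a single lateral
camera: the horizontal distance between the heel of the foreground foot at
its initial contact and the heel of the background foot at the next
(contralateral) initial contact.  Gait speed is the forward displacement of
the greater trochanter between the first and last detected IC of the trial
divided by the elapsed time; an alternative cadence-based estimate
(mean step length / mean step time) is available behind a switch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["step_length", "gait_speed", "manual_reference_compare",
           "cohort_table", "SpatioTemporal"]


@dataclass
class SpatioTemporal:
    """Per trial-side spatio-temporal summary."""

    gait_speed: float
    step_lengths: list = field(default_factory=list)

    @property
    def mean_step_length(self) -> float:
        return float(np.mean(self.step_lengths)) if self.step_lengths else np.nan


def step_length(heel_by_side: dict, ic_by_side: dict, foreground: str,
                fps: float = 30.0) -> list:
    """Step lengths (m) for each foreground IC followed by a background IC.

    ``heel_by_side`` maps side -> (n, 2) heel positions in metres;
    ``ic_by_side`` maps side -> IC frame indices.  Pairs in which the
    background IC precedes the foreground IC are skipped.
    """
    bg = [s for s in heel_by_side if s != foreground][0]
    fg_ics = sorted(int(i) for i in ic_by_side[foreground])
    bg_ics = sorted(int(i) for i in ic_by_side[bg])
    out = []
    for fic in fg_ics:
        nxt = [b for b in bg_ics if b > fic]
        if not nxt:
            continue
        bic = nxt[0]
        # the contralateral IC must be the immediately following step
        intervening = [f for f in fg_ics if fic < f < bic]
        if intervening:
            continue
        x0 = heel_by_side[foreground][fic, 0]
        x1 = heel_by_side[bg][bic, 0]
        if np.isnan(x0) or np.isnan(x1):
            continue
        out.append(float(abs(x1 - x0)))
    if not out:
        warnings.warn("no qualifying foreground/background IC pair")
    return out


def gait_speed(trochanter_xy: np.ndarray, ic_frames, fps: float = 30.0,
               method: str = "regression",
               step_lengths=None, step_times=None) -> float:
    """Trial gait speed in m/s from the trochanter's forward progression
    between the first and last initial contact of the trial.

    ``regression`` (default): least-squares linear trend of the trochanter's
    forward position over the IC-bounded interval, with a first-harmonic
    term (period = mean IC spacing) absorbing the within-cycle pelvis
    fluctuation.  On a linearly advancing trochanter this equals
    displacement over elapsed time exactly, but it is far less sensitive to
    single-frame uncertainty in the bounding contact frames.
    ``displacement``: raw endpoint displacement over elapsed time.
    ``cadence``: mean step length divided by mean step time.
    """
    ics = sorted(int(i) for i in ic_frames)
    if method == "cadence":
        if not step_lengths or step_times is None or len(step_times) == 0:
            raise ValueError("cadence method needs step_lengths and step_times")
        return float(np.mean(step_lengths) / np.mean(step_times))
    if len(ics) < 2:
        raise ValueError("gait speed needs at least two initial contacts")
    first, last = ics[0], ics[-1]
    dt = (last - first) / fps
    if method == "displacement":
        v = float(abs(trochanter_xy[last, 0] - trochanter_xy[first, 0]) / dt)
    elif method == "regression":
        fr = np.arange(first, last + 1)
        t = fr / fps
        x = np.asarray(trochanter_xy, float)[first:last + 1, 0]
        period = dt / max(1, len(ics) - 1)
        w = 2.0 * np.pi / period
        A = np.column_stack([np.ones_like(t), t, np.sin(w * t), np.cos(w * t)])
        coef, *_ = np.linalg.lstsq(A, x, rcond=None)
        v = float(abs(coef[1]))
    else:
        raise ValueError(f"unknown gait-speed method {method!r}")
    if v < 1e-9:
        warnings.warn("degenerate trial: walker is stationary")
    return v


def manual_reference_compare(auto_results, reference_results) -> dict:
    """Error statistics between automatic and reference event pipelines.

    Both arguments are sequences of (gait_speed, mean_step_length) tuples on
    the same trials; returns mean and SD of the absolute differences.
    """
    if len(auto_results) != len(reference_results):
        raise ValueError("mismatched trial counts between auto and reference")
    sp = np.array([abs(a[0] - r[0]) for a, r in zip(auto_results, reference_results)])
    st = np.array([abs(a[1] - r[1]) for a, r in zip(auto_results, reference_results)])
    return {
        "speed_abs_err_mean": float(np.mean(sp)),
        "speed_abs_err_sd": float(np.std(sp, ddof=1)) if sp.size > 1 else np.nan,
        "step_abs_err_mean": float(np.mean(st)),
        "step_abs_err_sd": float(np.std(st, ddof=1)) if st.size > 1 else np.nan,
        "n_trials": int(sp.size),
    }


def cohort_table(side_rows: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Cohort summary (mean, SD, range) over participant-side rows.

    ``side_rows`` has one row per participant-side with numeric parameter
    columns; missing entries are skipped column-wise.  SD is the sample SD
    (n-1) and is NaN for a single row.  Returns the input with three extra
    summary rows labelled mean/SD/min/max in the index.
    """
    if len(side_rows) == 0:
        raise ValueError("cohort table needs at least one participant-side row")
    if columns is None:
        columns = [c for c in side_rows.columns
                   if pd.api.types.is_numeric_dtype(side_rows[c])
                   and c not in ("participant", "trials")]
    stats = {}
    for c in columns:
        v = pd.to_numeric(side_rows[c], errors="coerce").dropna()
        stats[c] = {
            "mean": v.mean() if len(v) else np.nan,
            "sd": v.std(ddof=1) if len(v) > 1 else np.nan,
            "min": v.min() if len(v) else np.nan,
            "max": v.max() if len(v) else np.nan,
            "n": len(v),
        }
    return pd.DataFrame(stats)
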