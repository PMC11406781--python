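"""Trial-level analysis: landmark trajectories -> kinematics, events and
spatio-temporal parameters.

Accepts either a simulated/imported :class:`~gait2d.walker.WalkerTrajectory`
(both legs fully landmarked) or :class:`~gait2d.tracking.TrackedLandmarks`
from video (foreground-leg kinematics, both feet).  Raw trajectories are
gap-filled and low-pass filtered before differentiation; event detection,
cycle normalization and the spatio-temporal computations then share the
same smoothed series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import DWELL, V_THRESH, GaitEvents, detect_events
from .filters import fill_short_gaps, lowpass
from .kinematics import JointKinematics, compute_joint_angles, normalize_cycles
from .spatiotemporal import SpatioTemporal, gait_speed, step_length
from .tracking import (MAX_GAP_FRAMES, MIN_VALID_FRACTION, TrackedLandmarks,
                       TrialRejectedError)
from .walker import LANDMARKS, SIDES, WalkerTrajectory

__all__ = ["TrialAnalysis", "analyze_trial", "smooth_trajectory"]


@dataclass
class TrialAnalysis:
    """Everything the pipeline derives from one walking trial."""

    kinematics: dict                 # side -> JointKinematics (may be absent)
    events: GaitEvents
    spatiotemporal: dict             # side -> SpatioTemporal
    smoothed: dict                   # side -> {landmark: (n,2) m}
    quality: dict = field(default_factory=dict)
    foreground_side: str = "right"


def smooth_trajectory(sides: dict, fps: float = 30.0, cutoff: float = 6.0,
                      max_gap: int = MAX_GAP_FRAMES,
                      min_valid_fraction: float = MIN_VALID_FRACTION):
    """Gap-fill (<= max_gap) and zero-lag low-pass filter a landmark block.

    Returns (smoothed sides dict, quality dict).  Raises
    :class:`TrialRejectedError` when fewer than ``min_valid_fraction`` of
    frames have both feet present — the images/trajectories do not support
    reliable foot identification.
    """
    n = len(next(iter(next(iter(sides.values())).values())))
    feet_valid = np.ones(n, bool)
    for side in sides:
        for k in ("heel", "toe"):
            feet_valid &= np.isfinite(np.asarray(sides[side][k])[:, 0])
    valid_fraction = float(feet_valid.mean())
    if valid_fraction < min_valid_fraction:
        raise TrialRejectedError(
            "feet_unclear",
            f"valid-feet fraction {valid_fraction:.2f} < {min_valid_fraction}")
    out = {}
    n_interp = 0
    for side in sides:
        out[side] = {}
        for k, arr in sides[side].items():
            filled, interp, still = fill_short_gaps(np.asarray(arr, float),
                                                    max_gap)
            n_interp += int(interp.sum())
            if still.any():
                finite = np.isfinite(filled[:, 0])
                if finite.any():
                    i0, i1 = np.flatnonzero(finite)[[0, -1]]
                    if np.isfinite(filled[i0:i1 + 1, 0]).all():
                        filled[i0:i1 + 1] = lowpass(filled[i0:i1 + 1], fps,
                                                    cutoff)
                out[side][k] = filled
            else:
                out[side][k] = lowpass(filled, fps, cutoff)
    return out, {"valid_feet_fraction": valid_fraction,
                 "interpolated_samples": n_interp}


def analyze_trial(obj, v_thresh: float = V_THRESH, dwell: int = DWELL,
                  direction: float = 1.0, cutoff: float = 6.0,
                  events: GaitEvents | None = None) -> TrialAnalysis:
    """Run events + kinematics + spatio-temporal analysis on one trial.

    ``obj`` is a WalkerTrajectory (raw landmarks are smoothed here first) or
    TrackedLandmarks (already smoothed by the tracker).  Pass ``events`` to
    reuse externally determined (e.g. ground-truth or manually annotated)
    initial contacts instead of detecting them.
    """
    fps = getattr(obj, "fps", 30.0)
    fg = obj.foreground_side
    if isinstance(obj, TrackedLandmarks):
        smoothed, quality = obj.sides, dict(obj.quality)
    elif isinstance(obj, WalkerTrajectory):
        smoothed, quality = smooth_trajectory(obj.sides, fps, cutoff)
    else:
        raise TypeError("analyze_trial expects WalkerTrajectory or "
                        "TrackedLandmarks")

    if events is None:
        events = detect_events(
            {s: {"heel": smoothed[s]["heel"], "toe": smoothed[s]["toe"]}
             for s in smoothed},
            fps=fps, v_thresh=v_thresh, dwell=dwell)

    kinematics = {}
    for side in smoothed:
        if np.isnan(smoothed[side]["greater_trochanter"]).all():
            continue  # background-leg pen marks not tracked from video
        raw = compute_joint_angles(smoothed[side], direction)
        try:
            cycles = normalize_cycles(raw, events, side=side)
        except ValueError:
            cycles = []
        kin = JointKinematics(side=side,
                              timestamps=np.asarray(obj.timestamps),
                              raw=raw, cycles=cycles)
        kinematics[side] = kin

    st = {}
    heel_by_side = {s: smoothed[s]["heel"] for s in smoothed}
    for side in smoothed:
        ics = events.ic.get(side, [])
        try:
            speed = gait_speed(
                smoothed[side]["greater_trochanter"]
                if not np.isnan(smoothed[side]["greater_trochanter"]).all()
                else smoothed[fg]["greater_trochanter"],
                ics, fps)
        except ValueError:
            speed = np.nan
        with np.errstate(invalid="ignore"):
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                steps = step_length(heel_by_side, events.ic, foreground=side,
                                    fps=fps)
        st[side] = SpatioTemporal(gait_speed=speed, step_lengths=steps)

    return TrialAnalysis(kinematics=kinematics, events=events,
                         spatiotemporal=st, smoothed=smoothed,
                         quality=quality, foreground_side=fg)
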