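"""Frame sequence -> per-frame landmark trajectories.

Feet are identified purely by sock color (red = right, blue = left).  Pen
marks are assigned to the foreground leg using the depth-proxy channel when
the sequence carries one (the analogue of the RGB-D camera's depth image);
without it, marks are matched to the previous frame's positions.  The
background leg's pen marks are intentionally not tracked — behind a single
lateral camera they are frequently occluded by the near leg — so joint
kinematics from video are produced for the foreground side, while both feet
are tracked for event detection and spatio-temporal parameters.

Tracked pixel positions are converted to metric, y-up world coordinates at
this module boundary.  Gaps of up to ``max_gap`` frames are filled by
linear interpolation (and flagged); trajectories are then smoothed with a
zero-lag 4th-order low-pass at 6 Hz.  Trials in which fewer than 80 % of
frames have both feet validly detected are rejected with a machine-readable
reason code, mirroring the exclusion of recordings whose images do not
allow reliable foot identification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2hsv

from .filters import fill_short_gaps, lowpass
from .scene import DEPTH_FG_LEG, FrameSequence
from .segment import ColorSpec, class_mask, detect_pen_marks, extract_foot_points
from .walker import LANDMARKS, SIDES

__all__ = ["TrackedLandmarks", "TrialRejectedError", "track_sequence",
           "MAX_GAP_FRAMES", "MIN_VALID_FRACTION"]

log = logging.getLogger(__name__)

MAX_GAP_FRAMES = 5
MIN_VALID_FRACTION = 0.8


class TrialRejectedError(RuntimeError):
    """A trial whose images do not support reliable foot identification."""

    def __init__(self, reason_code: str, detail: str = ""):
        self.reason_code = reason_code
        super().__init__(f"trial rejected [{reason_code}] {detail}".strip())


@dataclass
class TrackedLandmarks:
    """Tracked landmark block with the same schema as a walker trajectory.

    ``sides`` holds smoothed metric positions (NaN = missing after gap
    filling); ``sides_px`` the raw pixel detections.  ``quality`` reports
    the fraction of frames with both feet validly detected and per-landmark
    interpolated-frame counts.
    """

    timestamps: np.ndarray
    sides: dict
    sides_px: dict
    pixels_per_meter: float
    quality: dict
    fps: float = 30.0
    foreground_side: str = "right"

    @property
    def n_frames(self) -> int:
        return len(self.timestamps)


def _track_frame(hsv, depth, spec, direction):
    """Detections for one frame: feet from sock color, fg marks from depth."""
    out = {s: {k: None for k in LANDMARKS} for s in SIDES}
    for side, cls in (("right", "right_sock_red"), ("left", "left_sock_blue")):
        pts = extract_foot_points(class_mask(hsv, spec, cls), direction)
        if pts is not None:
            out[side]["heel"], out[side]["toe"] = pts
    region = depth == DEPTH_FG_LEG if depth is not None else None
    marks = detect_pen_marks(hsv, spec, region)
    return out, marks


def _match_marks_to_previous(marks: dict, prev: dict) -> dict:
    """Reassign detected marks by proximity to the previous frame (fallback
    when no depth proxy distinguishes the legs)."""
    if prev is None or all(v is None for v in prev.values()):
        return marks
    pts = [v for v in marks.values() if v is not None]
    out = {}
    for name in marks:
        p_prev = prev.get(name)
        if p_prev is None or not pts:
            out[name] = marks[name]
            continue
        d = [float(np.hypot(*(p - p_prev))) for p in pts]
        out[name] = pts[int(np.argmin(d))]
    return out


def track_sequence(frames: FrameSequence, spec: ColorSpec | None = None,
                   walk_direction: float = 1.0,
                   max_gap: int = MAX_GAP_FRAMES,
                   min_valid_fraction: float = MIN_VALID_FRACTION,
                   smooth_cutoff_hz: float = 6.0) -> TrackedLandmarks:
    """Segment, track, gap-fill and smooth a rendered/recorded sequence."""
    if frames.n_frames < 2:
        raise ValueError("tracking needs at least two frames")
    spec = spec or ColorSpec()
    scene = frames.scene
    fg = scene.foreground_side
    n = frames.n_frames

    px = {s: {k: np.full((n, 2), np.nan) for k in LANDMARKS} for s in SIDES}
    prev_marks = None
    for f in range(n):
        img = frames.frames[f]
        depth = frames.depth[f] if frames.depth is not None else None
        # restrict color work to the walker's bounding box when the depth
        # proxy identifies it; detections are shifted back afterwards
        off = np.zeros(2)
        if depth is not None and depth.any():
            rows = np.flatnonzero(depth.any(axis=1))
            cols = np.flatnonzero(depth.any(axis=0))
            r0 = max(0, rows[0] - 8)
            r1 = min(img.shape[0], rows[-1] + 9)
            c0 = max(0, cols[0] - 8)
            c1 = min(img.shape[1], cols[-1] + 9)
            img = img[r0:r1, c0:c1]
            depth = depth[r0:r1, c0:c1]
            off = np.array([c0, r0], float)
        hsv = rgb2hsv(img)
        feet, marks = _track_frame(hsv, depth, spec, walk_direction)
        if depth is None:
            marks = _match_marks_to_previous(marks, prev_marks)
        prev_marks = marks
        for side in SIDES:
            for k in ("heel", "toe"):
                if feet[side][k] is not None:
                    px[side][k][f] = feet[side][k] + off
        for k, v in marks.items():
            if v is not None:
                px[fg][k][f] = v + off

    feet_valid = np.ones(n, bool)
    for side in SIDES:
        for k in ("heel", "toe"):
            feet_valid &= np.isfinite(px[side][k][:, 0])
    valid_fraction = float(feet_valid.mean())
    if valid_fraction < min_valid_fraction:
        raise TrialRejectedError(
            "feet_unclear",
            f"valid-feet fraction {valid_fraction:.2f} < {min_valid_fraction}")

    # pixel -> metric (y-up), gap fill, smooth
    sides_m = {}
    interpolated = {}
    for side in SIDES:
        sides_m[side] = {}
        for k in LANDMARKS:
            world = scene.px_to_world(px[side][k])
            filled, interp_mask, still = fill_short_gaps(world, max_gap)
            interpolated[f"{side}/{k}"] = int(interp_mask.sum())
            if still.any():
                if still.all():
                    sides_m[side][k] = filled
                    continue
                # smooth only the contiguous finite span; long interior gaps
                # would need resegmentation and stay NaN
                finite = np.isfinite(filled[:, 0])
                i0, i1 = np.flatnonzero(finite)[[0, -1]]
                if np.isfinite(filled[i0:i1 + 1, 0]).all():
                    filled[i0:i1 + 1] = lowpass(filled[i0:i1 + 1], frames.fps,
                                                smooth_cutoff_hz)
                sides_m[side][k] = filled
            else:
                sides_m[side][k] = lowpass(filled, frames.fps, smooth_cutoff_hz)

    return TrackedLandmarks(
        timestamps=frames.timestamps.copy(),
        sides=sides_m,
        sides_px=px,
        pixels_per_meter=scene.pixels_per_meter,
        quality={"valid_feet_fraction": valid_fraction,
                 "interpolated_frames": interpolated},
        fps=frames.fps,
        foreground_side=fg,
    )
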