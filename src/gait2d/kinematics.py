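"""Sagittal joint angles from 2D landmark positions, and gait-cycle normalization.

Conventions (all angles in degrees, walking direction +x, y up):

* **Hip flexion** — inclination of the femur (greater trochanter → lateral
  epicondyle) measured from the downward vertical, positive when the knee is
  forward of the hip. A vertical thigh reads 0°. This is a thigh-versus-room
  angle, not thigh-versus-pelvis: a single lateral camera cannot see the
  pelvis, so the value carries a known offset against marker-based 3D systems.
* **Knee flexion** — signed angle between the femur vector and the tibia
  vector (epicondyle → malleolus); 0° when collinear (full extension),
  positive in flexion, negative in hyperextension.
* **Ankle dorsiflexion** — signed angle between the foot axis (heel → toe)
  and the forward perpendicular of the tibia; 0° when the foot is
  perpendicular to the shank, dorsiflexion positive, plantarflexion negative.
* **Foot orientation** — angle of the heel → toe line to the horizontal,
  positive when the heel is higher than the toe (heel up).

For a chain sharing the same landmarks the identity
``foot_orientation = knee - hip - ankle`` holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "hip_flexion",
    "knee_flexion",
    "ankle_dorsiflexion",
    "foot_orientation",
    "normalize_cycles",
    "JointKinematics",
    "ANGLE_NAMES",
    "N_CYCLE_SAMPLES",
]

ANGLE_NAMES = ("hip", "knee", "ankle", "foot")
N_CYCLE_SAMPLES = 101  # 0..100 % inclusive


def _as_xy(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape[-1] != 2:
        raise ValueError("landmark positions must have a trailing dimension of 2 (x, y)")
    return a


def _check_nonzero(v: np.ndarray, what: str) -> None:
    norm = np.hypot(v[..., 0], v[..., 1])
    if np.any(norm < 1e-12):
        raise ValueError(f"degenerate {what}: coincident landmark positions")


def hip_flexion(trochanter, epicondyle, direction: float = 1.0):
    """Femur inclination from the downward vertical, flexion positive.

    ``direction`` is +1 when walking toward +x, -1 toward -x; it flips the
    sign so flexion stays positive regardless of walking direction.
    """
    t, e = _as_xy(trochanter), _as_xy(epicondyle)
    f = e - t
    _check_nonzero(f, "femur vector")
    ang = np.degrees(np.arctan2(direction * f[..., 0], -f[..., 1]))
    return ang if ang.ndim else float(ang)


def knee_flexion(trochanter, epicondyle, malleolus, direction: float = 1.0):
    """Signed femur-to-tibia angle: 0° extended, flexion positive."""
    t, e, m = _as_xy(trochanter), _as_xy(epicondyle), _as_xy(malleolus)
    f = e - t
    s = m - e
    _check_nonzero(f, "femur vector")
    _check_nonzero(s, "tibia vector")
    cross = s[..., 0] * f[..., 1] - s[..., 1] * f[..., 0]
    dot = f[..., 0] * s[..., 0] + f[..., 1] * s[..., 1]
    ang = np.degrees(np.arctan2(direction * cross, dot))
    return ang if ang.ndim else float(ang)


def ankle_dorsiflexion(epicondyle, malleolus, heel, toe, direction: float = 1.0):
    """Foot axis relative to the tibia perpendicular: dorsiflexion positive."""
    e, m = _as_xy(epicondyle), _as_xy(malleolus)
    h, p = _as_xy(heel), _as_xy(toe)
    s = m - e
    u = p - h
    _check_nonzero(s, "tibia vector")
    _check_nonzero(u, "foot vector")
    # forward perpendicular of the (downward) tibia vector
    perp = np.stack([-direction * s[..., 1], direction * s[..., 0]], axis=-1)
    cross = perp[..., 0] * u[..., 1] - perp[..., 1] * u[..., 0]
    dot = perp[..., 0] * u[..., 0] + perp[..., 1] * u[..., 1]
    ang = np.degrees(np.arctan2(direction * cross, dot))
    return ang if ang.ndim else float(ang)


def foot_orientation(heel, toe, direction: float = 1.0):
    """Heel→toe line versus the horizontal; heel-up positive, heel-down negative."""
    h, p = _as_xy(heel), _as_xy(toe)
    u = p - h
    _check_nonzero(u, "foot vector")
    ang = -np.degrees(np.arctan2(u[..., 1], direction * u[..., 0]))
    return ang if ang.ndim else float(ang)


@dataclass
class JointKinematics:
    """Raw per-frame angle series plus cycle-normalized curves for one side.

    ``raw`` maps angle name -> (n_frames,) array in degrees (NaN where the
    source landmarks were missing).  ``cycles`` is a list of per-cycle dicts:
    each holds the four 101-point normalized curves, the (ic, to, next_ic)
    frame triple and the toe-off percentage.
    """

    side: str
    timestamps: np.ndarray
    raw: dict
    cycles: list = field(default_factory=list)

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    def mean_curves(self) -> dict:
        """Pointwise mean of the normalized curves across cycles."""
        if not self.cycles:
            raise ValueError("no complete gait cycles to average")
        return {
            name: np.mean([c["curves"][name] for c in self.cycles], axis=0)
            for name in ANGLE_NAMES
        }

    @property
    def mean_toe_off_pct(self) -> float:
        if not self.cycles:
            raise ValueError("no complete gait cycles")
        return float(np.mean([c["toe_off_pct"] for c in self.cycles]))


def compute_joint_angles(landmarks: dict, direction: float = 1.0) -> dict:
    """Per-frame hip/knee/ankle/foot angle series from a landmark dict.

    ``landmarks`` maps landmark name -> (n_frames, 2) arrays in metres
    (``greater_trochanter``, ``lateral_epicondyle``, ``lateral_malleolus``,
    ``heel``, ``toe``).  Frames with any required landmark missing (NaN)
    yield NaN angles.
    """
    t = np.asarray(landmarks["greater_trochanter"], float)
    e = np.asarray(landmarks["lateral_epicondyle"], float)
    m = np.asarray(landmarks["lateral_malleolus"], float)
    h = np.asarray(landmarks["heel"], float)
    p = np.asarray(landmarks["toe"], float)
    n = t.shape[0]
    out = {name: np.full(n, np.nan) for name in ANGLE_NAMES}
    ok_te = np.isfinite(t).all(axis=1) & np.isfinite(e).all(axis=1)
    ok_m = np.isfinite(m).all(axis=1)
    ok_f = np.isfinite(h).all(axis=1) & np.isfinite(p).all(axis=1)
    with np.errstate(invalid="ignore"):
        f = e - t
        s = m - e
        u = p - h
        out["hip"][ok_te] = np.degrees(
            np.arctan2(direction * f[ok_te, 0], -f[ok_te, 1]))
        km = ok_te & ok_m
        out["knee"][km] = np.degrees(np.arctan2(
            direction * (s[km, 0] * f[km, 1] - s[km, 1] * f[km, 0]),
            f[km, 0] * s[km, 0] + f[km, 1] * s[km, 1]))
        am = ok_te & ok_m & ok_f
        perp = np.stack([-direction * s[:, 1], direction * s[:, 0]], axis=-1)
        out["ankle"][am] = np.degrees(np.arctan2(
            direction * (perp[am, 0] * u[am, 1] - perp[am, 1] * u[am, 0]),
            perp[am, 0] * u[am, 0] + perp[am, 1] * u[am, 1]))
        out["foot"][ok_f] = -np.degrees(np.arctan2(u[ok_f, 1], direction * u[ok_f, 0]))
    return out


def normalize_cycles(raw: dict, events, timestamps=None, side: str | None = None):
    """Resample raw angle series onto 0–100 % of each gait cycle.

    ``events`` provides ``cycles(side)`` -> list of (ic, to, next_ic) frame
    triples (half-open cycle [ic, next_ic)); alternatively pass a list of
    triples directly.  Cycles containing NaN frames in any angle are dropped
    with a log entry.  Returns a list of per-cycle dicts with 101-point
    curves and the toe-off percentage.
    """
    import logging

    log = logging.getLogger(__name__)
    if hasattr(events, "cycles"):
        triples = events.cycles(side)
    else:
        triples = list(events)
    if not triples:
        raise ValueError("no complete gait cycle (IC to next same-side IC) available")
    n = len(next(iter(raw.values())))
    out = []
    for ic, to, nxt in triples:
        if not (0 <= ic < to < nxt < n):
            raise ValueError(f"cycle ({ic},{to},{nxt}) outside the {n}-frame trial")
        # the closing IC frame supplies the 100 % sample (it also opens the
        # next half-open cycle)
        grid = np.linspace(ic, nxt, N_CYCLE_SAMPLES)
        bad = False
        curves = {}
        for name, series in raw.items():
            seg = series[ic:nxt + 1]
            if np.isnan(seg).any():
                bad = True
                break
            curves[name] = np.interp(grid, np.arange(ic, nxt + 1), seg)
        if bad:
            log.info("cycle (%d,%d,%d) dropped: missing frames inside cycle", ic, to, nxt)
            continue
        toe_off_pct = 100.0 * (to - ic) / (nxt - ic)
        out.append({"curves": curves, "cycle": (ic, to, nxt), "toe_off_pct": toe_off_pct})
    if not out:
        raise ValueError("all gait cycles contained missing frames")
    return out
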