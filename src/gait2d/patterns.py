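"""Parametric sagittal joint-angle curves for one gait cycle.

A normal walking template is defined by editable keyframes (cycle %, degrees)
for hip, knee and ankle, interpolated with periodic cubic splines so value and
slope are continuous across the 100 % → 0 % wrap.  Each named clinical gait
pattern is a set of default additive offset curves on top of that template
(zeroing the offsets recovers the normal template exactly):

* ``normal`` — heel-strike gait with the three foot rockers (heel contact
  0–10 %, foot flat 10–40 %, heel rise 40 % to toe-off).
* ``true_equinus`` — toe-walking, ankle plantarflexed throughout the cycle,
  knee and hip extended in stance (Rodda type I analogue).
* ``jump`` — toe-walking with ankle plantarflexion plus flexed knee and hip
  (type II analogue).
* ``apparent_equinus`` — toe-walking with a normal ankle dorsiflexion range;
  the toe contact comes from increased knee and hip flexion (type III).
* ``crouch`` — excessive ankle dorsiflexion with excessive knee and hip
  flexion, heel-contact gait (type IV analogue).
* ``short_hamstring`` — increased knee flexion at initial contact and at
  terminal swing, otherwise near-normal.
* ``hyperextension`` — foot flat from initial contact (no first rocker),
  plantarflexed ankle at contact with limited stance dorsiflexion, and knee
  hyperextension in stance (plantarflexion/knee-extension couple).

The foot-orientation curve is never free: for a planar thigh-shank-foot chain
``foot = knee - hip - ankle`` (heel-up positive), so it is derived from the
three joint curves and stays consistent with the rendered geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .kinematics import N_CYCLE_SAMPLES

__all__ = ["GaitPatternSpec", "NoiseSpec", "generate_joint_curves", "PATTERN_NAMES"]

CYCLE_GRID = np.linspace(0.0, 100.0, N_CYCLE_SAMPLES)

# ---------------------------------------------------------------------------
# keyframes: (cycle %, degrees); first and last value must match (periodic)

# Slow-walking normal template (cadence ~109 steps/min, step ~0.38 m): hip
# and tibia excursions are scaled to the short stride so the stance-phase
# pelvis advance stays consistent with a steady walking speed, while the
# knee keeps its full ~60 deg swing-flexion range.
_NORMAL_KEYS = {
    "hip": [(0, 17), (15, 11), (30, 1), (45, -8), (55, -10), (62, -6),
            (75, 5), (85, 14), (93, 18), (100, 17)],
    "knee": [(0, 5), (8, 13), (15, 15), (30, 7), (40, 4), (50, 8), (60, 22),
             (70, 55), (76, 62), (85, 30), (93, 7), (100, 5)],
    # designed through the foot-orientation rockers; see _NORMAL_FOOT below
}

# foot orientation for the normal template (heel-up positive); the normal
# ankle curve is derived as ankle = knee - hip - foot
_NORMAL_FOOT = [(0, -15), (5, -8), (10, 0), (15, 0), (20, 0), (25, 0),
                (30, 0), (35, 0), (40, 0), (45, 4), (52, 15), (60, 42),
                (67, 48), (75, 44), (83, 20), (90, -6), (95, -12), (100, -15)]

_PATTERN_OFFSETS = {
    "normal": {},
    "true_equinus": {
        "hip": [(0, -4), (50, -4), (100, -4)],
        "knee": [(0, -2), (15, -6), (40, -2), (60, 0), (75, -10), (85, -5), (100, -2)],
        "ankle": [(0, -24), (10, -18), (25, -15), (40, -16), (55, -12),
                  (60, -10), (70, -18), (85, -20), (100, -24)],
    },
    "jump": {
        "hip": [(0, 10), (30, 12), (55, 14), (80, 8), (100, 10)],
        "knee": [(0, 10), (20, 16), (45, 15), (60, 8), (80, 0), (100, 10)],
        "ankle": [(0, -22), (15, -16), (35, -14), (55, -12), (70, -15),
                  (85, -18), (100, -22)],
    },
    "apparent_equinus": {
        "hip": [(0, 8), (30, 10), (55, 12), (80, 6), (100, 8)],
        "knee": [(0, 24), (15, 22), (40, 20), (60, 12), (75, 2), (90, 14), (100, 24)],
        "ankle": [(0, -7), (20, -6), (45, -6), (60, -4), (80, -5), (100, -7)],
    },
    "crouch": {
        "hip": [(0, 22), (30, 25), (55, 28), (80, 20), (100, 22)],
        "knee": [(0, 28), (20, 30), (45, 32), (60, 25), (75, 12), (90, 20), (100, 28)],
        "ankle": [(0, 6), (25, 10), (45, 12), (60, 10), (75, 6), (100, 6)],
    },
    "short_hamstring": {
        "knee": [(0, 5), (10, 3), (30, 0), (60, 0), (80, 3), (88, 8), (100, 5)],
    },
    "hyperextension": {
        "hip": [(0, -6), (10, -3), (25, 0), (60, 0), (90, 0), (100, -6)],
        "knee": [(0, -2), (12, -5), (30, -14), (48, -11), (60, -8), (70, -3),
                 (80, 0), (90, 0), (100, -2)],
        "ankle": [(0, -11), (12, -2), (30, -14), (45, -7), (60, 4), (75, 0),
                  (90, -4), (100, -11)],
    },
}

PATTERN_NAMES = tuple(_PATTERN_OFFSETS)


@dataclass
class NoiseSpec:
    """Measurement-noise model for a simulated trial.

    ``jitter_sd``: i.i.d. Gaussian landmark jitter SD in metres per frame.
    ``dropout``: per-frame probability that a side's landmarks are missing.
    """

    jitter_sd: float = 0.005
    dropout: float = 0.0

    def __post_init__(self):
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout probability must be in [0, 1]")


@dataclass
class GaitPatternSpec:
    """One simulated walking condition.

    ``angle_offsets`` overrides the pattern's default additive offset curves;
    keys are joints (hip/knee/ankle), values keyframe lists or a scalar for a
    uniform shift.  ``curve_variability_sd`` adds a smooth random per-trial
    perturbation (degrees) emulating natural inter-trial kinematic
    variability; it depends only on ``seed``, not on the pattern.
    """

    pattern_name: str = "normal"
    cycle_duration: float = 1.1          # s; cadence ~109 steps/min
    step_length_target: float = 0.38     # m; with the cycle duration: 0.69 m/s
    stance_fraction: float = 0.60
    angle_offsets: dict | None = None
    curve_variability_sd: float = 2.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self):
        if self.pattern_name not in _PATTERN_OFFSETS:
            raise ValueError(
                f"unknown pattern {self.pattern_name!r}; valid patterns: "
                + ", ".join(PATTERN_NAMES))
        if self.cycle_duration <= 0:
            raise ValueError("cycle_duration must be > 0")
        if self.step_length_target <= 0:
            raise ValueError("step_length_target must be > 0")
        if not 0.1 < self.stance_fraction < 0.9:
            raise ValueError("stance_fraction must be in (0.1, 0.9)")
        if isinstance(self.noise, dict):
            self.noise = NoiseSpec(**self.noise)


def _periodic_spline(keys) -> CubicSpline:
    x = np.array([k[0] for k in keys], float)
    y = np.array([k[1] for k in keys], float)
    if x[0] != 0.0 or x[-1] != 100.0:
        raise ValueError("keyframes must span 0..100 %")
    if y[0] != y[-1]:
        raise ValueError("periodic keyframes need equal first/last values")
    return CubicSpline(x, y, bc_type="periodic")


def _zero_spline():
    return CubicSpline([0.0, 100.0], [0.0, 0.0], bc_type="periodic")


def _variability_spline(rng: np.random.Generator, sd: float) -> CubicSpline:
    """Smooth periodic perturbation with pointwise SD ~ ``sd`` degrees."""
    x = np.linspace(0.0, 100.0, 9)
    y = rng.normal(0.0, sd, 8)
    y = np.append(y, y[0])
    return CubicSpline(x, y, bc_type="periodic")


class JointCurveSet:
    """Callable joint-angle curves over one gait cycle (periodic in %)."""

    def __init__(self, splines: dict):
        self._s = splines  # hip/knee/ankle CubicSplines

    def __call__(self, joint: str, pct):
        pct = np.asarray(pct, float) % 100.0
        if joint == "foot":
            return (self._s["knee"](pct) - self._s["hip"](pct)
                    - self._s["ankle"](pct))
        return self._s[joint](pct)

    def sampled(self) -> dict:
        """The four curves sampled at 0–100 % in 1 % steps (101 points)."""
        return {j: np.asarray(self(j, CYCLE_GRID)) for j in
                ("hip", "knee", "ankle", "foot")}


def generate_joint_curves(pattern: GaitPatternSpec) -> JointCurveSet:
    """Hip/knee/ankle (and derived foot-orientation) curves for one cycle.

    The named pattern supplies default additive offsets; explicit
    ``angle_offsets`` in the spec replace them.  A seeded smooth perturbation
    of SD ``curve_variability_sd`` is added per joint, then the summed curve
    is re-smoothed through a periodic spline on the 1 % grid.
    """
    base = {j: _periodic_spline(_NORMAL_KEYS[j]) for j in ("hip", "knee")}
    foot = _periodic_spline(_NORMAL_FOOT)
    # normal ankle from the chain identity on the 1 % grid
    ankle_vals = base["knee"](CYCLE_GRID) - base["hip"](CYCLE_GRID) - foot(CYCLE_GRID)
    base["ankle"] = CubicSpline(CYCLE_GRID, ankle_vals, bc_type="periodic")

    offsets = _PATTERN_OFFSETS[pattern.pattern_name]
    if pattern.angle_offsets is not None:
        offsets = pattern.angle_offsets
    rng = np.random.default_rng(pattern.seed)
    wobble = {j: (_variability_spline(rng, pattern.curve_variability_sd)
                  if pattern.curve_variability_sd > 0 else _zero_spline())
              for j in ("hip", "knee", "ankle")}

    splines = {}
    for joint in ("hip", "knee", "ankle"):
        off = offsets.get(joint, 0.0)
        if np.isscalar(off):
            off_s = CubicSpline([0.0, 100.0], [off, off], bc_type="periodic")
        else:
            off_s = _periodic_spline(off)
        vals = (base[joint](CYCLE_GRID) + off_s(CYCLE_GRID)
                + wobble[joint](CYCLE_GRID))
        vals[-1] = vals[0]
        splines[joint] = CubicSpline(CYCLE_GRID, vals, bc_type="periodic")
    return JointCurveSet(splines)
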