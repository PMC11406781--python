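"""Per-side kinematic feature set and the normative reference band.

Features mirror the standard clinical report for sagittal gait curves:
hip maximum extension and range of motion; knee angle at initial contact,
loading-response peak (0–15 % of the cycle), peak extension in stance
(the minimum flexion between the loading-response peak and toe-off, which is
negative for a hyperextending knee), maximum in swing and range of motion;
ankle maximum dorsiflexion in stance and in swing; and the mean foot
orientation over 10–30 % of the cycle (the second-rocker window — positive
means the heel stays up, i.e. toe-walking).

The normative band is built from an ensemble of normal-pattern trials:
pointwise mean and sample SD of each 101-point curve, plus mean/SD of every
scalar feature.  Classification thresholds are "mean + 1 SD" against this
band, following the convention of reading clinical kinematics against a
1-SD laboratory normal corridor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinematics import ANGLE_NAMES, JointKinematics, N_CYCLE_SAMPLES

__all__ = ["GaitFeatures", "NormativeBand", "extract_features",
           "build_normative_band", "FEATURE_NAMES"]

FEATURE_NAMES = (
    "hip_max_extension", "hip_rom",
    "knee_at_ic", "knee_loading_response", "knee_peak_extension_in_stance",
    "knee_max_in_swing", "knee_rom",
    "ankle_max_dorsiflexion_stance", "ankle_max_dorsiflexion_swing",
    "foot_orientation_avg_10_30",
)


@dataclass
class GaitFeatures:
    """Scalar kinematic features for one side, averaged across cycles."""

    side: str
    values: dict
    gait_speed: float = np.nan
    step_length: float = np.nan
    n_cycles: int = 0

    def __getitem__(self, key):
        return self.values[key]


def _cycle_features(curves: dict, toe_off_pct: float) -> dict:
    hip = curves["hip"]
    knee = curves["knee"]
    ankle = curves["ankle"]
    foot = curves["foot"]
    to = int(round(np.clip(toe_off_pct, 1, 99)))
    lr_win = knee[0:16]                      # loading response: 0-15 %
    lr_peak_idx = int(np.argmax(lr_win))
    stance_after_lr = knee[lr_peak_idx:to + 1]
    return {
        "hip_max_extension": float(hip.min()),
        "hip_rom": float(hip.max() - hip.min()),
        "knee_at_ic": float(knee[0]),
        "knee_loading_response": float(lr_win.max()),
        "knee_peak_extension_in_stance": float(stance_after_lr.min()),
        "knee_max_in_swing": float(knee[to:].max()),
        "knee_rom": float(knee.max() - knee.min()),
        "ankle_max_dorsiflexion_stance": float(ankle[:to + 1].max()),
        "ankle_max_dorsiflexion_swing": float(ankle[to:].max()),
        "foot_orientation_avg_10_30": float(foot[10:31].mean()),
    }


def extract_features(kin: JointKinematics, spatiotemporal=None) -> GaitFeatures:
    """Features per cycle, averaged across the cycles of one side."""
    if not kin.cycles:
        raise ValueError("feature extraction needs at least one complete cycle")
    per_cycle = [_cycle_features(c["curves"], c["toe_off_pct"])
                 for c in kin.cycles]
    values = {k: float(np.mean([pc[k] for pc in per_cycle]))
              for k in FEATURE_NAMES}
    gs, sl = np.nan, np.nan
    if spatiotemporal is not None:
        gs = spatiotemporal.gait_speed
        sl = spatiotemporal.mean_step_length
    return GaitFeatures(side=kin.side, values=values, gait_speed=gs,
                        step_length=sl, n_cycles=len(per_cycle))


@dataclass
class NormativeBand:
    """Pointwise normal corridor plus feature statistics.

    ``curve_mean``/``curve_sd`` map angle name -> (101,) arrays;
    ``feature_mean``/``feature_sd`` map feature name -> scalar.  The default
    corridor half-width is 1 SD.
    """

    curve_mean: dict
    curve_sd: dict
    feature_mean: dict
    feature_sd: dict
    n_trials: int
    toe_off_pct: float = 60.0

    def upper(self, name: str, n_sd: float = 1.0) -> np.ndarray:
        return self.curve_mean[name] + n_sd * self.curve_sd[name]

    def lower(self, name: str, n_sd: float = 1.0) -> np.ndarray:
        return self.curve_mean[name] - n_sd * self.curve_sd[name]

    def feature_upper(self, name: str, n_sd: float = 1.0) -> float:
        return self.feature_mean[name] + n_sd * self.feature_sd[name]

    def feature_lower(self, name: str, n_sd: float = 1.0) -> float:
        return self.feature_mean[name] - n_sd * self.feature_sd[name]


def build_normative_band(ensemble) -> NormativeBand:
    """Pointwise mean/SD band from >= 5 normal-pattern JointKinematics.

    Each trial contributes its cycle-averaged curves and features, so the SD
    captures inter-trial variability rather than within-trial cycle noise.
    """
    ensemble = list(ensemble)
    if len(ensemble) < 5:
        raise ValueError("a normative band needs at least 5 trials")
    curves = {name: np.stack([k.mean_curves()[name] for k in ensemble])
              for name in ANGLE_NAMES}
    feats = [extract_features(k) for k in ensemble]
    fmat = {name: np.array([f[name] for f in feats]) for name in FEATURE_NAMES}
    return NormativeBand(
        curve_mean={n: c.mean(axis=0) for n, c in curves.items()},
        curve_sd={n: c.std(axis=0, ddof=1) for n, c in curves.items()},
        feature_mean={n: float(v.mean()) for n, v in fmat.items()},
        feature_sd={n: float(v.std(ddof=1)) for n, v in fmat.items()},
        n_trials=len(ensemble),
        toe_off_pct=float(np.mean([k.mean_toe_off_pct for k in ensemble])),
    )
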