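"""Rule-based sagittal gait-pattern classification (Rodda-type groups).

The classifier reproduces, with explicit numeric cutoffs, the expert reading
used for spastic bilateral gait: first the position of the foot (is the
child toe-walking?), then the ankle (plantarflexed throughout stance /
normal range / excessive dorsiflexion), then the knee and hip posture in
stance (extended vs increased flexion relative to a normal band):

* type I — true equinus: toe-walking, ankle plantarflexed throughout
  stance, knee and hip extended;
* type II — jump: toe-walking, ankle plantarflexed, knee and hip flexed;
* type III — apparent equinus: toe-walking with a normal ankle dorsiflexion
  range, toe contact driven by increased knee and hip flexion;
* type IV — crouch: excessive ankle dorsiflexion with excessive knee and
  hip flexion;
* otherwise — unclassified/mild deviation (curves essentially within the
  1-SD normal corridor, possibly with individual deviation flags).

Every comparison is recorded in an ordered rule trace for auditability.
The original classification is an expert judgement without published
numeric thresholds; all cutoffs here are configurable with documented
defaults (toe-walking when the mean 10–30 % foot orientation exceeds +10°
heel-up or the first rocker is absent; posture judged against the
mean + 1 SD of the normative band).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import GaitFeatures, NormativeBand
from .kinematics import JointKinematics

__all__ = ["RoddaResult", "ClassifierConfig", "classify_rodda",
           "deviation_flags", "RODDA_TYPES"]

RODDA_TYPES = ("I_true_equinus", "II_jump", "III_apparent_equinus",
               "IV_crouch", "unclassified_mild")

ALL_FLAGS = ("increased_knee_flexion_at_ic", "decreased_terminal_swing_extension",
             "knee_hyperextension_in_stance", "absent_first_rocker",
             "plantarflexion_knee_extension_couple")


@dataclass(frozen=True)
class ClassifierConfig:
    toe_walk_foot_threshold: float = 10.0   # deg heel-up, mean over 10-30 %
    heel_down_threshold: float = -2.0       # deg; first rocker needs foot below
    band_n_sd: float = 1.0                  # corridor half-width
    couple_ankle_bound: float = 5.0         # deg; max stance dorsiflexion for
                                            # the plantarflexion-extension couple


@dataclass
class RoddaResult:
    type: str
    rule_trace: list = field(default_factory=list)
    deviation_flags: set = field(default_factory=set)
    side: str = ""


def _trace(trace, criterion, observed, threshold, verdict):
    trace.append({"criterion": criterion, "observed": float(observed),
                  "threshold": float(threshold), "verdict": bool(verdict)})
    return bool(verdict)


def _first_rocker_absent(kin: JointKinematics, cfg: ClassifierConfig) -> float:
    """Minimum foot orientation over 0-10 % (mean across cycles)."""
    foot = np.mean([c["curves"]["foot"][:11] for c in kin.cycles], axis=0)
    return float(foot.min())


def deviation_flags(feat: GaitFeatures, kin: JointKinematics,
                    band: NormativeBand,
                    config: ClassifierConfig | None = None) -> set:
    """Mild-deviation flags for curves that escape the normal corridor."""
    cfg = config or ClassifierConfig()
    flags = set()
    if feat["knee_at_ic"] > band.feature_upper("knee_at_ic", cfg.band_n_sd):
        flags.add("increased_knee_flexion_at_ic")
    knee_ts = np.mean([c["curves"]["knee"][90:] for c in kin.cycles], axis=0)
    band_ts = band.upper("knee", cfg.band_n_sd)[90:]
    if knee_ts.min() > band_ts.min():
        flags.add("decreased_terminal_swing_extension")
    if feat["knee_peak_extension_in_stance"] < 0.0:
        flags.add("knee_hyperextension_in_stance")
    if _first_rocker_absent(kin, cfg) > cfg.heel_down_threshold:
        flags.add("absent_first_rocker")
    if ("knee_hyperextension_in_stance" in flags
            and feat["ankle_max_dorsiflexion_stance"] <= cfg.couple_ankle_bound):
        flags.add("plantarflexion_knee_extension_couple")
    return flags


def classify_rodda(feat: GaitFeatures, kin: JointKinematics,
                   band: NormativeBand,
                   config: ClassifierConfig | None = None) -> RoddaResult:
    """Ordered rule evaluation onto the four types or unclassified_mild."""
    if band is None:
        raise ValueError("classification requires a normative band")
    cfg = config or ClassifierConfig()
    trace = []

    foot_1030 = feat["foot_orientation_avg_10_30"]
    heel_up = _trace(trace, "toe_walking_foot_orientation", foot_1030,
                     cfg.toe_walk_foot_threshold,
                     foot_1030 > cfg.toe_walk_foot_threshold)
    fr_min = _first_rocker_absent(kin, cfg)
    no_first_rocker = _trace(trace, "absent_first_rocker", fr_min,
                             cfg.heel_down_threshold,
                             fr_min > cfg.heel_down_threshold)
    toe_walking = heel_up or no_first_rocker

    ankle_st = feat["ankle_max_dorsiflexion_stance"]
    plantar = _trace(trace, "ankle_plantarflexed_throughout_stance",
                     ankle_st, 0.0, ankle_st < 0.0)
    ankle_hi = band.feature_upper("ankle_max_dorsiflexion_stance", cfg.band_n_sd)
    excessive = _trace(trace, "ankle_excessive_dorsiflexion",
                       ankle_st, ankle_hi, ankle_st > ankle_hi)

    knee_hi = band.feature_upper("knee_peak_extension_in_stance", cfg.band_n_sd)
    knee_flexed = _trace(trace, "knee_increased_stance_flexion",
                         feat["knee_peak_extension_in_stance"], knee_hi,
                         feat["knee_peak_extension_in_stance"] > knee_hi)
    hip_hi = band.feature_upper("hip_max_extension", cfg.band_n_sd)
    hip_flexed = _trace(trace, "hip_increased_stance_flexion",
                        feat["hip_max_extension"], hip_hi,
                        feat["hip_max_extension"] > hip_hi)

    if toe_walking and plantar and not (knee_flexed or hip_flexed):
        verdict = "I_true_equinus"
    elif toe_walking and plantar:
        verdict = "II_jump"
    elif toe_walking and not excessive and knee_flexed and hip_flexed:
        verdict = "III_apparent_equinus"
    elif excessive and knee_flexed and hip_flexed:
        verdict = "IV_crouch"
    else:
        verdict = "unclassified_mild"

    flags = deviation_flags(feat, kin, band, cfg)
    return RoddaResult(type=verdict, rule_trace=trace,
                       deviation_flags=flags, side=feat.side)
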