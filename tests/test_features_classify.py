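"""Feature extraction, normative band and the Rodda-type classifier."""

import numpy as np
import pytest

from gait2d.analysis import analyze_trial
from gait2d.classify import ClassifierConfig, classify_rodda, deviation_flags
from gait2d.features import (FEATURE_NAMES, build_normative_band,
                             extract_features)
from gait2d.kinematics import JointKinematics
from gait2d.patterns import GaitPatternSpec, PATTERN_NAMES
from gait2d.walker import simulate_trial

EXPECTED_TYPE = {
    "normal": "unclassified_mild",
    "true_equinus": "I_true_equinus",
    "jump": "II_jump",
    "apparent_equinus": "III_apparent_equinus",
    "crouch": "IV_crouch",
    "short_hamstring": "unclassified_mild",
    "hyperextension": "unclassified_mild",
}


def _kin_from_curves(curves: dict, toe_off_pct=60.0, side="right"):
    return JointKinematics(side=side, timestamps=np.arange(101) / 30.0,
                           raw={}, cycles=[{"curves": curves,
                                            "cycle": (0, 60, 100),
                                            "toe_off_pct": toe_off_pct}])


def _flat(val):
    return np.full(101, float(val))


class TestExtractFeatures:
    def test_constant_knee_curve(self):
        curves = {"hip": _flat(0), "knee": _flat(10), "ankle": _flat(0),
                  "foot": _flat(0)}
        feat = extract_features(_kin_from_curves(curves))
        assert feat["knee_at_ic"] == pytest.approx(10.0)
        assert feat["knee_rom"] == pytest.approx(0.0)

    def test_normal_trial_knee_rom(self, clean_analyses):
        feat = extract_features(clean_analyses["normal"].kinematics["right"])
        assert 55.0 <= feat["knee_rom"] <= 65.0

    def test_hyperextension_trial_negative_stance_peak(self, clean_analyses):
        feat = extract_features(
            clean_analyses["hyperextension"].kinematics["right"])
        assert feat["knee_peak_extension_in_stance"] < 0.0

    def test_foot_window_uses_samples_10_to_30(self):
        foot = np.zeros(101)
        foot[10:31] = 12.0
        curves = {"hip": _flat(0), "knee": _flat(0), "ankle": _flat(0),
                  "foot": foot}
        feat = extract_features(_kin_from_curves(curves))
        assert feat["foot_orientation_avg_10_30"] == pytest.approx(12.0)

    def test_no_cycles_raises(self):
        kin = JointKinematics(side="right", timestamps=np.arange(5),
                              raw={}, cycles=[])
        with pytest.raises(ValueError):
            extract_features(kin)


class TestNormativeBand:
    def test_identical_trials_zero_sd(self, clean_analyses):
        kin = clean_analyses["normal"].kinematics["right"]
        band = build_normative_band([kin] * 5)
        assert np.allclose(band.curve_sd["knee"], 0.0)
        assert band.feature_sd["knee_rom"] == pytest.approx(0.0)

    def test_fewer_than_five_trials_rejected(self, clean_analyses):
        kin = clean_analyses["normal"].kinematics["right"]
        with pytest.raises(ValueError):
            build_normative_band([kin] * 4)

    def test_known_injected_sd_recovered(self):
        """An ensemble with 2 deg inter-trial SD recovers pointwise SD
        within 20%."""
        ens = []
        for i in range(24):
            spec = GaitPatternSpec(pattern_name="normal", seed=500 + i,
                                   curve_variability_sd=2.0)
            ana = analyze_trial(simulate_trial(spec, n_cycles=3, noisy=False))
            ens.append(ana.kinematics["right"])
        band = build_normative_band(ens)
        mid = band.curve_sd["hip"][20:80]
        assert abs(mid.mean() - 2.0) < 0.4

    def test_band_mean_tracks_template(self, normative_band, clean_trials):
        truth = clean_trials["normal"].true_curves["right"]["ankle"]
        # compare at midstance, away from contact-phase interpolation
        assert abs(normative_band.curve_mean["ankle"][40] - truth[40]) < 1.5


class TestClassifier:
    @pytest.mark.parametrize("pattern", PATTERN_NAMES)
    def test_each_template_classified_as_itself(self, pattern, clean_analyses,
                                                normative_band):
        ana = clean_analyses[pattern]
        kin = ana.kinematics["right"]
        feat = extract_features(kin, ana.spatiotemporal["right"])
        res = classify_rodda(feat, kin, normative_band)
        assert res.type == EXPECTED_TYPE[pattern]
        assert res.rule_trace, "rule trace must not be empty"

    def test_true_vs_apparent_equinus_distinction(self, clean_analyses,
                                                  normative_band):
        """The clinical differentiator: both toe-walk, but true equinus has
        stance plantarflexion with knee/hip extension, apparent equinus a
        normal ankle range with increased knee/hip flexion."""
        out = {}
        for pat in ("true_equinus", "apparent_equinus"):
            ana = clean_analyses[pat]
            kin = ana.kinematics["right"]
            feat = extract_features(kin)
            out[pat] = (feat, classify_rodda(feat, kin, normative_band))
        f_true, r_true = out["true_equinus"]
        f_app, r_app = out["apparent_equinus"]
        assert f_true["ankle_max_dorsiflexion_stance"] < 0
        assert f_app["ankle_max_dorsiflexion_stance"] >= 0
        assert f_app["knee_peak_extension_in_stance"] > \
            f_true["knee_peak_extension_in_stance"]
        assert r_true.type == "I_true_equinus"
        assert r_app.type == "III_apparent_equinus"

    def test_missing_band_raises(self, clean_analyses):
        kin = clean_analyses["normal"].kinematics["right"]
        feat = extract_features(kin)
        with pytest.raises(ValueError):
            classify_rodda(feat, kin, None)

    def test_determinism_and_total_coverage(self, clean_analyses,
                                            normative_band):
        from gait2d.classify import RODDA_TYPES

        for pat, ana in clean_analyses.items():
            kin = ana.kinematics["right"]
            feat = extract_features(kin)
            r1 = classify_rodda(feat, kin, normative_band)
            r2 = classify_rodda(feat, kin, normative_band)
            assert r1.type == r2.type
            assert r1.type in RODDA_TYPES

    def test_ankle_shift_monotone_verdict(self, clean_analyses,
                                          normative_band):
        """Uniformly dorsiflexing the ankle can only move the ankle verdict
        plantarflexed -> normal -> excessive, never backwards."""
        order = {"plantar": 0, "normal": 1, "excessive": 2}

        def verdict(shift):
            ana = clean_analyses["true_equinus"]
            kin = ana.kinematics["right"]
            feat = extract_features(kin)
            feat.values = dict(feat.values)
            feat.values["ankle_max_dorsiflexion_stance"] += shift
            res = classify_rodda(feat, kin, normative_band)
            tr = {t["criterion"]: t["verdict"] for t in res.rule_trace}
            if tr["ankle_plantarflexed_throughout_stance"]:
                return order["plantar"]
            return order["excessive" if tr["ankle_excessive_dorsiflexion"]
                         else "normal"]

        verdicts = [verdict(s) for s in np.linspace(0, 40, 17)]
        assert all(b >= a for a, b in zip(verdicts, verdicts[1:]))


class TestDeviationFlags:
    def test_short_hamstring_signature(self, clean_analyses, normative_band):
        """Increased knee flexion at IC plus decreased terminal-swing
        extension, with the first rocker still present."""
        ana = clean_analyses["short_hamstring"]
        kin = ana.kinematics["right"]
        flags = deviation_flags(extract_features(kin), kin, normative_band)
        assert "increased_knee_flexion_at_ic" in flags
        assert "decreased_terminal_swing_extension" in flags
        assert "absent_first_rocker" not in flags

    def test_hyperextension_couple(self, clean_analyses, normative_band):
        ana = clean_analyses["hyperextension"]
        kin = ana.kinematics["right"]
        flags = deviation_flags(extract_features(kin), kin, normative_band)
        assert "plantarflexion_knee_extension_couple" in flags
        assert "knee_hyperextension_in_stance" in flags
        assert "absent_first_rocker" in flags

    def test_normal_trial_empty_flags(self, clean_analyses, normative_band):
        ana = clean_analyses["normal"]
        kin = ana.kinematics["right"]
        flags = deviation_flags(extract_features(kin), kin, normative_band)
        assert flags == set()
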