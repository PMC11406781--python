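"""Angle conventions, the independent trigonometric oracle, and cycle
normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gait2d.kinematics import (ankle_dorsiflexion, compute_joint_angles,
                               foot_orientation, hip_flexion, knee_flexion,
                               normalize_cycles)


def _angle_of(v):
    """Independent oracle: direction angle of a 2D vector, degrees."""
    return np.degrees(np.arctan2(v[1], v[0]))


def _signed_between(a, b):
    """Independent oracle: signed angle from vector a to vector b in
    (-180, 180], degrees (counter-clockwise positive)."""
    d = _angle_of(b) - _angle_of(a)
    return (d + 180.0) % 360.0 - 180.0


class TestAngleExamples:
    @pytest.mark.parametrize("troch, epi, expected", [
        ((0, 1.00), (0, 0.60), 0.0),                  # vertical femur
        ((0, 1.00), (0.20, 0.60), 26.565051),         # arctan(0.2/0.4)
        ((0, 1.00), (-0.10, 0.60), -14.036243),       # extension is negative
    ])
    def test_hip_flexion(self, troch, epi, expected):
        assert hip_flexion(troch, epi) == pytest.approx(expected, abs=1e-5)

    def test_knee_collinear_is_zero(self):
        assert knee_flexion((0, 1.0), (0, 0.6), (0, 0.2)) == pytest.approx(0.0)

    def test_knee_flexion_example(self):
        # femur vertical, malleolus 0.15 m behind and 0.35 m below the knee
        val = knee_flexion((0, 1.0), (0, 0.6), (-0.15, 0.25))
        assert val == pytest.approx(23.198591, abs=1e-5)

    def test_knee_hyperextension_is_negative(self):
        assert knee_flexion((0, 1.0), (0, 0.6), (0.10, 0.22)) < 0

    def test_ankle_neutral(self):
        # tibia vertical, foot horizontal
        val = ankle_dorsiflexion((0, 0.6), (0, 0.2), (-0.05, 0.05), (0.15, 0.05))
        assert val == pytest.approx(0.0, abs=1e-9)

    def test_ankle_plantarflexion_by_rotation(self):
        # toe lowered 10 degrees below horizontal under a vertical tibia
        heel = np.array([0.0, 0.10])
        toe = heel + 0.2 * np.array([np.cos(np.radians(-10)),
                                     np.sin(np.radians(-10))])
        val = ankle_dorsiflexion((0, 0.7), (0, 0.3), heel, toe)
        assert val == pytest.approx(-10.0, abs=1e-9)

    @pytest.mark.parametrize("heel, toe, expected", [
        ((0, 0.05), (0.15, 0.05), 0.0),
        ((0, 0.10), (0.15, 0.05), 18.434949),
        ((0, 0.02), (0.15, 0.08), -21.801409),        # heel below toe
    ])
    def test_foot_orientation(self, heel, toe, expected):
        assert foot_orientation(heel, toe) == pytest.approx(expected, abs=1e-5)

    def test_degenerate_points_raise(self):
        with pytest.raises(ValueError):
            hip_flexion((0.1, 0.2), (0.1, 0.2))
        with pytest.raises(ValueError):
            foot_orientation((0.1, 0.2), (0.1, 0.2))
        with pytest.raises(ValueError):
            knee_flexion((0, 1.0), (0, 1.0), (0, 0.2))


@settings(derandomize=True, max_examples=250)
@given(st.lists(st.floats(-1.0, 1.0), min_size=10, max_size=10),
       st.floats(-80, 80), st.floats(-20, 140), st.floats(-60, 60))
def test_angles_agree_with_trig_oracle(coords, hip_true, knee_true, ankle_true):
    """All four angle operations match an independent arctangent oracle to
    1e-6 degrees on random non-degenerate configurations."""
    troch = np.array(coords[:2])
    L1, L2, L3 = 0.3 + 0.2 * abs(coords[2]), 0.3, 0.2
    hr, tr_ = np.radians(hip_true), np.radians(hip_true - knee_true)
    epi = troch + L1 * np.array([np.sin(hr), -np.cos(hr)])
    mall = epi + L2 * np.array([np.sin(tr_), -np.cos(tr_)])
    theta_f = tr_ + np.radians(ankle_true)
    heel = mall - 0.05 * np.array([np.cos(theta_f), np.sin(theta_f)])
    toe = heel + L3 * np.array([np.cos(theta_f), np.sin(theta_f)])

    femur, tibia, foot = epi - troch, mall - epi, toe - heel
    hip_oracle = _signed_between(np.array([0.0, -1.0]), femur)
    knee_oracle = _signed_between(tibia, femur)
    foot_oracle = -_angle_of(foot)
    perp = np.array([-tibia[1], tibia[0]])
    ankle_oracle = _signed_between(perp, foot)

    assert hip_flexion(troch, epi) == pytest.approx(hip_oracle, abs=1e-6)
    assert knee_flexion(troch, epi, mall) == pytest.approx(knee_oracle, abs=1e-6)
    assert ankle_dorsiflexion(epi, mall, heel, toe) == pytest.approx(
        ankle_oracle, abs=1e-6)
    assert foot_orientation(heel, toe) == pytest.approx(foot_oracle, abs=1e-6)


@settings(derandomize=True, max_examples=60)
@given(st.floats(-3, 3), st.floats(-3, 3), st.floats(-170, 170))
def test_rigid_motion_invariance(dx, dy, rot):
    """Translation changes no angle; rotation changes only the
    room-referenced angles (hip, foot), not the segment-relative ones."""
    pts = {"troch": np.array([0.1, 0.95]), "epi": np.array([0.18, 0.62]),
           "mall": np.array([0.12, 0.30]), "heel": np.array([0.05, 0.05]),
           "toe": np.array([0.26, 0.04])}
    knee0 = knee_flexion(pts["troch"], pts["epi"], pts["mall"])
    ankle0 = ankle_dorsiflexion(pts["epi"], pts["mall"], pts["heel"], pts["toe"])
    hip0 = hip_flexion(pts["troch"], pts["epi"])
    foot0 = foot_orientation(pts["heel"], pts["toe"])

    shift = {k: v + np.array([dx, dy]) for k, v in pts.items()}
    assert hip_flexion(shift["troch"], shift["epi"]) == pytest.approx(hip0, abs=1e-9)
    assert foot_orientation(shift["heel"], shift["toe"]) == pytest.approx(foot0, abs=1e-9)
    assert knee_flexion(shift["troch"], shift["epi"], shift["mall"]) == \
        pytest.approx(knee0, abs=1e-9)

    c, s = np.cos(np.radians(rot)), np.sin(np.radians(rot))
    R = np.array([[c, -s], [s, c]])
    rotp = {k: R @ v for k, v in pts.items()}
    assert knee_flexion(rotp["troch"], rotp["epi"], rotp["mall"]) == \
        pytest.approx(knee0, abs=1e-7)
    assert ankle_dorsiflexion(rotp["epi"], rotp["mall"], rotp["heel"],
                              rotp["toe"]) == pytest.approx(ankle0, abs=1e-7)
    if abs(rot) > 0.01:
        assert abs(hip_flexion(rotp["troch"], rotp["epi"]) - hip0) > 1e-6


class TestNormalizeCycles:
    def test_constant_signal(self):
        raw = {"knee": np.full(120, 10.0)}
        cycles = normalize_cycles(raw, [(10, 28, 40)])
        assert np.allclose(cycles[0]["curves"]["knee"], 10.0)
        assert cycles[0]["toe_off_pct"] == pytest.approx(60.0)

    def test_identity_on_101_frame_cycle(self):
        raw = {"hip": np.arange(120.0)}
        cycles = normalize_cycles(raw, [(5, 65, 105)])
        assert np.allclose(cycles[0]["curves"]["hip"], np.arange(5.0, 106.0))

    def test_zero_percent_equals_ic_value(self):
        rng = np.random.default_rng(0)
        raw = {"hip": rng.normal(size=90)}
        cycles = normalize_cycles(raw, [(7, 25, 40)])
        assert cycles[0]["curves"]["hip"][0] == pytest.approx(raw["hip"][7])

    def test_no_cycles_raises(self):
        with pytest.raises(ValueError):
            normalize_cycles({"hip": np.zeros(50)}, [])

    def test_cycles_with_missing_frames_dropped(self):
        raw = {"hip": np.ones(120)}
        raw["hip"][30] = np.nan
        cycles = normalize_cycles(raw, [(10, 28, 45), (45, 63, 80)])
        assert len(cycles) == 1
        assert cycles[0]["cycle"] == (45, 63, 80)

    def test_simulator_closure_on_template(self, clean_analyses, clean_trials):
        """Normalized knee curves of a simulated trial match the input
        template within 1 degree RMSE, once the template is evaluated at the
        actual phases of the detected cycle's frame grid (a cycle can only
        start on a frame, not at the exact contact instant)."""
        from gait2d.patterns import generate_joint_curves

        ana = clean_analyses["normal"]
        tr = clean_trials["normal"]
        curves = generate_joint_curves(tr.pattern)
        T, fps = tr.pattern.cycle_duration, tr.fps
        for cyc in ana.kinematics["right"].cycles:
            ic, _, nxt = cyc["cycle"]
            phase0 = (ic / fps / T - 0.4) % 1.0 * 100.0
            grid = phase0 + np.linspace(0.0, (nxt - ic) / fps / T * 100.0, 101)
            expected = curves("knee", grid)
            rmse = np.sqrt(np.mean((cyc["curves"]["knee"] - expected) ** 2))
            assert rmse < 1.0

    def test_resampling_preserves_extrema(self):
        x = np.sin(np.linspace(0, 2 * np.pi, 150)) * 30
        cycles = normalize_cycles({"a": x}, [(0, 80, 149)])
        resampled = cycles[0]["curves"]["a"]
        assert abs(resampled.max() - x.max()) < 0.1
        assert abs(resampled.min() - x.min()) < 0.1


def test_compute_joint_angles_closure(clean_trials):
    """Angles recomputed from forward-kinematics landmarks reproduce the
    generating curves to < 0.5 degrees for every pattern template."""
    from gait2d.patterns import generate_joint_curves, GaitPatternSpec, NoiseSpec

    for pat, tr in clean_trials.items():
        curves = generate_joint_curves(tr.pattern)
        phase = (tr.timestamps / tr.pattern.cycle_duration - 0.4) % 1.0 * 100
        ang = compute_joint_angles(tr.sides["right"])
        for j in ("hip", "knee", "ankle", "foot"):
            err = np.nanmax(np.abs(ang[j] - curves(j, phase)))
            assert err < 0.5, (pat, j, err)
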