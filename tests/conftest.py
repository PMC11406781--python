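import numpy as np
import pytest

from gait2d.analysis import analyze_trial
from gait2d.features import build_normative_band
from gait2d.patterns import PATTERN_NAMES, GaitPatternSpec, NoiseSpec
from gait2d.walker import simulate_trial


@pytest.fixture(scope="session")
def clean_trials():
    """Noise-free, variability-free trial per pattern template (3 cycles)."""
    out = {}
    for pat in PATTERN_NAMES:
        spec = GaitPatternSpec(pattern_name=pat, curve_variability_sd=0.0,
                               noise=NoiseSpec(0.0, 0.0))
        out[pat] = simulate_trial(spec, n_cycles=3, noisy=False)
    return out


@pytest.fixture(scope="session")
def clean_analyses(clean_trials):
    return {pat: analyze_trial(tr) for pat, tr in clean_trials.items()}


@pytest.fixture(scope="session")
def normative_band():
    """Band from 10 normal trials with default noise and variability."""
    ens = []
    for i in range(10):
        spec = GaitPatternSpec(pattern_name="normal", seed=100 + i)
        ana = analyze_trial(simulate_trial(spec, n_cycles=3))
        ens.append(ana.kinematics["right"])
    return build_normative_band(ens)


@pytest.fixture(scope="session")
def rendered_trial():
    """One rendered noisy normal trial with its source trajectories."""
    from gait2d.scene import render_frames
    from gait2d.tracking import track_sequence
    from gait2d.walker import add_noise, forward_kinematics
    from gait2d.anthropometry import Anthropometry
    from gait2d.patterns import generate_joint_curves

    spec = GaitPatternSpec(pattern_name="normal", seed=1)
    anthro = Anthropometry()
    clean = forward_kinematics(generate_joint_curves(spec), anthro, spec,
                               n_cycles=2)
    noisy = add_noise(clean)
    frames = render_frames(noisy)
    tracked = track_sequence(frames)
    return {"spec": spec, "clean": clean, "noisy": noisy, "frames": frames,
            "tracked": tracked}
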