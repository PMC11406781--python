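"""From landmark trajectories to joint kinematics and gait parameters.

Analyzes a noisy simulated trial: smooths the trajectories, detects initial
contacts (zero-velocity rule on heel/toe) and toe-offs, normalizes the
sagittal angle curves to 0-100% of the gait cycle and prints the standard
per-side summary a gait report would contain.
"""

import numpy as np

from gait2d import GaitPatternSpec, analyze_trial, extract_features, simulate_trial

spec = GaitPatternSpec(pattern_name="true_equinus", seed=11)
trial = simulate_trial(spec, n_cycles=3)
ana = analyze_trial(trial)

for side in ("right", "left"):
    kin = ana.kinematics[side]
    st = ana.spatiotemporal[side]
    feat = extract_features(kin, st)
    print(f"--- {side} ({kin.n_cycles} complete cycles, "
          f"toe-off at {kin.mean_toe_off_pct:.1f}% of cycle)")
    print(f"  gait speed {st.gait_speed:.3f} m/s, "
          f"mean step length {st.mean_step_length:.3f} m")
    print(f"  knee ROM {feat['knee_rom']:.1f} deg, "
          f"ankle max dorsiflexion in stance "
          f"{feat['ankle_max_dorsiflexion_stance']:.1f} deg "
          f"(negative = plantarflexed throughout: toe-walking)")
    print(f"  foot orientation 10-30% of cycle "
          f"{feat['foot_orientation_avg_10_30']:.1f} deg (heel-up positive)")
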