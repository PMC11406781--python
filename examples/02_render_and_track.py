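"""Render a walker to RGB frames and recover the landmarks by color.

Renders a noisy normal-gait trial in front of the green screen (red sock on
the right foot, blue on the left, pen marks on the foreground leg), runs the
color-filter tracker, and prints how far the tracked landmarks are from the
rendered ground truth.  Sub-centimetre medians mean the segmentation and
sub-pixel refinement recover the scene geometry at 130 px/m.
"""

import numpy as np

from gait2d import GaitPatternSpec, render_frames, simulate_trial, track_sequence

spec = GaitPatternSpec(pattern_name="normal", seed=3)
trial = simulate_trial(spec, n_cycles=2)          # default 5 mm landmark jitter
frames = render_frames(trial)
tracked = track_sequence(frames)

print(f"rendered {frames.n_frames} frames "
      f"({frames.scene.width}x{frames.scene.height}, "
      f"{frames.scene.pixels_per_meter:.0f} px/m)")
print(f"valid-feet fraction: {tracked.quality['valid_feet_fraction']:.0%}")
for name in ("heel", "toe", "lateral_malleolus", "lateral_epicondyle",
             "greater_trochanter"):
    err = np.hypot(*(tracked.sides["right"][name]
                     - trial.sides["right"][name]).T)
    print(f"  {name:20s} median position error {np.nanmedian(err) * 1000:5.1f} mm")
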