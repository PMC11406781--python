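"""Batch accuracy evaluations of the full pipeline on synthetic trials.

Two standing evaluations mirror the validation figures usually reported for
single-camera markerless gait systems:

* ``kinematic_accuracy_batch`` — render a batch of mixed-pattern trials with
  default landmark noise, run segmentation → tracking → kinematics, and
  report per-joint RMSE between the estimated and ground-truth normalized
  curves.  Both curves are normalized on the same (ground-truth) event
  frames, so the figure isolates measurement error, the quantity a
  concurrent 3D-system validation reports; event-detection accuracy is
  assessed separately.
* ``spatiotemporal_accuracy_batch`` — simulate a batch of noisy trials
  (trajectory level), detect initial contacts automatically, and compare
  gait speed and step length against the same quantities computed from the
  simulator's true contact frames.

All randomness derives from the ``seed`` argument.
"""

from __future__ import annotations

import numpy as np

from .analysis import analyze_trial
from .anthropometry import Anthropometry
from .events import GaitEvents
from .kinematics import compute_joint_angles, normalize_cycles
from .patterns import PATTERN_NAMES, GaitPatternSpec
from .scene import SceneConfig, render_frames
from .spatiotemporal import gait_speed, manual_reference_compare, step_length
from .tracking import track_sequence
from .walker import add_noise, forward_kinematics, simulate_trial
from .patterns import generate_joint_curves

__all__ = ["kinematic_accuracy_batch", "spatiotemporal_accuracy_batch",
           "MIXED_PATTERNS"]

# mixed-pattern rotation used for accuracy batches
MIXED_PATTERNS = ("normal", "true_equinus", "jump", "apparent_equinus",
                  "crouch", "short_hamstring", "hyperextension")


def _truth_events(traj) -> GaitEvents:
    return GaitEvents(ic={s: list(traj.true_events[s]["ic"]) for s in traj.sides},
                      to={s: list(traj.true_events[s]["to"]) for s in traj.sides})


def _normalized_truth(clean_traj, side: str) -> dict:
    """Ground-truth normalized curves of a trial on its real frame grid."""
    raw = compute_joint_angles(clean_traj.sides[side])
    ev = _truth_events(clean_traj)
    cycles = normalize_cycles(raw, ev, side=side)
    return {j: np.mean([c["curves"][j] for c in cycles], axis=0)
            for j in ("hip", "knee", "ankle", "foot")}


def kinematic_accuracy_batch(n_trials: int = 20, seed: int = 1,
                             n_cycles: int = 2,
                             scene: SceneConfig | None = None) -> dict:
    """Average per-joint RMSE (degrees) of the video pipeline vs ground truth.

    Each trial: one of the seven gait patterns in rotation, default landmark
    noise, rendered to frames and pushed through segmentation → tracking →
    kinematics on the foreground side.
    """
    anthro = Anthropometry()
    per_joint = {j: [] for j in ("hip", "knee", "ankle", "foot")}
    for i in range(n_trials):
        pattern = MIXED_PATTERNS[i % len(MIXED_PATTERNS)]
        spec = GaitPatternSpec(pattern_name=pattern, seed=seed * 1000 + i)
        curves = generate_joint_curves(spec)
        clean = forward_kinematics(curves, anthro, spec, n_cycles=n_cycles)
        noisy = add_noise(clean)
        frames = render_frames(noisy, scene)
        tracked = track_sequence(frames)
        ana = analyze_trial(tracked, events=_truth_events(clean))
        side = clean.foreground_side
        est = ana.kinematics[side].mean_curves()
        truth = _normalized_truth(clean, side)
        for j in per_joint:
            per_joint[j].append(
                float(np.sqrt(np.mean((est[j] - truth[j]) ** 2))))
    return {f"{j}_rmse_deg": float(np.mean(v)) for j, v in per_joint.items()} | {
        "n_trials": n_trials, "per_trial": per_joint}


def spatiotemporal_accuracy_batch(n_trials: int = 40, seed: int = 1,
                                  n_cycles: int = 3) -> dict:
    """Mean absolute error of automatic vs truth-event speed and step length."""
    auto, ref = [], []
    for i in range(n_trials):
        pattern = MIXED_PATTERNS[i % len(MIXED_PATTERNS)]
        spec = GaitPatternSpec(pattern_name=pattern, seed=seed * 1000 + i)
        traj = simulate_trial(spec, n_cycles=n_cycles, noisy=True)
        ana = analyze_trial(traj)                       # automatic events
        ref_ana = analyze_trial(traj, events=_truth_events(traj))
        side = traj.foreground_side
        for res, out in ((ana, auto), (ref_ana, ref)):
            st = res.spatiotemporal[side]
            out.append((st.gait_speed, st.mean_step_length))
    stats = manual_reference_compare(auto, ref)
    return stats
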