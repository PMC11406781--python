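"""Forward kinematics of the synthetic walker: angle curves -> landmark paths.

The walker advances left-to-right along a walkway at 30 frames/s.  Each side
follows the same joint-angle curves half a cycle out of phase.  During stance
the foot is anchored to the ground: the heel is the pivot while the foot is
heel-down or flat (first and second rockers) and the toe becomes the pivot
once the heel rises (third rocker); toe-walking patterns anchor the toe from
initial contact.  The pelvis (trochanter) trajectory during stance follows
from the anchored chain; swing-phase trochanter motion is filled with a
quintic segment matching position, velocity and acceleration of the
surrounding stance arcs, so every landmark decelerates smoothly into each
initial contact, as in real gait, instead of stopping abruptly.

By construction, recomputing the joint angles from the generated landmarks
returns the input curves exactly (closure), and the anchored foot point has
exactly zero velocity during its contact interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BPoly

from .anthropometry import Anthropometry
from .patterns import GaitPatternSpec, JointCurveSet, generate_joint_curves

__all__ = ["WalkerTrajectory", "forward_kinematics", "add_noise",
           "simulate_trial", "LANDMARKS", "SIDES", "FPS"]

FPS = 30.0
LANDMARKS = ("greater_trochanter", "lateral_epicondyle", "lateral_malleolus",
             "heel", "toe")
SIDES = ("right", "left")
WALKWAY_LENGTH = 7.0  # m
_SWITCH_EPS = 0.5     # deg of heel-up at which the pivot moves to the toe


@dataclass
class WalkerTrajectory:
    """Per-frame 2D metric landmark positions plus ground truth.

    ``sides`` maps side -> {landmark: (n, 2) float array, NaN = missing};
    ``missing`` maps side -> (n,) bool; ``true_events`` maps side ->
    {"ic": [...], "to": [...]} integer frame indices; ``true_curves`` maps
    side -> the 101-point input joint-angle curves of this trial.
    """

    timestamps: np.ndarray
    sides: dict
    true_events: dict
    true_curves: dict
    pattern: GaitPatternSpec
    anthro: Anthropometry
    fps: float = FPS
    foreground_side: str = "right"
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.timestamps)

    @property
    def background_side(self) -> str:
        return "left" if self.foreground_side == "right" else "right"

    def landmark(self, side: str, name: str) -> np.ndarray:
        return self.sides[side][name]

    def copy(self) -> "WalkerTrajectory":
        return WalkerTrajectory(
            timestamps=self.timestamps.copy(),
            sides={s: {k: v.copy() for k, v in lm.items()}
                   for s, lm in self.sides.items()},
            true_events={s: {k: list(v) for k, v in ev.items()}
                         for s, ev in self.true_events.items()},
            true_curves={s: {k: v.copy() for k, v in cv.items()}
                         for s, cv in self.true_curves.items()},
            pattern=self.pattern, anthro=self.anthro, fps=self.fps,
            foreground_side=self.foreground_side, meta=dict(self.meta),
        )

    @property
    def missing(self) -> dict:
        return {s: np.isnan(self.sides[s]["heel"][:, 0]) for s in self.sides}


def _chain_from_angles(h, k, a, anthro):
    """Unit geometry of the leg for given hip/knee/ankle angles (degrees).

    Returns direction data needed to build the chain from any anchored point:
    femur and tibia downward unit vectors, foot axis and its normal.
    """
    hr = np.radians(h)
    t_incl = np.radians(h - k)
    theta_f = np.radians(-(k - h - a))  # foot axis angle; -foot_orientation
    femur_down = np.stack([np.sin(hr), -np.cos(hr)], axis=-1)
    tibia_down = np.stack([np.sin(t_incl), -np.cos(t_incl)], axis=-1)
    u_f = np.stack([np.cos(theta_f), np.sin(theta_f)], axis=-1)
    n_f = np.stack([-np.sin(theta_f), np.cos(theta_f)], axis=-1)
    return femur_down, tibia_down, u_f, n_f


def _leg_from_trochanter(T, h, k, a, anthro):
    femur_down, tibia_down, u_f, n_f = _chain_from_angles(h, k, a, anthro)
    E = T + anthro.thigh_length * femur_down
    M = E + anthro.shank_length * tibia_down
    heel = M - anthro.heel_offset * u_f - anthro.ankle_height * n_f
    toe = heel + anthro.foot_length * u_f
    return E, M, heel, toe


def _trochanter_from_anchor(anchor, anchor_is_toe, h, k, a, anthro):
    femur_down, tibia_down, u_f, n_f = _chain_from_angles(h, k, a, anthro)
    if anchor_is_toe:
        heel = anchor - anthro.foot_length * u_f
    else:
        heel = anchor
    toe = heel + anthro.foot_length * u_f
    M = heel + anthro.heel_offset * u_f + anthro.ankle_height * n_f
    E = M - anthro.shank_length * tibia_down
    T = E - anthro.thigh_length * femur_down
    return T, E, M, heel, toe


def forward_kinematics(curves: JointCurveSet, anthro: Anthropometry,
                       pattern: GaitPatternSpec, n_cycles: int = 3,
                       foreground_side: str = "right",
                       start_x: float = 0.6) -> WalkerTrajectory:
    """Generate a ground-truthed landmark trajectory for one walkway pass.

    ``n_cycles`` is the number of complete gait cycles per side.  If the pass
    would leave the 7 m walkway the cycle count is truncated with a warning.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    T = pattern.cycle_duration
    sl = pattern.step_length_target
    sf = pattern.stance_fraction
    stride = 2.0 * sl

    needed = start_x + stride * (n_cycles + 1.5) + anthro.foot_length
    if needed > WALKWAY_LENGTH:
        max_cycles = max(1, int((WALKWAY_LENGTH - start_x - anthro.foot_length)
                                / stride - 1.5))
        warnings.warn(
            f"requested {n_cycles} cycles exceed the {WALKWAY_LENGTH} m "
            f"walkway; truncating to {max_cycles} cycles")
        n_cycles = max_cycles

    # lead-in/lead-out margin: the first IC happens 0.4 cycles into the
    # trial and the last one has at least 0.4 cycles of frames after it, so
    # boundary events are as detectable as interior ones
    n_frames = int(np.ceil((n_cycles + 1.3) * T * FPS))
    pad = int(np.ceil(T * FPS)) + 2
    ext_frames = np.arange(-pad, n_frames + pad)
    t_ext = ext_frames / FPS

    phase_offset = {foreground_side: 0.4,
                    ("left" if foreground_side == "right" else "right"): 0.9}

    # Pivot handover within stance: the heel is the pivot until the heel
    # rises for good (last upward crossing of the heel-up threshold), which
    # skips transient spline overshoot at the end of the first rocker.
    pct_fine = np.linspace(0.0, sf * 100.0, 481)
    foot_fine = curves("foot", pct_fine)
    above = foot_fine > _SWITCH_EPS
    if above[0]:
        switch_frac = 0.0                      # toe contact from IC
    elif above.any():
        upcross = np.flatnonzero(~above[:-1] & above[1:]) + 1
        switch_frac = pct_fine[upcross[-1]] / 100.0
    else:
        switch_frac = sf                       # heel pivot for all of stance

    sides_data = {}
    true_events = {}
    n_ext = len(ext_frames)
    for side, phi in phase_offset.items():
        u = t_ext / T - phi
        cyc = np.floor(u).astype(int)
        phase = u - cyc
        h = curves("hip", phase * 100.0)
        k = curves("knee", phase * 100.0)
        a = curves("ankle", phase * 100.0)

        in_stance = phase < sf
        toe_pivot = in_stance & (phase >= switch_frac)
        heel_pivot = in_stance & ~toe_pivot

        troch = np.full((n_ext, 2), np.nan)
        E = np.full((n_ext, 2), np.nan)
        M = np.full((n_ext, 2), np.nan)
        heel = np.full((n_ext, 2), np.nan)
        toe = np.full((n_ext, 2), np.nan)

        # ground-contact grid: heel-at-IC position advances one stride/cycle
        heel_ic_x = start_x + stride * (cyc + phi)
        theta0 = np.radians(-float(curves("foot", 0.0)))
        u_f0 = np.array([np.cos(theta0), np.sin(theta0)])

        if switch_frac == 0.0:
            toe_anchor_x = heel_ic_x + anthro.foot_length * u_f0[0]
            anchors_toe = np.stack([toe_anchor_x, np.zeros(n_ext)], axis=-1)
        else:
            anchors_heel = np.stack([heel_ic_x, np.zeros(n_ext)], axis=-1)

        if heel_pivot.any():
            idx = heel_pivot
            Tt, Ee, Mm, hh, tt = _trochanter_from_anchor(
                anchors_heel[idx], False, h[idx], k[idx], a[idx], anthro)
            troch[idx], E[idx], M[idx], heel[idx], toe[idx] = Tt, Ee, Mm, hh, tt

        if toe_pivot.any():
            if switch_frac > 0.0:
                # toe pivot point = toe position at the handover instant,
                # computed from the heel-anchored chain (C0 continuity)
                ph_s = switch_frac * 100.0
                _, _, u_fs, _ = _chain_from_angles(
                    curves("hip", ph_s), curves("knee", ph_s),
                    curves("ankle", ph_s), anthro)
                toe_anchor = (np.stack([heel_ic_x, np.zeros(n_ext)], axis=-1)
                              + anthro.foot_length * u_fs)
            else:
                toe_anchor = anchors_toe
            idx = toe_pivot
            Tt, Ee, Mm, hh, tt = _trochanter_from_anchor(
                toe_anchor[idx], True, h[idx], k[idx], a[idx], anthro)
            troch[idx], E[idx], M[idx], heel[idx], toe[idx] = Tt, Ee, Mm, hh, tt

        # Swing fill: quintic interpolation of the trochanter between stance
        # arcs, matching position, velocity and acceleration at both
        # boundaries.  Because every landmark equals the trochanter plus a
        # smooth angle-driven offset, this makes the landing foot decelerate
        # into contact over the natural terminal-swing timescale (its
        # velocity and acceleration both reach zero at the contact frame),
        # as a velocity-threshold event detector requires.
        stance_idx = np.flatnonzero(in_stance)
        gaps = np.flatnonzero(np.diff(stance_idx) > 1)
        dt = 1.0 / FPS
        for g in gaps:
            i0, i1 = stance_idx[g], stance_idx[g + 1]
            if i0 - 2 < 0 or i1 + 2 >= n_ext:
                continue
            sw = np.arange(i0 + 1, i1)
            for dim in range(2):
                p0, p1 = troch[i0, dim], troch[i1, dim]
                v0 = (troch[i0, dim] - troch[i0 - 1, dim]) / dt
                a0 = (troch[i0, dim] - 2 * troch[i0 - 1, dim]
                      + troch[i0 - 2, dim]) / dt ** 2
                v1 = (troch[i1 + 1, dim] - troch[i1, dim]) / dt
                a1 = (troch[i1 + 2, dim] - 2 * troch[i1 + 1, dim]
                      + troch[i1, dim]) / dt ** 2
                spl = BPoly.from_derivatives(
                    [t_ext[i0], t_ext[i1]],
                    [[p0, v0, a0], [p1, v1, a1]])
                troch[sw, dim] = spl(t_ext[sw])
        swing = ~in_stance
        if swing.any():
            idx = swing & np.isfinite(troch[:, 0])
            Ee, Mm, hh, tt = _leg_from_trochanter(
                troch[idx], h[idx], k[idx], a[idx], anthro)
            E[idx], M[idx], heel[idx], toe[idx] = Ee, Mm, hh, tt

        keep = slice(pad, pad + n_frames)
        sides_data[side] = {
            "greater_trochanter": troch[keep],
            "lateral_epicondyle": E[keep],
            "lateral_malleolus": M[keep],
            "heel": heel[keep],
            "toe": toe[keep],
        }

        # ground-truth events: first frame of each stance / swing interval
        ic_frames, to_frames = [], []
        for c in range(cyc[keep].min(), cyc[keep].max() + 1):
            ic = int(np.ceil((c + phi) * T * FPS))
            to = int(np.ceil((c + phi + sf) * T * FPS))
            if 0 <= ic < n_frames:
                ic_frames.append(ic)
            if 0 <= to < n_frames and ic >= 0:
                to_frames.append(to)
        true_events[side] = {"ic": sorted(ic_frames), "to": sorted(to_frames)}

    sampled = curves.sampled()
    traj = WalkerTrajectory(
        timestamps=np.arange(n_frames) / FPS,
        sides=sides_data,
        true_events=true_events,
        true_curves={s: {k: v.copy() for k, v in sampled.items()} for s in SIDES},
        pattern=pattern,
        anthro=anthro,
        foreground_side=foreground_side,
        meta={"n_cycles": n_cycles, "stride": stride,
              "speed_truth": stride / T, "switch_frac": switch_frac,
              "start_x": start_x},
    )
    return traj


def add_noise(traj: WalkerTrajectory, noise=None, seed: int | None = None
              ) -> WalkerTrajectory:
    """Seeded Gaussian landmark jitter plus per-frame side dropout."""
    if noise is None:
        noise = traj.pattern.noise
    if seed is None:
        seed = traj.pattern.seed
    if noise.jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    out = traj.copy()
    rng = np.random.default_rng(seed)
    n = out.n_frames
    for side in SIDES:
        for name in LANDMARKS:
            if noise.jitter_sd > 0:
                out.sides[side][name] = (out.sides[side][name]
                                         + rng.normal(0, noise.jitter_sd, (n, 2)))
        if noise.dropout > 0:
            drop = rng.random(n) < noise.dropout
            for name in LANDMARKS:
                out.sides[side][name][drop] = np.nan
    out.meta["noise_applied"] = {"jitter_sd": noise.jitter_sd,
                                 "dropout": noise.dropout, "seed": seed}
    return out


def simulate_trial(pattern: GaitPatternSpec, anthro: Anthropometry | None = None,
                   n_cycles: int = 3, noisy: bool = True,
                   foreground_side: str = "right") -> WalkerTrajectory:
    """Convenience wrapper: curves -> forward kinematics -> optional noise."""
    if anthro is None:
        anthro = Anthropometry()
    curves = generate_joint_curves(pattern)
    traj = forward_kinematics(curves, anthro, pattern, n_cycles=n_cycles,
                              foreground_side=foreground_side)
    if noisy and (pattern.noise.jitter_sd > 0 or pattern.noise.dropout > 0):
        traj = add_noise(traj)
    return traj
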