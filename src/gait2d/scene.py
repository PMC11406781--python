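"""Rendering of the synthetic walker into RGB frame sequences.

The scene emulates the acquisition setup of a single lateral camera in
front of a green screen: a stick-figure walker with a red sock on the right
foot and a blue sock on the left, and near-black pen marks at the greater
trochanter, lateral femoral epicondyle and lateral malleolus of each leg.
The background leg is drawn first so the foreground leg occludes it, and an
optional per-pixel depth-proxy channel labels background/foreground leg
pixels — the stand-in for the depth image of an RGB-D camera.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from skimage.draw import polygon as draw_polygon, disk as draw_disk

from .walker import WalkerTrajectory, LANDMARKS

__all__ = ["SceneConfig", "FrameSequence", "render_frames"]

DEPTH_BACKGROUND = 0
DEPTH_BG_LEG = 1
DEPTH_FG_LEG = 2


@dataclass
class SceneConfig:
    width: int = 960
    height: int = 540
    pixels_per_meter: float = 130.0
    origin_x_px: float = 15.0        # image x of world x = 0
    ground_y_px: float = 40.0        # pixels between image bottom and the floor
    background_rgb: tuple = (45, 160, 70)
    right_sock_rgb: tuple = (205, 35, 35)
    left_sock_rgb: tuple = (35, 60, 205)
    mark_rgb: tuple = (18, 18, 18)
    mark_radius_px: float = 4.0
    limb_rgb: tuple = (205, 175, 150)
    bg_limb_rgb: tuple = (185, 158, 135)
    limb_halfwidth_px: float = 4.0
    sock_top_m: float = 0.045        # sock extent above the heel-toe axis
    sock_bottom_m: float = 0.012     # and below it
    brightness_jitter: float = 0.03  # per-frame multiplicative lighting noise
    include_depth: bool = True
    foreground_side: str = "right"

    def __post_init__(self):
        if self.pixels_per_meter <= 0:
            raise ValueError("pixels_per_meter must be > 0")

    def world_to_px(self, xy: np.ndarray) -> np.ndarray:
        """Metric (x forward, y up) -> image (col, row); row grows downward."""
        xy = np.asarray(xy, float)
        col = xy[..., 0] * self.pixels_per_meter + self.origin_x_px
        row = self.height - self.ground_y_px - xy[..., 1] * self.pixels_per_meter
        return np.stack([col, row], axis=-1)

    def px_to_world(self, colrow: np.ndarray) -> np.ndarray:
        cr = np.asarray(colrow, float)
        x = (cr[..., 0] - self.origin_x_px) / self.pixels_per_meter
        y = (self.height - self.ground_y_px - cr[..., 1]) / self.pixels_per_meter
        return np.stack([x, y], axis=-1)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FrameSequence:
    frames: list                      # (H, W, 3) uint8 arrays
    timestamps: np.ndarray
    scene: SceneConfig
    depth: list | None = None         # (H, W) uint8 label maps, optional
    fps: float = 30.0

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def _thick_segment(img, depth, p0, p1, halfwidth, rgb, label):
    d = p1 - p0
    n = np.hypot(*d)
    if n < 1e-9:
        return
    perp = np.array([-d[1], d[0]]) / n * halfwidth
    corners = np.array([p0 + perp, p1 + perp, p1 - perp, p0 - perp])
    rr, cc = draw_polygon(corners[:, 1], corners[:, 0], shape=img.shape[:2])
    img[rr, cc] = rgb
    if depth is not None:
        depth[rr, cc] = label


def _sock_polygon(heel, toe, scene: SceneConfig):
    """Tapered octagon whose extreme tips are exactly heel and toe.

    The tip wedges are symmetric about the heel-toe axis (the sock only
    widens to its full upper height mid-foot), so a centroid taken near a
    tip is unbiased across the axis."""
    u = toe - heel
    L = np.hypot(*u)
    u = u / L
    n = np.array([-u[1], u[0]])      # up-normal in world coordinates
    a, b = scene.sock_top_m, scene.sock_bottom_m
    t1, t2 = 0.15 * L, 0.40 * L
    return np.array([
        heel,
        heel + t1 * u - b * n,
        toe - t1 * u - b * n,
        toe,
        toe - t1 * u + b * n,
        toe - t2 * u + a * n,
        heel + t2 * u + a * n,
        heel + t1 * u + b * n,
    ])


def _draw_leg(img, depth, lm, scene: SceneConfig, side: str, label: int):
    limb = scene.limb_rgb if label == DEPTH_FG_LEG else scene.bg_limb_rgb
    T = scene.world_to_px(lm["greater_trochanter"])
    E = scene.world_to_px(lm["lateral_epicondyle"])
    M = scene.world_to_px(lm["lateral_malleolus"])
    heel_w, toe_w = lm["heel"], lm["toe"]
    _thick_segment(img, depth, T, E, scene.limb_halfwidth_px, limb, label)
    _thick_segment(img, depth, E, M, scene.limb_halfwidth_px, limb, label)
    poly_w = _sock_polygon(np.asarray(heel_w), np.asarray(toe_w), scene)
    poly_px = scene.world_to_px(poly_w)
    rr, cc = draw_polygon(poly_px[:, 1], poly_px[:, 0], shape=img.shape[:2])
    sock = scene.right_sock_rgb if side == "right" else scene.left_sock_rgb
    img[rr, cc] = sock
    if depth is not None:
        depth[rr, cc] = label
    for p in (T, E, M):
        rr, cc = draw_disk((p[1], p[0]), scene.mark_radius_px,
                           shape=img.shape[:2])
        img[rr, cc] = scene.mark_rgb
        if depth is not None:
            depth[rr, cc] = label


def render_frames(traj: WalkerTrajectory, scene: SceneConfig | None = None,
                  seed: int | None = None) -> FrameSequence:
    """Rasterize a walker trajectory into an RGB frame sequence.

    Frames with missing (NaN) landmarks are rendered without the affected
    leg.  Raises if any finite landmark projects outside the image, naming
    the frame.  Rendering is deterministic for a given trajectory, scene
    and seed (the seed only drives the per-frame lighting jitter and
    defaults to the trajectory's pattern seed).
    """
    scene = scene or SceneConfig(foreground_side=traj.foreground_side)
    if seed is None:
        seed = traj.pattern.seed
    rng = np.random.default_rng(seed + 7919)
    n = traj.n_frames
    fg = scene.foreground_side
    bg = "left" if fg == "right" else "right"

    # bounds check on all finite landmark projections
    for side in (bg, fg):
        for name in LANDMARKS:
            p = scene.world_to_px(traj.sides[side][name])
            ok = np.isfinite(p).all(axis=1)
            bad = ok & ((p[:, 0] < 0) | (p[:, 0] >= scene.width)
                        | (p[:, 1] < 0) | (p[:, 1] >= scene.height))
            if bad.any():
                f = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"landmark {side}/{name} projects outside the image "
                    f"at frame {f}")

    frames, depths = [], []
    base = np.empty((scene.height, scene.width, 3), np.uint8)
    base[:] = scene.background_rgb
    for f in range(n):
        img = base.copy()
        depth = (np.zeros((scene.height, scene.width), np.uint8)
                 if scene.include_depth else None)
        for side, label in ((bg, DEPTH_BG_LEG), (fg, DEPTH_FG_LEG)):
            lm = {k: traj.sides[side][k][f] for k in LANDMARKS}
            if any(np.isnan(v).any() for v in lm.values()):
                continue
            _draw_leg(img, depth, lm, scene, side, label)
        if scene.brightness_jitter > 0:
            gain = 1.0 + rng.normal(0.0, scene.brightness_jitter)
            img = np.clip(img.astype(np.float32) * gain, 0, 255).astype(np.uint8)
        frames.append(img)
        if scene.include_depth:
            depths.append(depth)
    return FrameSequence(frames=frames, timestamps=traj.timestamps.copy(),
                         scene=scene, depth=depths if scene.include_depth else None,
                         fps=traj.fps)
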