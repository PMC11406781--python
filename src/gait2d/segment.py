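"""Color-filter segmentation of walker frames.

Pixels are classified in hue/saturation/value space against configurable
ranges for the red (right) sock, blue (left) sock, near-black pen marks and
the green background.  The defaults match the renderer's palette; real
video requires re-tuning through the same configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2hsv
from skimage.measure import label as cc_label, regionprops

__all__ = ["ColorSpec", "segment_color", "extract_foot_points",
           "detect_pen_marks", "COLOR_CLASSES"]

log = logging.getLogger(__name__)

COLOR_CLASSES = ("right_sock_red", "left_sock_blue", "landmark_dark",
                 "background_green")


@dataclass
class ColorSpec:
    """HSV ranges per color class (hue wraps; all channels in [0, 1])."""

    right_sock_red: dict = field(default_factory=lambda: {
        "hue": (0.94, 0.06), "sat": (0.45, 1.0), "val": (0.25, 1.0)})
    left_sock_blue: dict = field(default_factory=lambda: {
        "hue": (0.52, 0.75), "sat": (0.45, 1.0), "val": (0.2, 1.0)})
    landmark_dark: dict = field(default_factory=lambda: {
        "hue": (0.0, 1.0), "sat": (0.0, 1.0), "val": (0.0, 0.18)})
    background_green: dict = field(default_factory=lambda: {
        "hue": (0.2, 0.45), "sat": (0.3, 1.0), "val": (0.1, 1.0)})
    min_blob_px: int = 10

    def __post_init__(self):
        r, b = self.right_sock_red, self.left_sock_blue
        if _hue_overlap(r["hue"], b["hue"]):
            raise ValueError("sock hue ranges must be mutually exclusive")


def _hue_overlap(h1, h2) -> bool:
    def expand(h):
        lo, hi = h
        return [(lo, hi)] if lo <= hi else [(lo, 1.0), (0.0, hi)]
    for a0, a1 in expand(h1):
        for b0, b1 in expand(h2):
            if max(a0, b0) < min(a1, b1):
                return True
    return False


def _in_range(channel, lo_hi, wrap=False):
    lo, hi = lo_hi
    if wrap and lo > hi:
        return (channel >= lo) | (channel <= hi)
    return (channel >= lo) & (channel <= hi)


def class_mask(hsv: np.ndarray, spec: ColorSpec, which: str,
               min_area: int | None = None) -> np.ndarray:
    """Boolean mask for one color class on a pre-computed HSV image."""
    if which not in COLOR_CLASSES:
        raise ValueError(f"unknown color class {which!r}; one of {COLOR_CLASSES}")
    rng = getattr(spec, which)
    m = (_in_range(hsv[..., 0], rng["hue"], wrap=True)
         & _in_range(hsv[..., 1], rng["sat"])
         & _in_range(hsv[..., 2], rng["val"]))
    area = spec.min_blob_px if min_area is None else min_area
    if area > 1 and m.any():
        lab = cc_label(m, connectivity=2)
        counts = np.bincount(lab.ravel())
        small = np.flatnonzero(counts < area)
        if small.size:
            m &= ~np.isin(lab, small[small > 0])
    return m


def segment_color(frame: np.ndarray, spec: ColorSpec, which: str) -> np.ndarray:
    """Color-class mask of an RGB uint8 frame (blobs below min area removed)."""
    hsv = rgb2hsv(frame)
    return class_mask(hsv, spec, which)


def _largest_blob(mask: np.ndarray) -> np.ndarray:
    """Restrict a mask to its largest connected blob (area ties: leftmost)."""
    lab = cc_label(mask, connectivity=2)
    if lab.max() <= 1:
        return mask
    props = regionprops(lab)
    # sort by (-area, leftmost column) so equal areas pick the leftmost blob
    props.sort(key=lambda p: (-p.area, p.bbox[1]))
    log.info("multiple same-color blobs (%d); keeping the largest", len(props))
    return lab == props[0].label


def _refine_centroid(mask: np.ndarray, point: np.ndarray,
                     radius: float = 2.5) -> np.ndarray:
    """Sub-pixel refinement: centroid of mask pixels within ``radius`` px."""
    c, r = point
    r0, r1 = int(max(0, r - radius - 1)), int(r + radius + 2)
    c0, c1 = int(max(0, c - radius - 1)), int(c + radius + 2)
    sub = mask[r0:r1, c0:c1]
    rr, cc = np.nonzero(sub)
    if rr.size == 0:
        return point.astype(float)
    d2 = (rr + r0 - r) ** 2 + (cc + c0 - c) ** 2
    keep = d2 <= radius ** 2
    if not keep.any():
        return point.astype(float)
    return np.array([np.mean(cc[keep] + c0), np.mean(rr[keep] + r0)])


def extract_foot_points(mask: np.ndarray, walk_direction: float = 1.0):
    """(heel, toe) pixel points of a sock blob, or None if the mask is empty.

    The toe is the blob's extreme point along the walking direction and the
    heel the extreme point against it, both refined to sub-pixel precision
    by a local centroid over a 5-px neighborhood.  With several disjoint
    blobs the largest is used (ties broken by the leftmost).
    """
    if not mask.any():
        return None
    mask = _largest_blob(mask)
    rr, cc = np.nonzero(mask)
    # Extremes are taken along the blob's principal axis, oriented by the
    # walking direction: for a foot-shaped blob the principal axis follows
    # the heel-toe line, so the rule stays correct when the foot is steeply
    # heel-up (push-off), where a pure image-x extreme would catch a corner
    # of the sock instead of the toe tip.
    pts = np.stack([cc.astype(float), rr.astype(float)], axis=1)
    ctr = pts.mean(axis=0)
    d = pts - ctr
    cov = d.T @ d
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]
    if axis[0] * walk_direction < 0:
        axis = -axis
    proj = d @ axis
    out = []
    for which, idx, extreme in (("heel", np.argmin(proj), proj.min() - 0.4),
                                ("toe", np.argmax(proj), proj.max() + 0.4)):
        # centroid refinement gives a robust sub-pixel CROSS-axis position,
        # but pulls inward along the axis (the tip tapers); keep the
        # centroid's perpendicular component and the extreme pixel's
        # projection (plus a half-pixel edge term) along the axis
        c = _refine_centroid(mask, pts[idx]) - ctr
        perp = c - (c @ axis) * axis
        out.append(ctr + extreme * axis + perp)
    heel, toe = out
    return heel, toe


def detect_pen_marks(frame_or_hsv: np.ndarray, spec: ColorSpec,
                     leg_mask_region: np.ndarray | None = None) -> dict:
    """Up to three pen-mark centroids inside a leg region.

    Dark blobs within ``leg_mask_region`` (entire frame if None) are
    assigned to trochanter/epicondyle/malleolus by descending height
    (image-y ascending).  Missing marks are returned as None rather than
    raising.
    """
    if frame_or_hsv.dtype == np.uint8:
        hsv = rgb2hsv(frame_or_hsv)
    else:
        hsv = frame_or_hsv
    m = class_mask(hsv, spec, "landmark_dark")
    if leg_mask_region is not None:
        m = m & leg_mask_region
    out = {"greater_trochanter": None, "lateral_epicondyle": None,
           "lateral_malleolus": None}
    if not m.any():
        return out
    lab = cc_label(m, connectivity=2)
    props = [p for p in regionprops(lab) if p.area >= spec.min_blob_px]
    props.sort(key=lambda p: -p.area)
    props = props[:3]
    props.sort(key=lambda p: p.centroid[0])      # image y ascending
    names = ["greater_trochanter", "lateral_epicondyle", "lateral_malleolus"]
    if len(props) < 3:
        # keep the vertical-order rule meaningful: topmost -> trochanter etc.
        names = names[:len(props)]
    for name, p in zip(names, props):
        out[name] = np.array([p.centroid[1], p.centroid[0]])  # (col, row)
    return out
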