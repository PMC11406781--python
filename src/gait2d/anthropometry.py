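"""Body-segment geometry of the simulated walker.

Default segment lengths are derived from stature with the standard
body-segment fractions used in gait biomechanics (thigh 0.245 H, shank
0.246 H, foot length 0.152 H).  The default stature (1.36 m) matches the
mean height of school-age children with bilateral cerebral palsy that the
pipeline is aimed at.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Anthropometry"]


@dataclass(frozen=True)
class Anthropometry:
    stature: float = 1.36          # m
    thigh_length: float = None     # greater trochanter -> lateral epicondyle
    shank_length: float = None     # epicondyle -> lateral malleolus
    foot_length: float = None      # heel -> toe
    heel_offset: float = 0.05      # malleolus -> heel along the foot axis, m
    ankle_height: float = 0.06     # malleolus above the foot axis, m

    def __post_init__(self):
        if self.thigh_length is None:
            object.__setattr__(self, "thigh_length", 0.245 * self.stature)
        if self.shank_length is None:
            object.__setattr__(self, "shank_length", 0.246 * self.stature)
        if self.foot_length is None:
            object.__setattr__(self, "foot_length", 0.152 * self.stature)
        for name in ("stature", "thigh_length", "shank_length", "foot_length",
                     "heel_offset", "ankle_height"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.thigh_length + self.shank_length >= self.stature:
            raise ValueError("thigh + shank length must be smaller than stature")

    @property
    def leg_length(self) -> float:
        """Standing height of the greater trochanter above the ground."""
        return self.thigh_length + self.shank_length + self.ankle_height
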