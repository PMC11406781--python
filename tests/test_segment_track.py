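"""Color segmentation, foot/pen-mark extraction and sequence tracking."""

import numpy as np
import pytest
from skimage.draw import polygon as draw_polygon

from gait2d.scene import SceneConfig, render_frames
from gait2d.segment import (ColorSpec, detect_pen_marks, extract_foot_points,
                            segment_color)
from gait2d.tracking import TrialRejectedError, track_sequence
from gait2d.walker import add_noise, simulate_trial
from gait2d.patterns import GaitPatternSpec, NoiseSpec


def _uniform(rgb, shape=(120, 160)):
    img = np.empty(shape + (3,), np.uint8)
    img[:] = rgb
    return img


class TestSegmentColor:
    def test_uniform_green_gives_empty_red_mask(self):
        img = _uniform((45, 160, 70))
        assert not segment_color(img, ColorSpec(), "right_sock_red").any()

    def test_red_patch_detected_blue_unaffected(self):
        """Red-channel processing never alters blue-channel outputs."""
        img = _uniform((45, 160, 70))
        img[40:60, 50:80] = (205, 35, 35)
        spec = ColorSpec()
        red = segment_color(img, spec, "right_sock_red")
        blue_before = segment_color(img, spec, "left_sock_blue")
        img2 = img.copy()
        img2[40:60, 50:80] = (45, 160, 70)          # remove red patch
        blue_after = segment_color(img2, spec, "left_sock_blue")
        assert red[45, 60] and red.sum() == 20 * 30
        assert np.array_equal(blue_before, blue_after)

    def test_min_area_removes_specks(self):
        img = _uniform((45, 160, 70))
        img[10, 10] = (205, 35, 35)
        assert not segment_color(img, ColorSpec(), "right_sock_red").any()

    def test_mask_idempotent(self):
        img = _uniform((45, 160, 70))
        img[30:50, 40:70] = (205, 35, 35)
        spec = ColorSpec()
        m1 = segment_color(img, spec, "right_sock_red")
        highlighted = _uniform((45, 160, 70))
        highlighted[m1] = (205, 35, 35)
        m2 = segment_color(highlighted, spec, "right_sock_red")
        assert np.array_equal(m1, m2)

    def test_overlapping_sock_hues_rejected(self):
        with pytest.raises(ValueError):
            ColorSpec(right_sock_red={"hue": (0.5, 0.8), "sat": (0.4, 1),
                                      "val": (0.2, 1)})

    def test_unknown_class(self):
        with pytest.raises(ValueError):
            segment_color(_uniform((0, 0, 0)), ColorSpec(), "polka_dot")


class TestExtractFootPoints:
    def test_rectangle_extremes(self):
        mask = np.zeros((200, 300), bool)
        mask[100:115, 100:161] = True
        heel, toe = extract_foot_points(mask, 1.0)
        assert heel[0] == pytest.approx(100, abs=1.5)
        assert toe[0] == pytest.approx(160, abs=1.5)

    def test_empty_mask_is_missing(self):
        assert extract_foot_points(np.zeros((50, 50), bool)) is None

    def test_larger_blob_wins(self):
        mask = np.zeros((100, 300), bool)
        mask[40:50, 20:40] = True                    # small blob
        mask[40:52, 100:180] = True                  # large blob
        heel, toe = extract_foot_points(mask, 1.0)
        assert 98 <= heel[0] <= 103 and 176 <= toe[0] <= 181

    def test_walking_direction_flips_roles(self):
        mask = np.zeros((100, 300), bool)
        mask[40:50, 100:180] = True
        h1, t1 = extract_foot_points(mask, 1.0)
        h2, t2 = extract_foot_points(mask, -1.0)
        assert np.allclose(h1, t2) and np.allclose(t1, h2)


class TestDetectPenMarks:
    def test_vertical_ordering_rule(self):
        img = _uniform((45, 160, 70), (900, 400))
        from skimage.draw import disk
        for y in (400, 600, 800):
            rr, cc = disk((y, 200), 5, shape=img.shape[:2])
            img[rr, cc] = (18, 18, 18)
        marks = detect_pen_marks(img, ColorSpec())
        assert marks["greater_trochanter"][1] == pytest.approx(400, abs=1)
        assert marks["lateral_epicondyle"][1] == pytest.approx(600, abs=1)
        assert marks["lateral_malleolus"][1] == pytest.approx(800, abs=1)

    def test_missing_marks_flagged_not_raised(self):
        img = _uniform((45, 160, 70))
        marks = detect_pen_marks(img, ColorSpec())
        assert all(v is None for v in marks.values())


class TestRenderedFrameAccuracy:
    def test_background_is_scene_green(self, rendered_trial):
        frame = rendered_trial["frames"].frames[0]
        scene = rendered_trial["frames"].scene
        corner = frame[2, -3].astype(float)
        assert np.allclose(corner, scene.background_rgb, atol=25)

    def test_red_mask_area_matches_sock_polygon(self, rendered_trial):
        """Segmented right-sock area within 15% of the rendered polygon."""
        from gait2d.scene import _sock_polygon

        fs = rendered_trial["frames"]
        traj = rendered_trial["noisy"]
        f = 10
        mask = segment_color(fs.frames[f], ColorSpec(), "right_sock_red")
        poly_w = _sock_polygon(traj.sides["right"]["heel"][f],
                               traj.sides["right"]["toe"][f], fs.scene)
        poly_px = fs.scene.world_to_px(poly_w)
        rr, cc = draw_polygon(poly_px[:, 1], poly_px[:, 0],
                              shape=mask.shape)
        area_poly = len(rr)
        assert abs(mask.sum() - area_poly) <= 0.15 * area_poly

    def test_red_centroid_near_right_foot(self, rendered_trial):
        fs = rendered_trial["frames"]
        traj = rendered_trial["noisy"]
        f = 15
        mask = segment_color(fs.frames[f], ColorSpec(), "right_sock_red")
        rr, cc = np.nonzero(mask)
        centroid = np.array([cc.mean(), rr.mean()])
        mid_w = 0.5 * (traj.sides["right"]["heel"][f]
                       + traj.sides["right"]["toe"][f])
        mid_px = fs.scene.world_to_px(mid_w)
        assert np.hypot(*(centroid - mid_px)) < 5.0

    def test_heel_toe_and_marks_within_3px(self, rendered_trial):
        fs = rendered_trial["frames"]
        traj = rendered_trial["noisy"]
        tracked = rendered_trial["tracked"]
        scene = fs.scene
        for f in (5, 20, 40, 60):
            for name in ("heel", "toe", "greater_trochanter",
                         "lateral_epicondyle", "lateral_malleolus"):
                det = tracked.sides_px["right"][name][f]
                truth = scene.world_to_px(traj.sides["right"][name][f])
                assert np.hypot(*(det - truth)) < 3.0, (f, name)

    def test_rendering_deterministic(self, rendered_trial):
        fs2 = render_frames(rendered_trial["noisy"])
        assert np.array_equal(fs2.frames[7], rendered_trial["frames"].frames[7])

    def test_landmark_outside_image_names_frame(self, rendered_trial):
        scene = SceneConfig(width=120, height=90)
        with pytest.raises(ValueError, match="frame 0"):
            render_frames(rendered_trial["noisy"], scene)


class TestTrackSequence:
    def test_noise_free_rmse_under_1cm(self):
        spec = GaitPatternSpec(pattern_name="normal", seed=4,
                               curve_variability_sd=0.0,
                               noise=NoiseSpec(0.0, 0.0))
        traj = simulate_trial(spec, n_cycles=2, noisy=False)
        tracked = track_sequence(render_frames(traj))
        for name in traj.sides["right"]:
            err = np.hypot(*(tracked.sides["right"][name]
                             - traj.sides["right"][name]).T)
            assert np.nanquantile(err, 0.95) < 0.01, name

    def test_30_percent_dropout_rejected_with_reason(self):
        spec = GaitPatternSpec(pattern_name="normal", seed=4,
                               noise=NoiseSpec(0.0, 0.30))
        traj = simulate_trial(spec, n_cycles=2, noisy=True)
        with pytest.raises(TrialRejectedError) as err:
            track_sequence(render_frames(traj))
        assert err.value.reason_code == "feet_unclear"

    def test_needs_two_frames(self, rendered_trial):
        from gait2d.scene import FrameSequence

        fs = rendered_trial["frames"]
        single = FrameSequence(frames=fs.frames[:1],
                               timestamps=fs.timestamps[:1], scene=fs.scene,
                               depth=fs.depth[:1] if fs.depth else None)
        with pytest.raises(ValueError):
            track_sequence(single)

    def test_scale_equivariance(self):
        """Doubling pixels_per_meter leaves metric outputs unchanged within
        sub-pixel tolerance."""
        spec = GaitPatternSpec(pattern_name="normal", seed=9,
                               curve_variability_sd=0.0,
                               noise=NoiseSpec(0.0, 0.0))
        traj = simulate_trial(spec, n_cycles=1, noisy=False)
        lo = track_sequence(render_frames(
            traj, SceneConfig(pixels_per_meter=110, brightness_jitter=0)))
        hi = track_sequence(render_frames(
            traj, SceneConfig(pixels_per_meter=220, brightness_jitter=0)))
        for name in ("heel", "toe", "lateral_malleolus"):
            d = np.nanmax(np.hypot(*(lo.sides["right"][name]
                                     - hi.sides["right"][name]).T))
            assert d < 2.0 / 110.0, name


class TestSmoothingAndGaps:
    def test_constant_position_gap_interpolates_to_constant(self):
        from gait2d.filters import fill_short_gaps

        x = np.full((40, 2), 3.3)
        x[17] = np.nan
        filled, interp, still = fill_short_gaps(x, max_gap=5)
        assert filled[17, 0] == pytest.approx(3.3)
        assert interp[17] and not still.any()

    def test_long_gap_stays_missing(self):
        from gait2d.filters import fill_short_gaps

        x = np.ones((40, 2))
        x[10:20] = np.nan
        filled, interp, still = fill_short_gaps(x, max_gap=5)
        assert still[12] and not interp[12]

    def test_smoothing_preserves_stationary_mean(self):
        from gait2d.filters import lowpass

        x = np.full((200, 2), 0.73)
        sm = lowpass(x)
        assert np.allclose(sm, 0.73, atol=1e-9)
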