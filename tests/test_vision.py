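"""Vision-chain correctness against generator ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage import draw as skdraw

from pecktrack import scene, vision


def _blank(h=120, w=160, gray=220):
    return np.full((h, w), gray, dtype=np.uint8)


class TestCalibration:
    @pytest.mark.parametrize(
        "mm_per_px,expect,tol", [(0.1, 0.1, 0.005), (0.05, 0.05, 0.0025)]
    )
    def test_recovers_scale_from_ruler(self, mm_per_px, expect, tol):
        img = scene.render_ruler(scene.SceneConfig(mm_per_px=mm_per_px), 1.0)
        cal = vision.calibrate_from_ruler(img, 1.0)
        assert cal.mm_per_px == pytest.approx(expect, abs=tol)

    def test_blank_image_fails(self):
        with pytest.raises(vision.CalibrationError):
            vision.calibrate_from_ruler(_blank(), 1.0)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            vision.Calibration(mm_per_px=0.0)


class TestDetectEye:
    def test_recovers_scripted_eye_center(self, clean_scene):
        cfg, frames, truth = clean_scene
        for t in (0, len(frames) // 2, len(frames) - 1):
            ex, ey = vision.detect_eye(frames.frames[t])
            assert np.hypot(ex - truth.eye_center[t, 0], ey - truth.eye_center[t, 1]) <= 0.5

    def test_disc_beats_equal_area_square(self):
        """A dark square of the same area loses to the eye disc on
        circularity (disc ~1.0 vs square ~0.785)."""
        img = _blank()
        rr, cc = skdraw.disk((40, 40), 9)
        img[rr, cc] = 30
        side = int(round(np.sqrt(np.pi) * 9))  # same area as the disc
        img[80 : 80 + side, 100 : 100 + side] = 30
        ex, ey = vision.detect_eye(img)
        assert np.hypot(ex - 40, ey - 40) <= 1.0

    def test_blank_frame_fails(self):
        with pytest.raises(vision.DetectionFailure):
            vision.detect_eye(_blank())

    def test_candidates_outside_area_band_ignored(self):
        img = _blank()
        rr, cc = skdraw.disk((30, 30), 2)  # far too small to be the eye
        img[rr, cc] = 30
        with pytest.raises(vision.DetectionFailure):
            vision.detect_eye(img)


class TestHeadRoi:
    def test_roi_contains_both_tips(self, clean_scene):
        cfg, frames, truth = clean_scene
        t = len(frames) // 2
        e = vision.detect_eye(frames.frames[t])
        roi, (ox, oy) = vision.extract_head_roi(frames.frames[t], e)
        for tip in (truth.upper_tip[t], truth.lower_tip[t]):
            assert ox <= tip[0] < ox + roi.shape[1]
            assert oy <= tip[1] < oy + roi.shape[0]

    def test_corner_eye_clips_to_origin(self):
        img = _blank()
        roi, off = vision.extract_head_roi(img, (0.0, 0.0))
        assert off == (0, 0)
        assert roi.shape[0] <= img.shape[0] and roi.shape[1] <= img.shape[1]

    def test_offset_round_trip(self, clean_scene):
        cfg, frames, truth = clean_scene
        f = frames.frames[0]
        e = vision.detect_eye(f)
        roi, (ox, oy) = vision.extract_head_roi(f, e)
        assert np.array_equal(roi, f[oy : oy + roi.shape[0], ox : ox + roi.shape[1]])


class TestParticleRemoval:
    def test_no_particles_removal_is_noop(self, clean_scene):
        cfg, frames, truth = clean_scene
        t = 30
        f = frames.frames[t]
        e = truth.eye_center[t]
        roi, (ox, oy) = vision.extract_head_roi(f, tuple(e))
        eye_roi = (e[0] - ox, e[1] - oy)
        on, w1 = vision.remove_particle_pixels(roi, eye_roi, vision.VisionParams(remove_particles=True))
        off, w2 = vision.remove_particle_pixels(roi, eye_roi, vision.VisionParams(remove_particles=False))
        assert not w1 and not w2
        assert np.array_equal(on, off)

    def test_all_background_roi_gives_empty_mask_and_warning(self):
        mask, warn = vision.remove_particle_pixels(_blank(), (10.0, 10.0))
        assert warn and not mask.any()

    def test_opening_kernel_cleans_speckle_but_keeps_head(self, noisy_scene):
        cfg, frames, truth = noisy_scene
        t = int(truth.mandibulations[0].peak_frame)
        f = frames.frames[t]
        e = vision.detect_eye(f)
        p = vision.VisionParams(particle_kernel=3)
        roi, (ox, oy) = vision.extract_head_roi(f, e, p)
        eye_roi = (e[0] - ox, e[1] - oy)
        opened, warn = vision.remove_particle_pixels(roi, eye_roi, p)
        plain, _ = vision.remove_particle_pixels(roi, eye_roi, vision.VisionParams())
        assert not warn
        assert opened.sum() <= plain.sum()  # opening only removes pixels
        assert opened[int(eye_roi[1]), int(eye_roi[0])]  # head still present

    def test_removal_rescues_tip_under_particle(self, noisy_scene):
        """A feed particle overlapping the lower tip pushes the detected tip
        off by >2 px unless its pixels are excised first."""
        cfg, frames, truth = noisy_scene
        t = int(truth.mandibulations[0].peak_frame)
        f = frames.frames[t].copy()
        # plant an extra particle square on the lower tip
        lx, ly = truth.lower_tip[t]
        rr, cc = skdraw.disk((ly + 1, lx + 2), 4, shape=f.shape)
        f[rr, cc] = cfg.particle_gray
        e = vision.detect_eye(f)
        errs = {}
        for flag in (True, False):
            p = vision.VisionParams(remove_particles=flag)
            roi, (ox, oy) = vision.extract_head_roi(f, e, p)
            mask, _ = vision.remove_particle_pixels(roi, (e[0] - ox, e[1] - oy), p)
            _, (lx2, ly2) = vision.detect_beak_tips(mask, (e[0] - ox, e[1] - oy), "right", p)
            errs[flag] = np.hypot(lx2 + ox - lx, ly2 + oy - ly)
        assert errs[True] <= 2.0
        assert errs[False] > 2.0


class TestBeakTips:
    def test_recovers_scripted_tips(self, clean_scene):
        cfg, frames, truth = clean_scene
        cal = vision.Calibration(mm_per_px=cfg.mm_per_px)
        ht = vision.track_sequence(frames.frames, cal)
        open_frames = truth.gape_mm > 1.0
        for tips, true_tips in (
            (ht.upper_tip, truth.upper_tip),
            (ht.lower_tip, truth.lower_tip),
        ):
            err = np.hypot(*(tips - true_tips).T)[open_frames]
            assert err.max() <= 1.5

    def test_closed_beak_returns_near_zero_gape(self, clean_scene):
        cfg, frames, truth = clean_scene
        cal = vision.Calibration(mm_per_px=cfg.mm_per_px)
        ht = vision.track_sequence(frames.frames, cal)
        nearly_closed = truth.gape_mm < 0.21
        assert nearly_closed.any()
        assert np.all(ht.gape_px[nearly_closed] <= 2.0)

    def test_empty_mask_fails(self):
        with pytest.raises(vision.TipDetectionFailure):
            vision.detect_beak_tips(np.zeros((10, 10), bool), (5.0, 5.0))

    def test_gape_rmse_under_noise(self):
        """Five hundred frames at noise_sd=5: per-frame gape RMSE vs ground
        truth stays within 2 px."""
        rng = np.random.default_rng(42)
        episodes = [
            scene.make_episode(
                rng,
                [(min(i + 1, 4), float(rng.uniform(2.5, 4.5)), int(rng.integers(18, 26)), False)
                 for i in range(5)],
            )
            for _ in range(5)
        ]
        script = scene.make_script(rng, episodes)
        cfg = scene.SceneConfig(noise_sd=5.0, seed=42)
        frames, truth = scene.render_sequence(cfg, script)
        assert len(frames) >= 500
        cal = vision.Calibration(mm_per_px=cfg.mm_per_px)
        ht = vision.track_sequence(frames.frames, cal)
        err = ht.gape_px - truth.gape_mm / cfg.mm_per_px
        assert np.sqrt(np.mean(err**2)) <= 2.0


class TestTrackSequence:
    def test_clean_sequence_tracks_everything(self, clean_scene):
        cfg, frames, truth = clean_scene
        cal = vision.Calibration(mm_per_px=cfg.mm_per_px)
        ht = vision.track_sequence(frames.frames, cal)
        assert int(ht.flag.sum()) == 0
        eye_err = np.hypot(*(ht.eye - truth.eye_center).T)
        assert np.sqrt(np.mean(eye_err**2)) <= 0.5

    def test_gape_series_correlates_with_truth(self, clean_scene):
        from pecktrack.stats import spearman

        cfg, frames, truth = clean_scene
        cal = vision.Calibration(mm_per_px=cfg.mm_per_px)
        ht = vision.track_sequence(frames.frames, cal)
        assert spearman(ht.gape_mm, truth.gape_mm).statistic >= 0.99

    def test_gape_mm_is_scaled_gape_px(self, clean_scene):
        cfg, frames, _ = clean_scene
        cal = vision.Calibration(mm_per_px=cfg.mm_per_px)
        ht = vision.track_sequence(frames.frames, cal)
        assert np.array_equal(ht.gape_mm, ht.gape_px * cfg.mm_per_px)
        assert np.all(ht.gape_mm >= 0)

    def test_blanked_frames_flagged_and_interpolated(self, clean_scene):
        cfg, frames, truth = clean_scene
        stack = frames.frames.copy()
        for t in (40, 41, 60):
            stack[t] = cfg.background_gray  # nothing to detect
        cal = vision.Calibration(mm_per_px=cfg.mm_per_px)
        ht = vision.track_sequence(stack, cal)
        assert int(ht.flag.sum()) == 3
        assert set(np.nonzero(ht.flag)[0]) == {40, 41, 60}
        # frame 60 sits between two clean detections: linear interpolation
        expected = (ht.eye[59] + ht.eye[61]) / 2
        assert np.allclose(ht.eye[60], expected, atol=1e-9)

    def test_too_many_failures_rejects_sequence(self, clean_scene):
        cfg, frames, _ = clean_scene
        stack = frames.frames.copy()
        stack[: len(stack) // 2] = cfg.background_gray
        cal = vision.Calibration(mm_per_px=cfg.mm_per_px)
        with pytest.raises(vision.SequenceRejectedError):
            vision.track_sequence(stack, cal)

    @settings(deadline=None, max_examples=8, derandomize=True)
    @given(dx=st.integers(-12, 12), dy=st.integers(-8, 8))
    def test_eye_detection_translation_equivariant(self, dx, dy):
        cfg = scene.SceneConfig(noise_sd=0.0, particle_count=0, seed=3)
        rng = np.random.default_rng(3)
        script = scene.KinematicScript(
            episodes=[scene.make_episode(rng, [(1, 4.0, 16, False)])]
        )
        frames, truth = scene.render_sequence(cfg, script)
        f = frames.frames[8]
        e0 = vision.detect_eye(f)
        shifted = np.full_like(f, cfg.background_gray)
        src = f
        h, w = f.shape
        ys0, ys1 = max(0, dy), min(h, h + dy)
        xs0, xs1 = max(0, dx), min(w, w + dx)
        shifted[ys0:ys1, xs0:xs1] = src[ys0 - dy : ys1 - dy, xs0 - dx : xs1 - dx]
        e1 = vision.detect_eye(shifted)
        assert e1[0] - e0[0] == pytest.approx(dx, abs=1e-6)
        assert e1[1] - e0[1] == pytest.approx(dy, abs=1e-6)
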