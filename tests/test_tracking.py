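"""Masked feature tracking and the chained homography."""

from dataclasses import replace

import numpy as np
import pytest
from skimage.transform import rotate

from otoar import (
    SceneSpec,
    TrackerConfig,
    TrackingLostError,
    corner_deviation_px,
    detect_features,
    detect_tracking_failure,
    init_tracker,
    match_features,
    overlay_current,
    simulate_dataset,
    track_frame,
)
from otoar.pipeline import PipelineConfig, register_dataset
from otoar.registration import EllipseMask


@pytest.fixture(scope="module")
def tracked_scene():
    ds = simulate_dataset(replace(SceneSpec.preset_2min(13), duration_s=4.0))
    reg = register_dataset(ds, PipelineConfig(seed=4))
    return ds, reg


class TestDetectFeatures:
    def test_masked_detection_stays_inside_mask(self, tracked_scene):
        ds, reg = tracked_scene
        feats = detect_features(ds.frame(0), reg.mask)
        assert len(feats) >= 200
        assert reg.mask.contains(feats.keypoints).all()

    def test_uniform_frame_flags_low_texture(self):
        flat = np.full((240, 240), 128, dtype=np.uint8)
        feats = detect_features(flat, None)
        assert feats.low_texture

    def test_rotation_repeatability(self, tracked_scene):
        """At least 60% of keypoints re-detected within 2 px after rotating
        the frame by 30 degrees and mapping back."""
        ds, _ = tracked_scene
        gray = ds.frame(0)[..., :3] @ np.array([0.2125, 0.7154, 0.0721]) / 255.0
        f0 = detect_features(gray, None)
        rot = rotate(gray, 30, center=(gray.shape[1] / 2, gray.shape[0] / 2))
        f1 = detect_features(rot, None)
        ang = np.deg2rad(30)
        c = np.array([gray.shape[1] / 2, gray.shape[0] / 2])
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        back = (f1.keypoints - c) @ R.T + c
        d = np.linalg.norm(f0.keypoints[:, None] - back[None], axis=2)
        # keep original keypoints that stayed inside the rotated view
        inside = np.linalg.norm(f0.keypoints - c, axis=1) < min(c) * 0.7
        recovered = (d.min(axis=1)[inside] < 2.0).mean()
        assert recovered >= 0.6


class TestMatchFeatures:
    def test_identical_sets_match_one_to_one(self, tracked_scene):
        ds, reg = tracked_scene
        f = detect_features(ds.frame(0), reg.mask)
        m = match_features(f, f)
        assert len(m) == len(f)
        assert np.array_equal(m[:, 0], m[:, 1])

    def test_ambiguous_duplicates_are_rejected(self):
        """A keypoint whose best and second-best matches are equally close
        carries no correspondence information and must be dropped."""
        from otoar.tracking import FrameFeatures

        rng = np.random.default_rng(3)
        desc = rng.integers(0, 2, (40, 256)) > 0

        def feats(d):
            k = len(d)
            return FrameFeatures(rng.uniform(0, 100, (k, 2)), np.ones(k),
                                 np.zeros(k), d)

        n = 20
        dup = np.vstack([desc, desc[:n]])  # first 20 descriptors twice
        m = match_features(feats(desc), feats(dup))
        assert not np.isin(m[:, 0], np.arange(n)).any()
        # the unambiguous half still matches one-to-one
        assert np.array_equal(np.sort(m[:, 0]), np.arange(n, 40))

    def test_disjoint_random_descriptors_rarely_match(self, rng):
        from otoar.tracking import FrameFeatures

        def fake(seed):
            r = np.random.default_rng(seed)
            return FrameFeatures(r.uniform(0, 100, (64, 2)), np.ones(64),
                                 np.zeros(64), r.integers(0, 2, (64, 256)) > 0)

        m = match_features(fake(0), fake(1))
        assert len(m) <= 6


class TestTrackFrame:
    def test_static_video_chain_stays_at_identity(self, static_ds):
        reg = register_dataset(static_ds, PipelineConfig(seed=3))
        state = init_tracker(static_ds.frame(0), reg.mask)
        from otoar import Homography

        for fi in range(1, len(static_ds)):
            state = track_frame(state, static_ds.frame(fi))
            assert state.status == "tracking"
        dev = corner_deviation_px(state.H_cum, Homography.identity(),
                                  static_ds.spec.frame_size)
        assert dev < 0.5

    def test_chain_follows_truth_homography(self, tracked_scene):
        ds, reg = tracked_scene
        state = init_tracker(ds.frame(0), reg.mask, TrackerConfig(seed=1))
        for fi in range(1, len(ds)):
            state = track_frame(state, ds.frame(fi))
            assert state.status == "tracking"
        truth = ds.truths[len(ds) - 1].true_plane_homography
        ring = ds.truths[0].fiducial_px
        err = np.linalg.norm(state.H_cum.apply(ring) - truth.apply(ring), axis=1)
        assert err.max() < 1.0

    def test_jerk_breaks_tracking(self):
        ds = simulate_dataset(SceneSpec.preset_jerk(5, duration_s=4.0,
                                                    jerk_time_s=2.0))
        reg = register_dataset(ds, PipelineConfig(seed=5))
        state = init_tracker(ds.frame(0), reg.mask)
        statuses = []
        for fi in range(1, len(ds)):
            if state.status != "tracking":
                break
            state = track_frame(state, ds.frame(fi))
            statuses.append((fi, state.status))
        lost = [fi for fi, s in statuses if s == "lost"]
        assert lost and abs(lost[0] - int(2.0 * ds.spec.fps)) <= 1

    def test_lost_state_rejects_further_tracking(self, static_ds):
        reg = register_dataset(static_ds, PipelineConfig(seed=3))
        state = init_tracker(static_ds.frame(0), reg.mask)
        state = replace(state, status="lost")
        with pytest.raises(TrackingLostError):
            track_frame(state, static_ds.frame(1))

    def test_matched_keypoints_lie_inside_mapped_mask(self, tracked_scene):
        """Keypoints carried by the tracker were detected inside the mask
        current at their frame; after the mask is remapped through the new
        chain they stay within a few pixels of it."""
        ds, reg = tracked_scene
        state = init_tracker(ds.frame(0), reg.mask)
        for fi in range(1, 6):
            prev_mask = state.mask
            state = track_frame(state, ds.frame(fi))
            assert prev_mask.contains(state.prev_features.keypoints,
                                      margin=6.0).all()


class TestFailureDetection:
    @pytest.mark.parametrize(
        "inliers,err,expected",
        [(50, 0.4, False), (4, 0.4, True), (50, 7.0, True), (8, 5.0, False)],
    )
    def test_thresholds(self, inliers, err, expected):
        assert detect_tracking_failure(inliers, err) is expected

    def test_sweep_matches_bruteforce_reclassification(self, rng):
        inl = rng.integers(0, 40, 200)
        errs = rng.uniform(0, 10, 200)
        flags = [detect_tracking_failure(i, e) for i, e in zip(inl, errs)]
        brute = [(i < 8) or (e > 5.0) for i, e in zip(inl, errs)]
        assert flags == brute


class TestOverlay:
    def test_identity_chain_beta_zero_returns_ct(self, static_ds):
        from otoar import Homography

        ct = np.repeat(static_ds.ct_render[:, :, None], 3, axis=2)
        out = overlay_current(ct, Homography.identity(), static_ds.frame(0),
                              beta=0.0)
        assert np.abs(out.astype(int) - ct.astype(int)).max() <= 1

    def test_translation_shifts_overlay(self, static_ds):
        from otoar import Homography

        ct = np.repeat(static_ds.ct_render[:, :, None], 3, axis=2)
        out = overlay_current(ct, Homography.translation(15, 0),
                              static_ds.frame(0), beta=0.0)
        assert np.abs(out[:, 15:].astype(int) - ct[:, :-15].astype(int)).mean() < 2

    def test_lost_returns_raw_frame(self, static_ds):
        from otoar import Homography

        frame = static_ds.frame(0)
        out = overlay_current(static_ds.ct_render, Homography.identity(), frame,
                              beta=0.3, tracking=False)
        assert np.array_equal(out, frame)


def test_ellipse_mask_contains_is_vectorized():
    mask = EllipseMask((50.0, 50.0), (20.0, 10.0), 0.0)
    pts = np.array([[50, 50], [69, 50], [50, 59], [71, 50], [50, 61]])
    assert list(mask.contains(pts)) == [True, True, True, False, False]


def test_compose_ar_view_paints_instrument(static_ds):
    from otoar import Homography, compose_ar_view

    ct = np.repeat(static_ds.ct_render[:, :, None], 3, axis=2)
    frame = static_ds.frame(0)
    out = compose_ar_view(ct, Homography.identity(), frame, beta=0.5,
                          marker_px=np.array([[100.0, 100.0]]),
                          tip_px=np.array([150.0, 150.0]))
    assert tuple(out[100, 100]) == (240, 210, 40)   # marker disc
    assert tuple(out[150, 156]) == (240, 210, 40)   # tip cross arm
    plain = compose_ar_view(ct, Homography.identity(), frame, beta=0.5)
    assert not np.array_equal(out, plain)
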