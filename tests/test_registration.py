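"""CT marker extraction, registration, ellipse mask and blending."""

import numpy as np
import pytest

from otoar import (
    ConfigError,
    EstimationError,
    Homography,
    RegistrationError,
    SceneSpec,
    blend,
    extract_ct_markers,
    fit_ellipse_mask,
    refine_and_register,
    registration_error_mm,
    simulate_dataset,
)
from otoar.pipeline import PipelineConfig, register_dataset
from otoar.registration import BlendConfig, px_per_mm_from_distances


class TestExtractCtMarkers:
    def test_recovers_all_rendered_markers_subpixel(self, static_ds):
        markers = extract_ct_markers(static_ds.ct_render)
        assert len(markers) == len(static_ds.ct_marker_px)
        det = np.array([m.center_px for m in markers])
        d = np.linalg.norm(det[:, None] - static_ds.ct_marker_px[None], axis=2)
        assert np.all(d.min(axis=0) < 0.5)

    def test_blank_image_gives_empty_list(self):
        assert extract_ct_markers(np.zeros((128, 128), dtype=np.uint8)) == []

    def test_five_marker_scene_yields_five(self):
        ds = simulate_dataset(SceneSpec(seed=21, n_fiducials=5, duration_s=1.0))
        assert len(extract_ct_markers(ds.ct_render)) == 5

    def test_multichannel_input_rejected(self):
        with pytest.raises(ConfigError):
            extract_ct_markers(np.zeros((32, 32, 3)))


class TestRefineAndRegister:
    def test_exact_correspondences_fit_to_machine_precision(self, rng):
        H = Homography(np.array([[1.02, 0.01, 5.0], [-0.02, 0.98, -3.0],
                                 [1e-5, 0.0, 1.0]]))
        ct = rng.uniform(50, 350, (6, 2))
        res = refine_and_register(ct, H.apply(ct), frame=None, seed=0)
        assert res.rmse_px < 1e-3

    def test_window_refinement_beats_click_noise(self, registration_ds):
        cfg = PipelineConfig(seed=5, click_noise_px=3.0 / np.sqrt(3))
        res = register_dataset(registration_ds, cfg)
        assert res.rmse_px < 1.0

    def test_three_clicks_rejected(self, rng):
        pts = rng.uniform(0, 100, (3, 2))
        with pytest.raises(RegistrationError):
            refine_and_register(pts, pts)

    def test_mismatched_counts_rejected(self, rng):
        with pytest.raises(RegistrationError):
            refine_and_register(rng.uniform(0, 10, (6, 2)),
                                rng.uniform(0, 10, (5, 2)))

    def test_mask_contains_all_video_fiducials(self, registration_ds):
        res = register_dataset(registration_ds, PipelineConfig(seed=2))
        vid = np.array([m.center_px for m in res.correspondences[1]])
        assert res.mask.contains(vid).all()

    def test_warped_ct_markers_land_within_rmse_of_video_points(self, registration_ds):
        res = register_dataset(registration_ds, PipelineConfig(seed=2))
        ct = np.array([m.center_px for m in res.correspondences[0]])
        vid = np.array([m.center_px for m in res.correspondences[1]])
        d = np.linalg.norm(res.H_R.apply(ct) - vid, axis=1)
        assert np.sqrt(np.mean(d**2)) == pytest.approx(res.rmse_px, rel=1e-9)


class TestEllipseMask:
    def test_circle_recovers_scaled_radius(self):
        th = np.linspace(0, 2 * np.pi, 7)[:-1]
        pts = np.column_stack([50 + 30 * np.cos(th), 40 + 30 * np.sin(th)])
        mask = fit_ellipse_mask(pts, margin=0.1)
        assert np.allclose(mask.semi_axes_px, 33.0, rtol=0.01)
        assert np.allclose(mask.center_px, (50, 40), atol=0.3)

    def test_axis_aligned_ellipse_recovered(self):
        th = np.linspace(0, 2 * np.pi, 6)[:-1]
        pts = np.column_stack([100 + 60 * np.cos(th), 80 + 25 * np.sin(th)])
        mask = fit_ellipse_mask(pts, margin=0.0)
        assert np.allclose(sorted(mask.semi_axes_px), [25, 60], rtol=0.02)

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(4.0), 2 * np.arange(4.0)])
        with pytest.raises(EstimationError):
            fit_ellipse_mask(pts)

    def test_four_points_fall_back_to_circle(self):
        pts = np.array([[0.0, 0], [10, 0], [10, 10], [0, 10]])
        mask = fit_ellipse_mask(pts, margin=0.1)
        assert mask.semi_axes_px[0] == mask.semi_axes_px[1]
        assert mask.contains(pts).all()

    def test_homography_transform_is_exact_conic_image(self, rng):
        th = np.linspace(0, 2 * np.pi, 33)[:-1]
        pts = np.column_stack([200 + 80 * np.cos(th), 150 + 50 * np.sin(th)])
        mask = fit_ellipse_mask(pts, margin=0.0)
        H = Homography(np.array([[1.1, 0.08, 12.0], [-0.05, 0.95, -8.0],
                                 [2e-5, -1e-5, 1.0]]))
        moved = mask.transform(H)
        mapped_boundary = H.apply(mask.boundary_points(48))
        # mapped boundary points sit on the transformed ellipse
        assert moved.contains(mapped_boundary, margin=0.5).all()
        assert not moved.contains(mapped_boundary * 1.2).all()


class TestBlend:
    def test_beta_one_returns_microscope_image(self, rng):
        m = (rng.uniform(0, 255, (16, 16, 3))).astype(np.uint8)
        c = (rng.uniform(0, 255, (16, 16, 3))).astype(np.uint8)
        assert np.array_equal(blend(m, c, BlendConfig(beta=1.0)), m)

    def test_beta_zero_returns_ct_image(self, rng):
        m = (rng.uniform(0, 255, (16, 16))).astype(np.uint8)
        c = (rng.uniform(0, 255, (16, 16))).astype(np.uint8)
        assert np.array_equal(blend(m, c, BlendConfig(beta=0.0)), c)

    def test_half_blend_is_arithmetic_mean(self):
        m = np.full((4, 4), 100, dtype=np.uint8)
        c = np.full((4, 4), 200, dtype=np.uint8)
        assert np.all(blend(m, c, BlendConfig(beta=0.5)) == 150)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ConfigError):
            blend(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_invalid_beta_rejected(self):
        with pytest.raises(ConfigError):
            BlendConfig(beta=1.5)


class TestRegistrationError:
    def test_perfect_correspondences_give_zero(self, rng):
        ct = rng.uniform(0, 200, (5, 2))
        res = refine_and_register(ct, ct, frame=None, seed=0)
        assert registration_error_mm(res, 60.0) < 1e-9

    def test_pixel_to_mm_conversion(self):
        # a single 6 px offset at 60 px/mm is 0.1 mm
        assert 6.0 / 60.0 == pytest.approx(0.1)

    def test_matches_direct_formula(self, rng):
        H = Homography.translation(3.0, -2.0)
        ct = rng.uniform(0, 200, (6, 2))
        video = H.apply(ct) + rng.normal(0, 2.0, (6, 2))
        res = refine_and_register(ct, video, frame=None, seed=0)
        mapped = res.H_R.apply(ct)
        expected = np.sqrt(np.mean(np.sum((mapped - video) ** 2, axis=1))) / 60.0
        assert registration_error_mm(res, 60.0) == pytest.approx(expected, abs=1e-12)

    def test_px_per_mm_from_known_distances(self):
        pts = np.array([[0.0, 0.0], [120.0, 0.0], [0.0, 240.0]])
        scale = px_per_mm_from_distances(pts, {(0, 1): 2.0, (0, 2): 4.0})
        assert scale == pytest.approx(60.0)
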