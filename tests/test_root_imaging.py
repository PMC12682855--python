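"""Panorama stitching, SVD denoising, LoG segmentation and area extraction."""

import numpy as np
import pytest

from pindicator import (
    RootAreaSeries,
    ViewStack,
    clean_top_connected,
    fit_growth_spline,
    projected_area,
    render_root_scene,
    segment_roots,
    stitch_panorama,
    svd_denoise,
)
from pindicator.root_imaging import estimate_view_offsets


def _dice(a, b):
    return 2 * np.logical_and(a, b).sum() / (a.sum() + b.sum())


class TestStitchPanorama:
    def test_blank_views_concatenate_to_blank_panorama(self):
        views = [np.full((40, 60), 0.5)] * 6
        pano = stitch_panorama(views)
        assert pano.shape == (40, 360)  # zero estimated overlap
        assert np.ptp(pano) == 0

    def test_known_offsets_recovered_within_two_px(self):
        scene = render_root_scene(seed=3, noise_sigma=0.03)
        offsets = estimate_view_offsets(scene.stack.views)
        assert np.max(np.abs(offsets - scene.offsets)) <= 2

    def test_panorama_reconstructs_scene_content(self):
        scene = render_root_scene(seed=4, noise_sigma=0.0)
        pano = stitch_panorama(scene.stack)
        w = scene.image.shape[1]
        assert pano.shape[0] == scene.image.shape[0]
        # overlap-averaged panorama reproduces the underlying cylinder surface
        assert np.allclose(pano[:, :w], scene.image, atol=1e-12)

    def test_inconsistent_dimensions_rejected(self):
        views = [np.zeros((10, 20))] * 5 + [np.zeros((10, 21))]
        with pytest.raises(ValueError, match="dimensions"):
            stitch_panorama(views)

    def test_view_stack_requires_six_views(self):
        with pytest.raises(ValueError, match="six"):
            ViewStack(views=tuple(np.zeros((4, 4)) for _ in range(5)))


class TestSvdDenoise:
    def test_full_rank_is_identity(self, rng):
        img = rng.uniform(size=(30, 40))
        out = svd_denoise(img, rank=30)
        assert np.abs(out - img).max() <= 1e-9

    def test_exact_rank_one_input_recovered(self, rng):
        u = rng.uniform(0.2, 0.8, size=(25, 1))
        v = rng.uniform(0.2, 0.8, size=(1, 35))
        img = u @ v
        assert np.abs(svd_denoise(img, rank=1) - img).max() < 1e-12

    def test_denoising_beats_noisy_input_on_low_rank_scene(self, rng):
        u = rng.uniform(0.0, 1.0, size=(40, 5))
        v = rng.uniform(0.0, 1.0, size=(5, 50))
        clean = (u @ v) / 5.0
        noisy = np.clip(clean + rng.normal(scale=0.05, size=clean.shape), 0, 1)
        denoised = svd_denoise(noisy, rank=5)
        rmse = lambda a: np.sqrt(np.mean((a - clean) ** 2))
        assert rmse(denoised) < rmse(noisy)

    def test_error_nonincreasing_in_rank(self, rng):
        img = rng.uniform(size=(20, 30))
        errors = [np.linalg.norm(img - svd_denoise(img, r)) for r in range(1, 21)]
        assert all(e2 <= e1 + 1e-9 for e1, e2 in zip(errors, errors[1:]))

    def test_invalid_rank_rejected(self, rng):
        img = rng.uniform(size=(10, 10))
        with pytest.raises(ValueError):
            svd_denoise(img, 0)
        with pytest.raises(ValueError):
            svd_denoise(img, 11)


class TestSegmentRoots:
    def test_blank_image_gives_empty_mask(self):
        assert not segment_roots(np.full((50, 50), 0.7)).any()

    def test_rendered_skeleton_dice_overlap(self):
        scene = render_root_scene(seed=6, stroke_width=3, noise_sigma=0.02)
        mask = segment_roots(scene.image, sigma=1.5)
        assert _dice(mask, scene.mask) >= 0.8

    def test_polarity_flag_gives_identical_mask(self):
        scene = render_root_scene(seed=7, stroke_width=3, noise_sigma=0.0)
        dark = segment_roots(scene.image, sigma=1.5, dark_roots=True)
        bright = segment_roots(1.0 - scene.image, sigma=1.5, dark_roots=False)
        assert np.array_equal(dark, bright)

    def test_nonfinite_pixels_rejected(self):
        img = np.full((10, 10), 0.5)
        img[3, 3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            segment_roots(img)


class TestCleanTopConnected:
    def test_component_touching_top_row_is_kept(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[0:15, 8:11] = True
        assert np.array_equal(clean_top_connected(mask), mask)

    def test_floating_speck_removed(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[0:30, 18:21] = True        # root from the top
        mask[35:37, 2:4] = True         # far-away speck
        cleaned = clean_top_connected(mask)
        assert cleaned[:30, 18:21].all()
        assert not cleaned[35:, :].any()

    def test_output_is_subset_of_input(self, rng):
        mask = rng.uniform(size=(60, 60)) > 0.7
        cleaned = clean_top_connected(mask)
        assert not np.any(cleaned & ~mask)

    def test_empty_mask_allowed(self):
        assert not clean_top_connected(np.zeros((5, 5), dtype=bool)).any()

    def test_scene_with_noise_blobs_recovers_area(self):
        scene = render_root_scene(seed=8, stroke_width=3, noise_sigma=0.0)
        mask = scene.mask.copy()
        rng = np.random.default_rng(8)
        for _ in range(20):  # scattered artefact blobs away from the top
            r = rng.integers(150, 230)
            c = rng.integers(0, 470)
            mask[r:r + 3, c:c + 3] = True
        cleaned = clean_top_connected(mask)
        assert abs(cleaned.sum() - scene.area_px) / scene.area_px <= 0.05


class TestProjectedArea:
    @pytest.mark.parametrize(
        "n_white, coeff, expected",
        [(100, 0.0042, 0.001764), (0, 0.0042, 0.0), (100, 1.0, 100.0)],
    )
    def test_conversion_arithmetic(self, n_white, coeff, expected):
        mask = np.zeros((10, 10), dtype=bool)
        mask.ravel()[:n_white] = True
        count, area = projected_area(mask, coeff)
        assert count == n_white
        assert area == pytest.approx(expected)

    def test_nonpositive_coeff_rejected(self):
        with pytest.raises(ValueError):
            projected_area(np.ones((2, 2), dtype=bool), 0.0)


class TestGrowthSpline:
    def test_exact_cubic_reproduced(self):
        t = np.linspace(0.0, 10.0, 12)
        y = 2 + 3 * t - 0.5 * t**2 + 0.1 * t**3
        fit = fit_growth_spline(RootAreaSeries("t", t, y), df=8)
        assert np.abs(fit(t) - y).max() <= 1e-8

    def test_derivative_of_cubic(self):
        t = np.linspace(0.0, 10.0, 12)
        y = t**3
        fit = fit_growth_spline(RootAreaSeries("t", t, y), df=8)
        assert fit.derivative(5.0) == pytest.approx(75.0, rel=1e-6)

    def test_monotone_logistic_fit_essentially_nondecreasing_without_noise(self):
        # unconstrained LSQ splines wiggle by a fraction of a percent at the
        # plateau; monotonicity is asserted up to 0.1 % of the asymptote
        t = np.arange(7.0, 97.0, 7.0)
        y = 30000 / (1 + np.exp(-0.12 * (t - 45)))
        fit = fit_growth_spline(RootAreaSeries("t", t, y), df=8)
        grid = np.linspace(t[0], t[-1], 200)
        assert (np.diff(fit(grid)) >= -1e-3 * y.max()).all()
        assert fit(t[-1]) > 0.9 * y.max() > 10 * fit(t[0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_growth_spline(RootAreaSeries("t", [0.0, 1.0], [0.0, 1.0]), df=4)


class TestFullPipeline:
    @pytest.mark.parametrize("stroke, sigma", [(3, 1.6), (5, 3.0)])
    @pytest.mark.parametrize("noise", [0.02, 0.05])
    def test_area_recovered_within_ten_percent(self, stroke, sigma, noise):
        for seed in (0, 1, 2):
            scene = render_root_scene(seed=seed, stroke_width=stroke,
                                      noise_sigma=noise)
            mask = clean_top_connected(segment_roots(scene.image, sigma=sigma))
            count, _ = projected_area(mask)
            assert abs(count - scene.area_px) / scene.area_px <= 0.10
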