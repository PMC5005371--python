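"""Image-processing chain: emissivity, sharpening, thresholding, edges,
segmentation and daily aggregation."""

import numpy as np
import pytest
from scipy import ndimage

from pinetherm.imaging import (
    SegmentationConfig,
    ThermalImage,
    aggregate_daily,
    correct_emissivity,
    detect_edges,
    estimate_emissivity,
    intermodes_threshold,
    segment_scene,
    unsharp_mask,
)
from pinetherm.synthetic import SceneParams, default_region_layout, generate_thermal_scene

UNIT_EPS = SegmentationConfig(emissivities={"canopy": 1.0, "wet": 1.0, "dry": 1.0})


def intermodes_oracle(values, bins=256):
    """Brute-force intermodes: exact integer smoothing, coded independently.

    Smooths the unnormalized histogram with (1, 2, 1) using Python integers
    until two plateau-aware local maxima remain, then returns the midpoint
    of the mode bin centers.
    """
    values = np.asarray(values, float).ravel()
    hist, edges = np.histogram(values, bins=bins, range=(values.min(), values.max()))
    centers = (edges[:-1] + edges[1:]) / 2.0
    h = [int(c) for c in hist]

    def maxima(hh):
        out, i = [], 0
        while i < len(hh):
            j = i
            while j + 1 < len(hh) and hh[j + 1] == hh[i]:
                j += 1
            lo = hh[i - 1] if i else -1
            hi = hh[j + 1] if j + 1 < len(hh) else -1
            if hh[i] > lo and hh[i] > hi and hh[i] > 0:
                out.append((i + j) // 2)
            i = j + 1
        return out

    def step(hh):
        padded = [0] + hh + [0]
        return [padded[i] + 2 * padded[i + 1] + padded[i + 2] for i in range(len(hh))]

    for _ in range(10_000):
        m = maxima(h)
        if len(m) < 2:
            raise ValueError("oracle: not bimodal")
        if len(m) == 2:
            probe = h
            if all(len(maxima(probe := step(probe))) == 2 for _ in range(50)):
                return (centers[m[0]] + centers[m[1]]) / 2.0
        h = step(h)
    raise ValueError("oracle: not bimodal")


class TestEmissivity:
    def test_identity_when_temperatures_agree(self):
        assert estimate_emissivity(30.0, 30.0) == pytest.approx(1.0)

    def test_kelvin_quotient_hand_value(self):
        # 303.15 / 306.15
        assert estimate_emissivity(30.0, 33.0) == pytest.approx(0.9902, abs=1e-4)

    def test_domain_violations(self):
        with pytest.raises(ValueError):
            estimate_emissivity(np.nan, 30.0)
        with pytest.raises(ValueError):
            estimate_emissivity(-300.0, 30.0)

    def test_suspect_values_flagged(self):
        with pytest.warns(UserWarning, match="suspect"):
            estimate_emissivity(30.0, 800.0)

    def test_correction_identity_and_hand_value(self):
        assert correct_emissivity(30.0, 1.0) == pytest.approx(30.0)
        # inverse of the kelvin-quotient calibration: 306.15 * 0.990201 - 273.15
        eps = 303.15 / 306.15
        assert correct_emissivity(33.0, eps) == pytest.approx(30.0, abs=1e-9)

    def test_round_trip_with_estimate(self):
        t_contact, t_image = 28.3, 31.9
        eps = estimate_emissivity(t_contact, t_image)
        assert correct_emissivity(t_image, eps) == pytest.approx(t_contact, abs=1e-9)

    def test_monotone_in_apparent_temperature(self):
        assert correct_emissivity(31.0, 0.9) > correct_emissivity(30.0, 0.9)

    def test_nonpositive_emissivity_rejected(self):
        with pytest.raises(ValueError):
            correct_emissivity(30.0, 0.0)


class TestUnsharpMask:
    def test_constant_image_unchanged(self):
        img = np.full((40, 40), 31.5)
        assert np.allclose(unsharp_mask(img), img)

    def test_hot_pixel_amplified(self):
        img = np.zeros((41, 41))
        img[20, 20] = 1.0
        assert unsharp_mask(img)[20, 20] > 1.0

    def test_step_edge_matches_direct_convolution_oracle(self):
        rng = np.random.default_rng(5)
        img = np.where(np.arange(64)[None, :] < 32, 25.0, 40.0) + rng.normal(
            0, 0.01, (64, 64)
        )
        w, sigma = 0.9, 2.0
        # independent oracle: separable gaussian built from the closed form,
        # applied with explicit reflective padding
        radius = int(4 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        k = np.exp(-0.5 * (x / sigma) ** 2)
        k /= k.sum()
        pad = np.pad(img, radius, mode="symmetric")
        blur = np.apply_along_axis(lambda r: np.convolve(r, k, "valid"), 1, pad)
        blur = np.apply_along_axis(lambda c: np.convolve(c, k, "valid"), 0, blur)
        expect = (img - w * blur) / (1 - w)
        got = unsharp_mask(img, radius=sigma, weight=w)
        assert np.allclose(got, expect, atol=1e-8)

    def test_step_overshoot_symmetric(self):
        img = np.where(np.arange(64)[None, :] < 32, 0.0, 1.0).repeat(64, axis=0).reshape(64, 64)
        sharp = unsharp_mask(img)
        overshoot = sharp.max() - 1.0
        undershoot = -sharp.min()
        assert overshoot > 0.05
        assert overshoot == pytest.approx(undershoot, rel=1e-9)

    def test_invalid_weight_rejected(self):
        with pytest.raises(ValueError):
            unsharp_mask(np.zeros((8, 8)), weight=1.0)


class TestIntermodes:
    def test_symmetric_delta_peaks_give_midpoint(self):
        vals = np.concatenate([np.full(500, 20.0), np.full(300, 40.0)])
        assert intermodes_threshold(vals) == pytest.approx(30.0)

    def test_agrees_exactly_with_bruteforce_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            mu1 = rng.uniform(20, 30)
            mu2 = mu1 + rng.uniform(6, 15)
            n1, n2 = rng.integers(2000, 8000, 2)
            vals = np.concatenate(
                [rng.normal(mu1, rng.uniform(0.5, 1.5), n1),
                 rng.normal(mu2, rng.uniform(0.3, 1.0), n2)]
            )
            assert intermodes_threshold(vals) == intermodes_oracle(vals)

    def test_gaussian_mixture_close_to_valley(self):
        rng = np.random.default_rng(3)
        vals = np.concatenate([rng.normal(28, 1, 7000), rng.normal(40, 0.5, 3000)])
        thr = intermodes_threshold(vals)
        assert 30 < thr < 38

    def test_single_mode_raises(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError, match="not bimodal"):
            intermodes_threshold(rng.normal(30, 1, 5000))

    def test_constant_input_raises(self):
        with pytest.raises(ValueError, match="constant"):
            intermodes_threshold(np.full(100, 30.0))


class TestDetectEdges:
    def test_constant_image_gives_zero(self):
        assert np.all(detect_edges(np.full((16, 16), 35.0)) == 0)

    def test_vertical_unit_step_magnitude_four(self):
        img = np.where(np.arange(16)[None, :] < 8, 0.0, 1.0).repeat(16, 0).reshape(16, 16)
        mag = detect_edges(img)
        # standard Sobel response to a unit step peaks at 4 beside the step
        assert mag[8, 7] == pytest.approx(4.0)
        assert mag[8, 8] == pytest.approx(4.0)

    def test_rotation_commutes_with_magnitude(self):
        rng = np.random.default_rng(2)
        img = rng.normal(30, 1, (32, 32))
        assert np.allclose(detect_edges(np.rot90(img)), np.rot90(detect_edges(img)))

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            detect_edges(np.zeros((2, 5)))


class TestSegmentScene:
    def test_exact_recovery_on_clean_scene(self, clean_scene):
        scene, layout = clean_scene
        res = segment_scene(ThermalImage(scene.grid), UNIT_EPS, layout)
        assert res.median_temps["canopy"] == pytest.approx(scene.true_temps["canopy"])
        assert res.median_temps["wet"] == pytest.approx(scene.true_temps["wet"])
        assert res.median_temps["dry"] == pytest.approx(scene.true_temps["dry"])

    def test_noisy_scene_recovery_within_two_tenths(self, noisy_scene):
        scene, layout = noisy_scene
        res = segment_scene(ThermalImage(scene.grid), UNIT_EPS, layout)
        assert abs(res.median_temps["canopy"] - scene.true_temps["canopy"]) < 0.2

    def test_masks_disjoint_and_medians_from_original_raster(self, noisy_scene):
        scene, layout = noisy_scene
        res = segment_scene(ThermalImage(scene.grid), UNIT_EPS, layout)
        overlap = (
            res.canopy_mask.astype(int) + res.wet_mask + res.dry_mask + res.background_mask
        )
        assert np.all(overlap == 1)
    def test_medians_from_original_raster_under_extreme_sharpening(self, clean_scene):
        # medians must be read from the original raster: an extreme
        # sharpening weight distorts the sharpened values massively but
        # leaves the reported canopy median exactly at the truth on a
        # noise-free scene
        scene, layout = clean_scene
        extreme = SegmentationConfig(
            unsharp_weight=0.98, emissivities={"canopy": 1.0, "wet": 1.0, "dry": 1.0}
        )
        res = segment_scene(ThermalImage(scene.grid), extreme, layout)
        assert res.median_temps["canopy"] == pytest.approx(
            scene.true_temps["canopy"], abs=1e-9
        )

    def test_canopy_median_below_threshold_on_mask_scale(self, noisy_scene):
        scene, layout = noisy_scene
        res = segment_scene(ThermalImage(scene.grid), UNIT_EPS, layout)
        sharp = np.clip(
            unsharp_mask(scene.grid), scene.grid.min(), scene.grid.max()
        )
        assert np.median(sharp[res.canopy_mask]) < res.threshold_used

    def test_emissivity_correction_applied_per_region(self, clean_scene):
        scene, layout = clean_scene
        res = segment_scene(ThermalImage(scene.grid), SegmentationConfig(), layout)
        # pine emissivity 0.90 raises the 30 degC canopy reading
        assert res.median_temps["canopy"] == pytest.approx(
            correct_emissivity(30.0, 0.90), abs=1e-6
        )

    def test_no_contrast_scene_propagates_not_bimodal(self):
        rng = np.random.default_rng(0)
        grid = np.full((128, 128), 40.0) + rng.normal(0, 0.05, (128, 128))
        layout = {"wet": (8, 8, 30, 40), "dry": (8, 88, 30, 120)}
        with pytest.raises(ValueError, match="not bimodal"):
            segment_scene(ThermalImage(grid), UNIT_EPS, layout)

    def test_reference_rectangle_outside_image_rejected(self, noisy_scene):
        scene, _ = noisy_scene
        with pytest.raises(ValueError, match="outside"):
            segment_scene(
                ThermalImage(scene.grid), UNIT_EPS,
                {"wet": (0, 0, 10, 10), "dry": (0, 500, 10, 600)},
            )

    def test_edge_removal_reduces_error_under_mixing(self):
        # paired over seeds: mean |error| strictly smaller with edge removal
        errs, errs_no = [], []
        for seed in range(15):
            params = SceneParams(noise_sd=0.08, edge_mix_fraction=0.3, seed=seed)
            scene = generate_thermal_scene(params)
            layout = default_region_layout(params)
            img = ThermalImage(scene.grid)
            res = segment_scene(img, UNIT_EPS, layout)
            res_no = segment_scene(img, UNIT_EPS, layout, remove_edges=False)
            errs.append(abs(res.median_temps["canopy"] - 30.0))
            errs_no.append(abs(res_no.median_temps["canopy"] - 30.0))
        assert np.mean(errs) < np.mean(errs_no)


class TestAggregateDaily:
    def _result(self, med):
        from pinetherm.imaging import SegmentationResult

        m = np.ones((4, 4), bool)
        return SegmentationResult(m, m, m, m, {"canopy": med, "wet": 20.0, "dry": 38.0},
                                  30.0, {"canopy": 16, "wet": 16, "dry": 16})

    def test_single_replicate_identity(self):
        out = aggregate_daily([self._result(29.0)])
        assert out["canopy"] == 29.0 and out["n_replicates"] == 1

    def test_mean_of_three_replicates(self):
        out = aggregate_daily([self._result(29.0), self._result(30.0), self._result(31.0)])
        assert out["canopy"] == pytest.approx(30.0)

    def test_failed_replicates_skipped_then_all_failed_raises(self):
        with pytest.warns(UserWarning, match="skipped"):
            out = aggregate_daily([None, self._result(30.0)])
        assert out["n_replicates"] == 1
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning, match="skipped"):
                aggregate_daily([None, None])

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            aggregate_daily([])
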