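"""Tests for ACA focus detection, ring quantification and normalization."""

import numpy as np
import pytest

from cpcquant.centromere import (
    CellMeasurement,
    DetectionConfig,
    detect_foci,
    estimate_background_mask,
    measure_ring,
    normalize_condition,
    recruitment_ratio,
)
from cpcquant.synthetic import ImageScene, SpotTruth, generate_cell_image


def _scene_with_spots(centroids_um, amps=None, noise=2.0, size=128, seed=0,
                      sigma=0.13, background=100.0, channels=("ACA", "marker")):
    amps = amps or {"ACA": 1000.0, "marker": 500.0}
    spots = [SpotTruth(centroid_um=c, sigma_um=sigma, amplitude=dict(amps))
             for c in centroids_um]
    scene = ImageScene(width_px=size, height_px=size, channels=channels,
                       spots=spots, background_level=background,
                       gaussian_sd=noise, seed=seed)
    return generate_cell_image(scene), scene


class TestDetectFoci:
    def test_noise_only_image_has_no_foci(self, rng):
        img = rng.normal(100.0, 2.0, size=(96, 96))
        assert detect_foci(img) == []

    def test_uniform_image_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="uniform"):
            assert detect_foci(np.full((32, 32), 4095.0)) == []

    def test_single_spot_subpixel_centroid(self):
        (images, truth), scene = _scene_with_spots([(3.3, 4.1)], noise=0.0)
        foci = detect_foci(images["ACA"])
        assert len(foci) == 1
        cx, cy = foci[0].centroid_px
        assert abs(cx - truth["x_px"][0]) < 0.5
        assert abs(cy - truth["y_px"][0]) < 0.5

    def test_recall_precision_on_46_spot_field(self, rng):
        """23 centromere pairs at SNR ~10: recall and precision >= 0.95
        against the truth table at a 3-px matching radius."""
        size, px = 256, 0.0645
        pts = []
        while len(pts) < 46:
            cand = rng.uniform(1.5, size * px - 1.5, size=2)
            if all(np.hypot(*(cand - p)) > 0.8 for p in pts):
                pts.append(cand)
        (images, truth), scene = _scene_with_spots(
            [tuple(p) for p in pts], noise=5.0, size=size, seed=1,
            amps={"ACA": 500.0, "marker": 300.0},
        )
        foci = detect_foci(images["ACA"])
        det = np.array([f.centroid_px for f in foci])
        tru = truth[["x_px", "y_px"]].to_numpy()
        matched = set()
        hits = 0
        for d in det:
            dist = np.hypot(*(tru - d).T)
            j = int(np.argmin(dist))
            if dist[j] <= 3.0 and j not in matched:
                matched.add(j)
                hits += 1
        recall = hits / len(tru)
        precision = hits / max(len(det), 1)
        assert recall >= 0.95
        assert precision >= 0.95


class TestMeasureRing:
    def test_uniform_marker_with_zero_background(self):
        (images, _), _ = _scene_with_spots([(3.0, 3.0)], noise=0.0)
        focus = detect_foci(images["ACA"])[0]
        marker = np.full_like(images["ACA"], 7.0)
        bg = np.zeros_like(marker, dtype=bool)
        bg[:5, :5] = True
        marker[bg] = 0.0
        m = measure_ring(marker, focus, background_region=bg)
        assert m.corrected == pytest.approx(7.0)

    def test_constant_offset_cancels(self):
        """corrected is independent of an additive offset, against a
        brute-force pixel-sum oracle."""
        (images, _), _ = _scene_with_spots([(3.0, 3.0)], noise=0.0)
        focus = detect_foci(images["ACA"])[0]
        bg = np.zeros_like(images["marker"], dtype=bool)
        bg[:8, :8] = True
        base = measure_ring(images["marker"], focus, background_region=bg)
        shifted = measure_ring(images["marker"] + 37.5, focus, background_region=bg)
        assert shifted.corrected == pytest.approx(base.corrected, abs=1e-9)
        # oracle: explicit ring pixel sum
        from scipy.ndimage import binary_dilation
        from skimage.morphology import disk

        ring = binary_dilation(focus.mask, structure=disk(3)) & ~focus.mask
        oracle = images["marker"][ring].mean() - images["marker"][bg].mean()
        assert base.corrected == pytest.approx(oracle)

    def test_ring_disjoint_from_mask_and_nonempty(self):
        (images, _), _ = _scene_with_spots([(3.0, 3.0)], noise=0.0)
        focus = detect_foci(images["ACA"])[0]
        m = measure_ring(images["marker"], focus)
        assert m.n_ring_px > 0

    def test_border_ring_flagged(self):
        (images, _), _ = _scene_with_spots([(0.3, 0.3)], noise=0.0, size=64)
        foci = detect_foci(images["ACA"], DetectionConfig(min_area_px=2))
        assert foci, "corner spot should still be detectable"
        m = measure_ring(images["marker"], foci[0])
        assert "ring_clipped_by_border" in m.flags

    def test_translation_invariance(self):
        (images, _), scene = _scene_with_spots([(3.0, 3.0)], noise=0.0)
        focus = detect_foci(images["ACA"])[0]
        bg = np.zeros_like(images["marker"], dtype=bool)
        bg[:8, :8] = True
        a = measure_ring(images["marker"], focus, background_region=bg)
        shift = 5
        rolled = np.roll(np.roll(images["marker"], shift, axis=0), shift, axis=1)
        focus_shift = type(focus)(
            centroid_px=(focus.centroid_px[0] + shift, focus.centroid_px[1] + shift),
            mask=np.roll(np.roll(focus.mask, shift, axis=0), shift, axis=1),
            area_px=focus.area_px,
        )
        b = measure_ring(rolled, focus_shift, background_region=np.roll(
            np.roll(bg, shift, axis=0), shift, axis=1))
        assert b.corrected == pytest.approx(a.corrected, abs=1e-9)

    def test_linearity_in_gain(self):
        (images, _), _ = _scene_with_spots([(3.0, 3.0)], noise=0.0)
        focus = detect_foci(images["ACA"])[0]
        bg = np.zeros_like(images["marker"], dtype=bool)
        bg[:8, :8] = True
        a = measure_ring(images["marker"], focus, background_region=bg)
        b = measure_ring(images["marker"] * 2.5, focus, background_region=bg)
        assert b.corrected == pytest.approx(2.5 * a.corrected, rel=1e-12)


class TestNormalize:
    def _measurements(self, values, condition):
        return [
            CellMeasurement(cell_id=f"{condition}_{i}", condition=condition,
                            ring_mean=v, background_mean=0.0, corrected=v)
            for i, v in enumerate(values)
        ]

    def test_reference_mean_maps_to_one(self):
        ms = self._measurements([2.0, 4.0, 6.0], "rescue")
        normalize_condition(ms, "rescue")
        assert np.mean([m.normalized for m in ms]) == pytest.approx(1.0)

    def test_two_groups_preserve_ratio(self):
        ms = self._measurements([2.0, 2.0], "rescue") + self._measurements(
            [1.0, 1.0], "knockdown"
        )
        normalize_condition(ms, "rescue")
        by = {}
        for m in ms:
            by.setdefault(m.condition, []).append(m.normalized)
        assert np.mean(by["rescue"]) == pytest.approx(1.0)
        assert np.mean(by["knockdown"]) == pytest.approx(0.5)

    def test_negative_corrected_excluded_from_reference_mean(self):
        ms = self._measurements([2.0, 2.0], "rescue")
        bad = CellMeasurement("x", "rescue", -1.0, 0.0, -1.0,
                              flags=["negative_corrected"])
        normalize_condition(ms + [bad], "rescue")
        assert ms[0].normalized == pytest.approx(1.0)

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            normalize_condition(self._measurements([1.0], "a"), "b")


class TestRecruitmentRatio:
    def test_identical_channels_give_one(self):
        (images, _), _ = _scene_with_spots(
            [(3.0, 3.0)], amps={"ACA": 1000.0, "marker": 400.0}, noise=0.0
        )
        focus = detect_foci(images["ACA"])[0]
        bg = np.zeros_like(images["marker"], dtype=bool)
        bg[:8, :8] = True
        r = recruitment_ratio(images["marker"], images["marker"], focus, bg, bg)
        assert r == pytest.approx(1.0)

    def test_zero_target_gives_zero(self):
        (images, _), _ = _scene_with_spots([(3.0, 3.0)], noise=0.0)
        focus = detect_foci(images["ACA"])[0]
        bg = np.zeros_like(images["marker"], dtype=bool)
        bg[:8, :8] = True
        flat = np.full_like(images["marker"], 50.0)
        assert recruitment_ratio(flat, images["marker"], focus, bg, bg) == pytest.approx(0.0)

    def test_twofold_target_recovers_ratio_two(self):
        (images, _), _ = _scene_with_spots(
            [(3.0, 3.0)], amps={"ACA": 1000.0, "marker": 800.0, "GFP": 400.0},
            noise=0.0, channels=("ACA", "marker", "GFP"),
        )
        focus = detect_foci(images["ACA"])[0]
        bg = np.zeros_like(images["marker"], dtype=bool)
        bg[:8, :8] = True
        r = recruitment_ratio(images["marker"], images["GFP"], focus, bg, bg)
        assert r == pytest.approx(2.0, rel=0.05)

    def test_nonpositive_gfp_rejected(self):
        (images, _), _ = _scene_with_spots([(3.0, 3.0)], noise=0.0)
        focus = detect_foci(images["ACA"])[0]
        bg = np.zeros_like(images["marker"], dtype=bool)
        bg[:8, :8] = True
        flat = np.full_like(images["marker"], 50.0)
        with pytest.raises(ValueError, match="GFP"):
            recruitment_ratio(images["marker"], flat, focus, bg, bg)


def test_background_mask_finds_mode_region(rng):
    img = np.full((64, 64), 40.0) + rng.normal(0, 0.1, size=(64, 64))
    img[:10, :10] = 500.0
    mask = estimate_background_mask(img)
    assert img[mask].mean() == pytest.approx(40.0, abs=1.0)
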