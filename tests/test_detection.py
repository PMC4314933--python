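"""Sobel gradient, thresholding, morphology pipeline and background estimation."""

import numpy as np
import pytest

import afmetrics as am
from afmetrics.detection import SOBEL_COL, SOBEL_ROW, edge_pixels
from afmetrics.errors import NoParticleError, ParameterError


def brute_force_sobel(h):
    """Index-wise 3x3 kernel correlation with edge replication (the oracle)."""
    rows, cols = h.shape
    padded = np.pad(h, 1, mode="edge")
    gx = np.zeros_like(h, dtype=float)
    gy = np.zeros_like(h, dtype=float)
    for r in range(rows):
        for c in range(cols):
            for dr in range(3):
                for dc in range(3):
                    gx[r, c] += SOBEL_COL[dr, dc] * padded[r + dr, c + dc]
                    gy[r, c] += SOBEL_ROW[dr, dc] * padded[r + dr, c + dc]
    return np.sqrt(gx**2 + gy**2)


class TestSobel:
    def test_constant_image_zero_gradient(self, flat_map):
        assert np.all(am.sobel_magnitude(flat_map) == 0.0)

    def test_vertical_step_peaks_on_step(self):
        h = np.zeros((10, 10))
        h[:, 5:] = 3.0
        g = am.sobel_magnitude(am.HeightMap(h, 1.0, 1.0))
        assert np.all(g[:, 4] > 0) and np.all(g[:, 5] > 0)
        assert np.all(g[:, 0] == 0) and np.all(g[:, 9] == 0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            h = rng.normal(size=(5, 5))
            g = am.sobel_magnitude(am.HeightMap(h, 1.0, 1.0))
            np.testing.assert_allclose(g, brute_force_sobel(h), atol=1e-12)


class TestDetectParticles:
    def test_blob_detected_as_single_filled_component(self, blob_map):
        hmap, _ = blob_map
        pmask = am.detect_particles(hmap, 1.0)
        labeled, selected = am.label_and_select_largest(pmask)
        assert labeled.n_particles == 1
        apex = np.unravel_index(np.argmax(hmap.heights), hmap.shape)
        assert pmask.mask[apex]

    def test_huge_factor_gives_empty_mask(self, blob_map):
        hmap, _ = blob_map
        assert not am.detect_particles(hmap, 1000.0).mask.any()

    def test_border_touching_blob_suppressed(self):
        r = np.arange(48)[:, None]
        c = np.arange(48)[None, :]
        h = 3.0 * np.exp(-((r - 2) ** 2 + (c - 24) ** 2) / (2 * 3.0**2))
        pmask = am.detect_particles(am.HeightMap(h, 1.0, 1.0), 1.0)
        assert not pmask.mask.any()

    def test_mask_shape_and_no_border_pixels(self, blob_map):
        hmap, _ = blob_map
        pmask = am.detect_particles(hmap, 0.5)
        assert pmask.mask.shape == hmap.shape
        border = np.concatenate(
            [pmask.mask[0], pmask.mask[-1], pmask.mask[:, 0], pmask.mask[:, -1]]
        )
        assert not border.any()

    def test_invalid_factor(self, blob_map):
        hmap, _ = blob_map
        with pytest.raises(ParameterError):
            am.detect_particles(hmap, 0.0)

    @pytest.mark.parametrize("f_low,f_high", [(0.5, 1.0), (1.0, 2.0), (0.2, 5.0)])
    def test_raw_threshold_monotonicity(self, blob_map, f_low, f_high):
        """Raising the factor can only shrink the raw edge-pixel set."""
        hmap, _ = blob_map
        low = edge_pixels(hmap, f_low)
        high = edge_pixels(hmap, f_high)
        assert not np.any(high & ~low)


class TestBackground:
    def test_flat_image_empty_mask(self, flat_map):
        pmask = am.ParticleMask(np.zeros(flat_map.shape, bool), 1.0, 0.0)
        assert am.estimate_background(flat_map, pmask) == pytest.approx(1.0)

    def test_particle_excluded(self, blob_map):
        hmap, _ = blob_map
        pmask = am.ParticleMask(hmap.heights > 0.01, 1.0, 0.0)
        assert am.estimate_background(hmap, pmask) == pytest.approx(0.0, abs=0.02)

    def test_checkerboard_exclusion(self):
        h = np.indices((8, 8)).sum(axis=0) % 2 * 2.0
        hmap = am.HeightMap(h, 1.0, 1.0)
        pmask = am.ParticleMask(h == 2.0, 1.0, 0.0)
        assert am.estimate_background(hmap, pmask) == pytest.approx(0.0)

    def test_all_foreground_error(self, flat_map):
        pmask = am.ParticleMask(np.ones(flat_map.shape, bool), 1.0, 0.0)
        with pytest.raises(NoParticleError):
            am.estimate_background(flat_map, pmask)


class TestLabelAndSelect:
    def _mask_with_blobs(self, areas):
        mask = np.zeros((40, 40), bool)
        col = 2
        for i, a in enumerate(areas):
            side = int(np.sqrt(a))
            mask[2 + 10 * i:2 + 10 * i + side, col:col + side] = True
        return am.ParticleMask(mask, 1.0, 0.0)

    def test_largest_selected(self):
        pmask = self._mask_with_blobs([30, 70])
        labeled, selected = am.label_and_select_largest(pmask)
        assert labeled.n_particles == 2
        assert labeled.areas_px[selected - 1] == labeled.areas_px.max()

    def test_tie_broken_to_first_in_scan_order(self):
        pmask = self._mask_with_blobs([36, 36])
        _, selected = am.label_and_select_largest(pmask)
        assert selected == 1

    def test_empty_mask_error(self, flat_map):
        pmask = am.ParticleMask(np.zeros(flat_map.shape, bool), 1.0, 0.0)
        with pytest.raises(NoParticleError):
            am.label_and_select_largest(pmask)


class TestIntensityThreshold:
    def test_fraction_of_max(self, blob_map):
        hmap, _ = blob_map
        pmask = am.intensity_threshold_mask(hmap, 0.2)
        level = 0.2 * hmap.heights.max()
        np.testing.assert_array_equal(pmask.mask, hmap.heights >= level)

    def test_uniform_image_full_mask(self, flat_map):
        assert am.intensity_threshold_mask(flat_map, 0.5).mask.all()

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 2.0])
    def test_fraction_domain(self, flat_map, bad):
        with pytest.raises(ParameterError):
            am.intensity_threshold_mask(flat_map, bad)


def test_gradient_detection_robust_to_plane_tilt():
    """With a 20%-of-height tilt, the gradient mask moves less than the
    intensity mask (measured as IoU against the untilted mask)."""
    hmap, truth = am.make_blob((96, 96), (47.5, 47.5), sigma_px=4.0, amplitude_nm=3.0)
    tilt = am.add_plane(hmap, 0.0, 0.2 * truth.amplitude_nm / hmap.shape[1])

    grad_flat = am.detect_particles(hmap, 1.0).mask
    grad_tilt = am.detect_particles(tilt, 1.0).mask
    int_flat = am.intensity_threshold_mask(hmap, 0.15).mask
    int_tilt = am.intensity_threshold_mask(tilt, 0.15).mask

    assert am.mask_iou(grad_tilt, grad_flat) > am.mask_iou(int_tilt, int_flat)
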