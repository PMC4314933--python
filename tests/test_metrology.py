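"""Volume, path, profile, skeleton and angle measurements against oracles."""

import math

import numpy as np
import pytest

import afmetrics as am
from afmetrics.errors import BoundsError, ParameterError
from afmetrics.metrology import GAUSSIAN_FWHM_FACTOR


def labeled_from_bool(mask):
    return am.LabeledParticles(
        labels=mask.astype(int),
        n_particles=1,
        areas_px=np.array([int(mask.sum())]),
    )


class TestVolume:
    def test_flat_top_particle_arithmetic(self):
        h = np.zeros((8, 8))
        h[2:4, 2:7] = 2.0          # 10 pixels of 2 nm
        hmap = am.HeightMap(h, 1.0, 1.0)
        mask = h > 0
        vol = am.particle_volume(hmap, labeled_from_bool(mask), 1, 0.0)
        assert vol.volume_nm3 == pytest.approx(20.0)
        assert vol.n_pixels == 10

    def test_gaussian_blob_matches_continuum_integral(self, blob_map):
        """Discrete sum over a >=4 sigma mask converges to 2 pi sigma^2 A."""
        hmap, truth = blob_map
        r = np.arange(64)[:, None]
        c = np.arange(64)[None, :]
        mask = (r - 31.5) ** 2 + (c - 31.5) ** 2 <= (4 * truth.sigma_px) ** 2
        vol = am.particle_volume(hmap, labeled_from_bool(mask), 1, 0.0)
        assert vol.volume_nm3 == pytest.approx(truth.analytic_volume_nm3, rel=0.01)

    def test_background_equal_to_height_gives_zero(self):
        h = np.full((8, 8), 1.5)
        hmap = am.HeightMap(h, 1.0, 1.0)
        mask = np.zeros((8, 8), bool)
        mask[3:5, 3:5] = True
        vol = am.particle_volume(hmap, labeled_from_bool(mask), 1, 1.5)
        assert vol.volume_nm3 == pytest.approx(0.0)

    def test_invariant_to_constant_height_shift(self, blob_map):
        hmap, _ = blob_map
        pmask = am.detect_particles(hmap, 0.5)
        labeled, sel = am.label_and_select_largest(pmask)
        bg1 = am.estimate_background(hmap, pmask)
        v1 = am.particle_volume(hmap, labeled, sel, bg1).volume_nm3

        from dataclasses import replace

        shifted = replace(hmap, heights=hmap.heights + 7.3)
        bg2 = am.estimate_background(shifted, pmask)
        v2 = am.particle_volume(shifted, labeled, sel, bg2).volume_nm3
        assert bg2 == pytest.approx(bg1 + 7.3)
        assert v2 == pytest.approx(v1, rel=1e-9)

    def test_absent_label(self, blob_map):
        hmap, _ = blob_map
        mask = hmap.heights > 0.5
        with pytest.raises(ParameterError):
            am.particle_volume(hmap, labeled_from_bool(mask), 2, 0.0)


class TestPathLength:
    def test_axis_aligned_with_pixel_size(self):
        hmap = am.HeightMap(np.zeros((8, 8)), 2.0, 2.0)
        path = am.TracePath([[0, 0], [0, 3]])
        assert am.path_length(path, hmap) == pytest.approx(6.0)

    def test_three_four_five(self):
        hmap = am.HeightMap(np.zeros((8, 8)), 1.0, 1.0)
        assert am.path_length(am.TracePath([[0, 0], [3, 4]]), hmap) == pytest.approx(5.0)

    def test_polyline_additivity(self, rng):
        hmap = am.HeightMap(np.zeros((32, 32)), 1.0, 1.0)
        pts = rng.uniform(0, 31, (6, 2))
        whole = am.path_length(am.TracePath(pts), hmap)
        parts = sum(
            am.path_length(am.TracePath(pts[i:i + 2]), hmap) for i in range(5)
        )
        assert whole == pytest.approx(parts)

    def test_anisotropic_pixels(self):
        hmap = am.HeightMap(np.zeros((8, 8)), 3.0, 1.0)   # x 3 nm, y 1 nm
        path = am.TracePath([[0, 0], [4, 3]])             # 4 rows, 3 cols
        assert am.path_length(path, hmap) == pytest.approx(math.hypot(4 * 1.0, 3 * 3.0))


class TestHeightProfile:
    def test_flat_image(self, flat_map):
        prof = am.height_profile(flat_map, am.TracePath([[2, 2], [10, 12]]))
        np.testing.assert_allclose(prof.heights_nm, 1.0)
        assert prof.std_height_nm == pytest.approx(0.0)

    def test_ramp_matches_bilinear_closed_form(self):
        r = np.arange(16)[:, None]
        c = np.arange(16)[None, :]
        hmap = am.HeightMap(0.5 * r + 0.25 * c + 0.0 * r * c, 1.0, 1.0)
        path = am.TracePath([[1.0, 2.0], [9.0, 14.0]])
        prof = am.height_profile(hmap, path, step_px=0.5)
        # bilinear interpolation reproduces a bilinear surface exactly
        pts = am.metrology.resample_path(path, 0.5)
        np.testing.assert_allclose(
            prof.heights_nm, 0.5 * pts[:, 0] + 0.25 * pts[:, 1], atol=1e-12
        )

    def test_apex_found_on_ridge_crossing(self, blob_map):
        hmap, _ = blob_map
        prof = am.height_profile(hmap, am.TracePath([[31.5, 5], [31.5, 58]]))
        imax = np.argmax(prof.heights_nm)
        assert prof.arc_positions_nm[imax] == pytest.approx(26.5, abs=1.0)

    def test_out_of_bounds_path(self, flat_map):
        with pytest.raises(BoundsError):
            am.height_profile(flat_map, am.TracePath([[2, 2], [40, 2]]))


class TestWidthProfile:
    @staticmethod
    def _ridge(sigma, pixel=1.0):
        line = am.centerline_line((40, 12), (40, 108))
        hmap, _ = am.make_filament((80, 120), line, sigma, 2.0, pixel)
        return hmap

    def test_fwhm_matches_half_max_crossing_oracle(self):
        """Fitted FWHM agrees with the direct half-maximum crossing width."""
        sigma = 2.0
        hmap = self._ridge(sigma)
        path = am.TracePath([[40.0, 20], [40.0, 100]])
        wp = am.width_profile(hmap, path, half_width_px=8)
        # oracle: analytic cross-section h(s) = A exp(-s^2/2sigma^2) crosses
        # half max at s = +- sigma sqrt(2 ln 2)
        oracle_fwhm = 2 * sigma * math.sqrt(2 * math.log(2))
        assert wp.mean_fwhm_nm == pytest.approx(oracle_fwhm, rel=0.02)

    def test_fwhm_scales_with_pixel_size(self):
        wide = am.width_profile(
            self._ridge(2.0, 1.0), am.TracePath([[40.0, 20], [40.0, 100]]), 8
        )
        fine = am.width_profile(
            self._ridge(2.0, 0.5), am.TracePath([[40.0, 20], [40.0, 100]]), 8
        )
        assert fine.mean_fwhm_nm == pytest.approx(wide.mean_fwhm_nm / 2, rel=1e-6)

    def test_fwhm_sigma_factor_exact(self):
        """Every converged fit satisfies FWHM = 2 sqrt(2 ln 2) sigma (~2.35)."""
        hmap = self._ridge(2.5)
        wp = am.width_profile(hmap, am.TracePath([[40.0, 20], [40.0, 100]]), 10)
        for fit in wp.converged_fits:
            assert fit.fwhm_nm / (fit.sigma_px * hmap.pixel_size_x) == pytest.approx(
                GAUSSIAN_FWHM_FACTOR, abs=1e-9
            )
        assert round(GAUSSIAN_FWHM_FACTOR, 1) == 2.4   # the conventional "~2.3-2.4"

    def test_half_width_domain(self, blob_map):
        hmap, _ = blob_map
        with pytest.raises(ParameterError):
            am.width_profile(hmap, am.TracePath([[31, 10], [31, 50]]), half_width_px=2)


class TestSkeleton:
    def test_straight_chain_length(self):
        sk = np.zeros((5, 12), bool)
        sk[2, 1:11] = True
        assert am.skeleton_length(sk, 1.0, 1.0) == pytest.approx(9.0)

    def test_diagonal_chain_length(self):
        sk = np.eye(10, dtype=bool)
        assert am.skeleton_length(sk, 1.0, 1.0) == pytest.approx(9 * math.sqrt(2))

    def test_t_shape_matches_pair_enumeration_oracle(self):
        """Branched skeletons sum every adjacent pair once (incl. junction diagonals)."""
        sk = np.zeros((9, 9), bool)
        sk[4, 1:8] = True          # horizontal stroke
        sk[1:4, 4] = True          # vertical stroke meeting it
        assert am.skeleton_length(sk, 1.0, 1.0) == pytest.approx(
            brute_force_chain_length(sk)
        )

    def test_random_curves_match_pair_enumeration(self, rng):
        for _ in range(10):
            sk = random_thin_curve(rng)
            assert am.skeleton_length(sk, 1.0, 1.0) == pytest.approx(
                brute_force_chain_length(sk)
            )

    def test_thin_ridge_is_its_own_skeleton(self):
        h = np.zeros((7, 54))
        h[3, 2:52] = 2.0           # 1 px wide, 50 px long
        res = am.skeletonize_molecule(am.HeightMap(h, 1.0, 1.0), 1.0)
        assert res.length_nm == pytest.approx(49.0)

    def test_min_pixels_filters_small_component(self):
        h = np.zeros((40, 40))
        h[5:7, 5:8] = 2.0                     # 6 px speck
        h[15:29, 10:26] = 2.0                 # 224 px block
        res = am.skeletonize_molecule(am.HeightMap(h, 1.0, 1.0), 1.0, min_pixels=10)
        assert not res.skeleton[5:7, 5:8].any()
        assert res.skeleton[15:29, 10:26].any()

    def test_semicircle_arc_length_recovered(self):
        """Calibrated chain length of a half-circle filament ~ pi * R."""
        line = am.centerline_arc((150, 150), 100, 0, math.pi)
        hmap, truth = am.make_filament((300, 300), line, 2.5, 2.0, 1.0)
        res = am.skeletonize_molecule(hmap, 1.0, 10, length_estimator="calibrated")
        assert res.length_nm == pytest.approx(math.pi * 100, rel=0.05)

    def test_empty_support_error(self, flat_map):
        with pytest.raises(am.errors.AFMetricsError):
            am.skeletonize_molecule(flat_map, 5.0)

    def test_empty_skeleton_warns_and_returns_zero(self, caplog):
        with caplog.at_level("WARNING", logger="afmetrics"):
            assert am.skeleton_length(np.zeros((4, 4), bool)) == 0.0
        assert "empty" in caplog.text


def brute_force_chain_length(sk, psx=1.0, psy=1.0):
    """Enumerate all 8-adjacent true-pixel pairs once; sum their distances."""
    coords = np.argwhere(sk)
    total = 0.0
    for i in range(len(coords)):
        for j in range(i + 1, len(coords)):
            dr = abs(coords[i][0] - coords[j][0])
            dc = abs(coords[i][1] - coords[j][1])
            if max(dr, dc) == 1:
                total += math.hypot(dr * psy, dc * psx)
    return total


def random_thin_curve(rng, n=30, size=48):
    """Random 8-connected pixel walk (possibly self-touching)."""
    sk = np.zeros((size, size), bool)
    r, c = size // 2, size // 2
    for _ in range(n):
        sk[r, c] = True
        dr, dc = rng.integers(-1, 2), rng.integers(-1, 2)
        r = int(np.clip(r + dr, 1, size - 2))
        c = int(np.clip(c + dc, 1, size - 2))
    return sk


class TestAngles:
    def test_collinear(self):
        m = am.measure_angle((0, 0), (0, 5), (0, 9))
        assert m.angle_deg == pytest.approx(180.0)

    def test_right_angle(self):
        assert am.measure_angle((0, 5), (0, 0), (5, 0)).angle_deg == pytest.approx(90.0)

    def test_forty_five(self):
        assert am.measure_angle((1, 0), (0, 0), (1, 1)).angle_deg == pytest.approx(45.0)

    def test_anisotropic_pixels_change_angle(self):
        iso = am.measure_angle((1, 0), (0, 0), (1, 1), 1.0, 1.0)
        aniso = am.measure_angle((1, 0), (0, 0), (1, 1), 2.0, 1.0)
        assert iso.angle_deg == pytest.approx(45.0)
        assert aniso.angle_deg == pytest.approx(math.degrees(math.atan2(2, 1)), rel=1e-6)

    def test_degenerate_vertex(self):
        with pytest.raises(ParameterError):
            am.measure_angle((0, 0), (0, 0), (1, 1))


class TestUpsample:
    def test_constant_preserved(self, flat_map):
        up = am.upsample_for_display(flat_map, 10)
        np.testing.assert_allclose(up.heights, 1.0, atol=1e-12)

    def test_dimensions_and_pixel_size(self, blob_map):
        hmap, _ = blob_map
        up = am.upsample_for_display(hmap, 10)
        assert up.shape == (640, 640)
        assert up.pixel_size_x == pytest.approx(hmap.pixel_size_x / 10)

    def test_linear_ramp_reproduced(self):
        # cubic interpolation reproduces a linear ramp away from the clamped
        # borders (boundary influence decays geometrically into the interior)
        r = np.arange(32)[:, None] * np.ones((1, 32))
        up = am.upsample_for_display(am.HeightMap(r, 1.0, 1.0), 4)
        coord = (np.arange(128) + 0.5) / 4 - 0.5
        expect = coord[:, None] * np.ones((1, 128))
        np.testing.assert_allclose(
            up.heights[24:-24, 24:-24], expect[24:-24, 24:-24], atol=1e-3
        )
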