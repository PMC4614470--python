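import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from conftest import annulus_mask, circle_contour
from cortadapt.geometry import BoneShapeParams, CrossSection, Landmark, \
    make_bone_volume
from cortadapt.thickness import (ThicknessChangeMap, ThicknessMap,
                                 apply_mask, bin_thickness,
                                 extract_boundaries, map_thickness,
                                 pixel_thickness, second_moment_of_area,
                                 thickness_change)


def brute_force_thickness(peri, endo, pixel_size):
    """O(N*M) all-pairs oracle for the shortest peri->endo distance."""
    return cdist(peri, endo).min(axis=1) * pixel_size


class TestBoundaries:
    def test_annulus_gives_two_concentric_rings(self, annulus_section):
        peri, endo = extract_boundaries(annulus_section)
        c = 0.5 * (annulus_section.mask.shape[0] - 1)
        r_peri = np.hypot(*(peri - c).T)
        r_endo = np.hypot(*(endo - c).T)
        assert np.all(np.abs(r_peri - 120.0) < 1.5)
        assert np.all(np.abs(r_endo - 79.5) < 1.5)

    def test_interior_porosity_is_filled(self, annulus_section):
        mask = annulus_section.mask.copy()
        mask[36:39, 136] = False  # 3-px blood-vessel hole in the wall
        holed = CrossSection(mask, 1.0, 0.5)
        ref_p, ref_e = extract_boundaries(annulus_section)
        got_p, got_e = extract_boundaries(holed)
        assert np.array_equal(np.sort(ref_p, 0), np.sort(got_p, 0))
        assert np.array_equal(np.sort(ref_e, 0), np.sort(got_e, 0))

    def test_detached_trabecular_blob_is_discarded(self, annulus_section):
        mask = annulus_section.mask.copy()
        mask[5:15, 5:10] = True  # 50-px unconnected fragment
        ref_p, _ = extract_boundaries(annulus_section)
        got_p, _ = extract_boundaries(CrossSection(mask, 1.0, 0.5))
        assert np.array_equal(np.sort(ref_p, 0), np.sort(got_p, 0))

    def test_solid_section_is_an_error(self):
        mask = annulus_mask(64, 25, 0)
        with pytest.raises(ValueError, match="cavity"):
            extract_boundaries(CrossSection(mask, 1.0, 0.5))


class TestPixelThickness:
    def test_concentric_circles(self):
        peri = circle_contour(1250, 600.0)
        endo = circle_contour(1250, 400.0)
        th = pixel_thickness(peri, endo, 1.0)
        np.testing.assert_allclose(th, 200.0, atol=1.0)

    def test_eccentric_inner_circle(self):
        peri = circle_contour(1250, 600.0)
        endo = circle_contour(1250, 400.0, center=(0.0, 50.0))
        th = pixel_thickness(peri, endo, 1.0)
        assert th.min() == pytest.approx(150.0, abs=1.0)
        assert th.max() == pytest.approx(250.0, abs=1.0)

    def test_matches_brute_force_all_pairs_oracle(self, annulus_section):
        peri, endo = extract_boundaries(annulus_section)
        fast = pixel_thickness(peri, endo, 1.0)
        slow = brute_force_thickness(peri, endo, 1.0)
        np.testing.assert_allclose(fast, slow, rtol=0, atol=1e-9)


class TestBinning:
    def test_uniform_ring_fills_all_bins(self, annulus_section):
        peri, endo = extract_boundaries(annulus_section)
        th = pixel_thickness(peri, endo, 1.0)
        c = 0.5 * (annulus_section.mask.shape[0] - 1)
        means, edges = bin_thickness(peri, th, (c, c), 180)
        assert np.all(np.isfinite(means))
        np.testing.assert_allclose(means, 40.0, atol=1.0)

    def test_default_bin_width_is_two_degrees(self):
        means, edges = bin_thickness(np.array([[0, 1]]), np.array([5.0]),
                                     (0.0, 0.0), 180)
        assert np.diff(edges)[0] == pytest.approx(math.pi / 90)

    def test_single_pixel_bin_keeps_its_value(self):
        means, _ = bin_thickness(np.array([[0, 10]]), np.array([7.5]),
                                 (0.0, 0.0), 180)
        assert means[0] == 7.5
        assert np.isnan(means[1:]).all()


class TestThicknessChange:
    def _map(self, values):
        values = np.atleast_2d(np.asarray(values, dtype=float))
        edges = np.linspace(0, 2 * np.pi, values.shape[1] + 1)
        return ThicknessMap(values, edges, np.linspace(0, 1, values.shape[0]))

    def test_identity_is_zero(self):
        m = self._map([[200.0, 210.0, 190.0]])
        change = thickness_change(m, m)
        np.testing.assert_array_equal(change.dth, 0.0)

    def test_ratio_matches_expected_value(self):
        change = thickness_change(self._map([[200.0]]), self._map([[334.0]]))
        assert change.dth[0, 0] == pytest.approx(0.67)

    def test_thinning_preserved_as_negative(self):
        change = thickness_change(self._map([[200.0]]), self._map([[150.0]]))
        assert change.dth[0, 0] == pytest.approx(-0.25)

    def test_missing_bins_propagate(self):
        left = self._map([[200.0, np.nan]])
        right = self._map([[220.0, 200.0]])
        change = thickness_change(left, right)
        assert np.isnan(change.dth[0, 1]) and not change.mask[0, 1]

    def test_self_change_of_volume_is_identically_zero(self,
                                                       small_bone_volume):
        tm = map_thickness(small_bone_volume, 60)
        change = thickness_change(tm, tm)
        assert np.all(change.dth[change.mask] == 0.0)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            thickness_change(self._map([[1.0, 2.0]]), self._map([[1.0]]))


class TestMask:
    def _change(self, nz=10, nb=36):
        dth = np.zeros((nz, nb))
        edges = np.linspace(0, 2 * np.pi, nb + 1)
        return ThicknessChangeMap(dth, np.ones((nz, nb), bool), edges,
                                  np.linspace(0, 1, nz))

    def test_keep_all_leaves_mask_unchanged(self):
        change = self._change()
        out = apply_mask(change, [(0.0, 2 * np.pi, 0.0, 1.0)])
        assert np.array_equal(out.mask, change.mask)

    def test_rectangle_bin_count(self):
        out = apply_mask(self._change(), [(0.0, np.pi, 0.15, 1.0)])
        # 18 of 36 bins; Z >= 0.15 keeps 8 of the 10 slices at 0, 1/9, ...
        assert out.mask.sum() == 18 * 8

    def test_wrapped_theta_range(self):
        out = apply_mask(self._change(), [(1.5 * np.pi, 0.5 * np.pi,
                                           0.0, 1.0)])
        assert out.mask.sum() == 18 * 10

    def test_empty_kept_region_is_error(self):
        with pytest.raises(ValueError):
            apply_mask(self._change(), [(0.0, 2 * np.pi, 2.0, 3.0)])


class TestSecondMoment:
    def test_annulus_matches_closed_form(self):
        sec = CrossSection(annulus_mask(1250, 600, 400), 1.0, 0.5)
        props = second_moment_of_area(sec)
        exact = math.pi * (600.0 ** 4 - 400.0 ** 4) / 4.0
        assert props.I_xx == pytest.approx(exact, rel=0.01)
        assert props.I_yy == pytest.approx(exact, rel=0.01)
        assert props.area_um2 == pytest.approx(
            math.pi * (600.0 ** 2 - 400.0 ** 2), rel=0.01)

    def test_product_moment_vanishes_for_symmetric_section(
            self, annulus_section):
        props = second_moment_of_area(annulus_section)
        assert abs(props.I_xy) < 1e-6 * props.I_xx

    def test_central_moments_translation_invariant(self, annulus_section):
        shifted = CrossSection(np.roll(annulus_section.mask, (7, -4),
                                       axis=(0, 1)), 1.0, 0.5)
        a = second_moment_of_area(annulus_section)
        b = second_moment_of_area(shifted)
        assert a.I_xx == pytest.approx(b.I_xx, rel=1e-9)
        assert a.I_min == pytest.approx(b.I_min, rel=1e-9)


def test_rotating_section_permutes_bins():
    """A 90 deg rotation shifts the thickness map by a quarter turn."""
    bump = Landmark(math.radians(40.0), math.radians(60.0), 30.0)
    p = BoneShapeParams(n_slices=1, pixel_size=1.0,
                        outer_radius_prox_um=150.0,
                        outer_radius_dist_um=150.0,
                        wall_prox_um=50.0, wall_dist_um=50.0,
                        landmarks=[bump], ecc_amplitude_um=0.0,
                        ecc_wobble_um=0.0)
    vol = make_bone_volume(p)
    sec = vol.sections[0]
    rot = CrossSection(np.rot90(sec.mask), 1.0, 0.5)
    tm = map_thickness(vol, 180).th[0]
    rot_vol = make_bone_volume(p)
    rot_vol.sections[0] = rot
    tm_rot = map_thickness(rot_vol, 180).th[0]
    # np.rot90 maps (x, y) -> (y, -x): theta decreases by 90 deg
    np.testing.assert_allclose(tm_rot, np.roll(tm, -45), atol=2.0)
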