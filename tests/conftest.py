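import math

import numpy as np
import pytest

from cortadapt.geometry import (BoneShapeParams, CrossSection, Landmark,
                                make_bone_volume)


def annulus_mask(size: int, r_out: float, r_in: float,
                 center=None) -> np.ndarray:
    """Pixel annulus r_in <= r <= r_out about the image centre (or a given
    (row, col) offset of the inner circle for eccentric walls)."""
    c = 0.5 * (size - 1)
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.hypot(yy - c, xx - c)
    outer = r <= r_out
    if center is None:
        inner = r < r_in
    else:
        r2 = np.hypot(yy - c - center[0], xx - c - center[1])
        inner = r2 < r_in
    return outer & ~inner


def circle_contour(size: int, radius: float, center=(0.0, 0.0)) -> np.ndarray:
    """(N, 2) row/col pixels of a one-pixel-wide discretised circle."""
    c = 0.5 * (size - 1)
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.hypot(yy - c - center[0], xx - c - center[1])
    return np.argwhere(np.abs(r - radius) <= 0.5)


@pytest.fixture
def annulus_section() -> CrossSection:
    """Concentric annulus, r_out=120 px, r_in=80 px, 1 um/px."""
    return CrossSection(annulus_mask(272, 120, 80), 1.0, 0.5)


@pytest.fixture
def annulus_params() -> BoneShapeParams:
    """Straight circular tube: r_out=120 um, wall 40 um, no landmarks."""
    return BoneShapeParams(
        n_slices=3, pixel_size=1.0, length_um=600.0,
        outer_radius_prox_um=120.0, outer_radius_dist_um=120.0,
        wall_prox_um=40.0, wall_dist_um=40.0,
        ecc_amplitude_um=0.0, ecc_wobble_um=0.0)


@pytest.fixture
def small_bone_params() -> BoneShapeParams:
    """Miniature curved bone with one crest, cheap enough for loop tests."""
    return BoneShapeParams(
        n_slices=8, pixel_size=2.0, length_um=2000.0,
        outer_radius_prox_um=250.0, outer_radius_dist_um=220.0,
        wall_prox_um=90.0, wall_dist_um=70.0,
        landmarks=[Landmark(math.radians(300.0), math.radians(50.0), 50.0)],
        ecc_amplitude_um=200.0, ecc_wobble_um=15.0)


@pytest.fixture
def small_bone_volume(small_bone_params):
    return make_bone_volume(small_bone_params)
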