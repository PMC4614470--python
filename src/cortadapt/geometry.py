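"""Parametric tibia-like bone volumes for pipeline testing and simulation.

The generator emulates binary micro-CT cross sections of a curved hollow
long-bone diaphysis: an annular cortical shell whose outer radius carries
cosine-tapered angular landmark bumps (interosseous crest, tibial ridge,
soleal line, proximal crest analogues), whose section centroid drifts along
the bone axis (the natural bow that turns axial load into bending), and
whose wall thickness tapers proximal to distal.  A paired "loaded" geometry
is produced by applying a known relative thickening field to the periosteal
boundary, giving a ground truth for round-trip tests of the thickness
mapping and adaptation pipeline.

Coordinates: each slice lives on a pixel grid; the bone's load axis pierces
the image centre.  theta = 0 along +x, measured counter-clockwise in the
image frame (x = column offset, y = row offset, in micrometres); the axial
coordinate Z is normalised to [0, 1] from proximal to distal.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Landmark",
    "BoneShapeParams",
    "CrossSection",
    "BoneVolume",
    "SurfaceGrid",
    "default_params",
    "make_bone_volume",
    "apply_thickening_field",
    "build_surface_grid",
]

_N_THETA_DENSE = 1440  # samples of the analytic polar boundary functions


@dataclass(frozen=True)
class Landmark:
    """A cosine-tapered radial bump on the periosteal boundary.

    The bump raises the outer radius (and hence the local wall thickness)
    by up to ``amplitude_um`` at ``theta_center``, rolling off smoothly to
    zero at +-``width_rad``/2 and over the outer 20% of its Z extent.
    """

    theta_center: float  # rad
    width_rad: float
    amplitude_um: float
    z_range: tuple[float, float] = (0.0, 1.0)

    def profile(self, theta: np.ndarray, z: float) -> np.ndarray:
        half = 0.5 * self.width_rad
        d = np.angle(np.exp(1j * (theta - self.theta_center)))  # wrapped
        radial = np.where(np.abs(d) < half,
                          0.5 * (1.0 + np.cos(np.pi * d / half)), 0.0)
        z0, z1 = self.z_range
        if not (z0 <= z <= z1):
            return np.zeros_like(theta)
        edge = 0.2 * (z1 - z0)
        axial = 1.0
        if edge > 0:
            if z < z0 + edge:
                axial = 0.5 * (1.0 - math.cos(math.pi * (z - z0) / edge))
            elif z > z1 - edge:
                axial = 0.5 * (1.0 - math.cos(math.pi * (z1 - z) / edge))
        return self.amplitude_um * axial * radial


@dataclass
class BoneShapeParams:
    """Geometry of the synthetic tibia.

    Linear proximal->distal tapers for outer radius and wall thickness,
    landmark bumps, and a centroid-eccentricity profile e(Z) (offset of the
    section centre from the load axis, micrometres) that produces
    mediolateral bending under axial load.
    """

    n_slices: int = 100
    pixel_size: float = 1.0        # um / px
    pixels: int | None = None      # image edge length; None -> auto-fit
    length_um: float = 10_000.0    # axial span of Z in [0, 1]
    outer_radius_prox_um: float = 600.0
    outer_radius_dist_um: float = 480.0
    wall_prox_um: float = 220.0
    wall_dist_um: float = 150.0
    landmarks: list[Landmark] = field(default_factory=list)
    ecc_amplitude_um: float = 500.0     # peak |e(Z)|, sin(pi Z) profile
    ecc_azimuth_rad: float = math.radians(120.0)  # direction of the bow
    ecc_wobble_um: float = 40.0         # secondary sin(2 pi Z) component
    noise_amplitude_um: float = 0.0     # seeded boundary roughness, off
    seed: int = 0

    def base_outer_radius(self, z: float) -> float:
        return self.outer_radius_prox_um + (
            self.outer_radius_dist_um - self.outer_radius_prox_um) * z

    def base_wall_thickness(self, z: float) -> float:
        return self.wall_prox_um + (self.wall_dist_um - self.wall_prox_um) * z

    def centroid_eccentricity(self, z: float) -> tuple[float, float]:
        m = self.ecc_amplitude_um * math.sin(math.pi * z)
        ex = m * math.cos(self.ecc_azimuth_rad)
        ey = m * math.sin(self.ecc_azimuth_rad)
        w = self.ecc_wobble_um * math.sin(2.0 * math.pi * z)
        ex += w * math.cos(self.ecc_azimuth_rad + 0.5 * math.pi)
        ey += w * math.sin(self.ecc_azimuth_rad + 0.5 * math.pi)
        return ex, ey

    def validate(self) -> None:
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        zs = np.linspace(0.0, 1.0, max(self.n_slices, 2))
        for z in zs:
            wall = self.base_wall_thickness(z)
            r_out = self.base_outer_radius(z)
            if wall <= 0:
                raise ValueError(f"wall thickness must be > 0 (Z={z:.2f})")
            if r_out <= wall:
                raise ValueError(f"outer radius must exceed wall (Z={z:.2f})")
        half = 0.5 * self.image_pixels() * self.pixel_size
        for z in zs:
            ex, ey = self.centroid_eccentricity(z)
            if math.hypot(ex, ey) >= half:
                raise ValueError("eccentricity exceeds image half-width")

    def image_pixels(self) -> int:
        if self.pixels is not None:
            return self.pixels
        bump = sum(lm.amplitude_um for lm in self.landmarks)
        # one full wall of headroom so thickening fields / simulated growth
        # up to dTh/Th ~ 1 stay inside the frame
        margin = max(self.wall_prox_um, self.wall_dist_um) + bump
        extent = (self.ecc_amplitude_um + self.ecc_wobble_um
                  + max(self.outer_radius_prox_um, self.outer_radius_dist_um)
                  + bump + self.noise_amplitude_um + margin + 16.0)
        return 2 * int(math.ceil(extent / self.pixel_size))

    def slice_spacing_um(self) -> float:
        return self.length_um / max(self.n_slices - 1, 1)


def default_params() -> BoneShapeParams:
    """The standard synthetic mouse-tibia configuration.

    Mid-diaphysis outer radius ~0.6 mm tapering to ~0.48 mm, cortical wall
    220 -> 150 um, four landmark crests at the murine angular positions
    (interosseous crest 300 deg, tibial ridge 50 deg, soleal line 220 deg,
    proximal crest 160 deg), and a bow of peak 500 um: section centroids
    drift towards 120 deg so the load axis falls on the crest side of the
    centroid.  The bow makes bending dominate the axial term (roughly 2.3x
    at mid-shaft), reproducing the in vivo strain split -- deep compression
    at the interosseous crest, genuine tension on the opposite (medial
    analogue) surface -- with peak strains of a few thousand microstrain
    under the 13 N cycle.
    """
    return BoneShapeParams(
        landmarks=[
            Landmark(math.radians(300.0), math.radians(50.0), 130.0, (0.0, 1.0)),
            Landmark(math.radians(50.0), math.radians(35.0), 100.0, (0.0, 0.55)),
            Landmark(math.radians(220.0), math.radians(30.0), 60.0, (0.1, 0.7)),
            Landmark(math.radians(160.0), math.radians(30.0), 50.0, (0.0, 0.4)),
        ],
    )


@dataclass
class CrossSection:
    """One binary transverse slice: True = cortical bone."""

    mask: np.ndarray          # bool, (pixels, pixels)
    pixel_size: float         # um / px
    z: float                  # normalised axial coordinate in [0, 1]

    def __post_init__(self) -> None:
        if not (0.0 <= self.z <= 1.0):
            raise ValueError("Z must lie in [0, 1]")
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class _PolarModel:
    """Analytic polar boundary functions of a generated volume.

    r_out/r_in are sampled on a dense uniform theta grid per slice, measured
    from the slice centre ``center_um`` (offset from the image centre).
    """

    theta: np.ndarray            # (n_theta,)
    r_out: np.ndarray            # (n_slices, n_theta) um
    r_in: np.ndarray             # (n_slices, n_theta) um
    center_um: np.ndarray        # (n_slices, 2) (x, y) um from image centre
    z: np.ndarray                # (n_slices,)

    def copy(self) -> "_PolarModel":
        return _PolarModel(self.theta.copy(), self.r_out.copy(),
                           self.r_in.copy(), self.center_um.copy(),
                           self.z.copy())


@dataclass
class BoneVolume:
    """Ordered stack of cross sections plus physical metadata."""

    sections: list[CrossSection]
    pixel_size: float
    slice_spacing_um: float
    polar: _PolarModel | None = None   # present for synthetic volumes

    def __post_init__(self) -> None:
        zs = [s.z for s in self.sections]
        if any(b <= a for a, b in zip(zs, zs[1:])):
            raise ValueError("sections must be sorted by strictly increasing Z")

    @property
    def z(self) -> np.ndarray:
        return np.array([s.z for s in self.sections])

    @property
    def n_slices(self) -> int:
        return len(self.sections)


def _rasterize_slice(theta: np.ndarray, r_out: np.ndarray, r_in: np.ndarray,
                     center_um: np.ndarray, pixels: int,
                     pixel_size: float) -> np.ndarray:
    """Pixel-grid annular region between the polar boundary functions.

    Work is confined to the bounding box of the outer boundary; the frame
    may be much larger than the bone.
    """
    c = 0.5 * (pixels - 1)
    r_max = float(r_out.max()) + 2.0 * pixel_size
    lo = max(int(np.floor(c + (min(center_um) - r_max) / pixel_size)), 0)
    hi = min(int(np.ceil(c + (max(center_um) + r_max) / pixel_size)) + 1,
             pixels)
    coords = (np.arange(lo, hi) - c) * pixel_size
    x = coords[None, :] - center_um[0]
    y = coords[:, None] - center_um[1]
    r = np.hypot(x, y)
    th = np.mod(np.arctan2(y, x), 2.0 * np.pi)
    # periodic linear interpolation of the boundary radii
    ro = np.interp(th, theta, r_out, period=2.0 * np.pi)
    ri = np.interp(th, theta, r_in, period=2.0 * np.pi)
    mask = np.zeros((pixels, pixels), dtype=bool)
    mask[lo:hi, lo:hi] = (r <= ro) & (r >= ri)
    return mask


def make_bone_volume(params: BoneShapeParams) -> BoneVolume:
    """Generate the binary image stack described by ``params``.

    The outer boundary at (theta, Z) is the base outer radius plus the sum
    of landmark bumps; the inner boundary sits ``base_wall_thickness``
    radially inward; the whole section is displaced from the load axis by
    the centroid eccentricity.  Deterministic for a fixed seed.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    theta = np.linspace(0.0, 2.0 * np.pi, _N_THETA_DENSE, endpoint=False)
    pixels = params.image_pixels()
    n = params.n_slices
    zs = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.5])

    r_out = np.empty((n, theta.size))
    r_in = np.empty((n, theta.size))
    centers = np.empty((n, 2))
    sections = []
    for i, z in enumerate(zs):
        ro = np.full(theta.size, params.base_outer_radius(z))
        for lm in params.landmarks:
            ro = ro + lm.profile(theta, z)
        if params.noise_amplitude_um > 0:
            # smooth periodic roughness from a few random harmonics
            for h in range(2, 7):
                a = rng.normal(scale=params.noise_amplitude_um / 5.0)
                b = rng.uniform(0, 2 * np.pi)
                ro = ro + a * np.cos(h * theta + b)
        # crests are solid ridges: the endosteal boundary follows the base
        # radius, so bumps (and noise) thicken the local wall
        wall = params.base_wall_thickness(z)
        ri = np.full(theta.size, params.base_outer_radius(z) - wall)
        if np.any(ri <= 0):
            raise ValueError("wall thickness exceeds outer radius")
        if wall < 2.0 * params.pixel_size:
            raise ValueError(
                f"degenerate wall: {wall:.1f} um is thinner than 2 px "
                f"({2 * params.pixel_size:.1f} um) at Z={z:.2f}")
        center = np.array(params.centroid_eccentricity(z))
        mask = _rasterize_slice(theta, ro, ri, center, pixels,
                                params.pixel_size)
        sections.append(CrossSection(mask, params.pixel_size, float(z)))
        r_out[i], r_in[i], centers[i] = ro, ri, center

    polar = _PolarModel(theta, r_out, r_in, centers, zs)
    return BoneVolume(sections, params.pixel_size, params.slice_spacing_um(),
                      polar=polar)


def _polar_from_mask(section: CrossSection,
                     theta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Recover (r_out, r_in, centre) of a star-convex annular mask by ray
    marching from its area centroid.  Accuracy ~1 px."""
    mask = section.mask
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty mask")
    c = 0.5 * (mask.shape[0] - 1)
    px = section.pixel_size
    cx = (cols.mean() - c) * px
    cy = (rows.mean() - c) * px
    r_max = mask.shape[0] * px
    r_samples = np.arange(0.0, r_max, 0.5 * px)
    xs = cx + np.cos(theta)[:, None] * r_samples[None, :]
    ys = cy + np.sin(theta)[:, None] * r_samples[None, :]
    jj = np.clip(np.round(xs / px + c).astype(int), 0, mask.shape[1] - 1)
    ii = np.clip(np.round(ys / px + c).astype(int), 0, mask.shape[0] - 1)
    hit = mask[ii, jj]
    any_hit = hit.any(axis=1)
    if not any_hit.all():
        raise ValueError("mask is not star-convex about its centroid")
    first = hit.argmax(axis=1)
    last = hit.shape[1] - 1 - hit[:, ::-1].argmax(axis=1)
    return r_samples[last], r_samples[first], np.array([cx, cy])


def apply_thickening_field(volume: BoneVolume,
                           field: np.ndarray) -> BoneVolume:
    """Displace the periosteal boundary outward by a relative field.

    ``field`` holds non-negative Delta-Th/Th values on an (n_slices,
    n_theta_bins) grid (uniform theta bins over [0, 2 pi)); the wall
    thickness at (theta, Z) becomes Th * (1 + field) with the endosteal
    boundary unchanged.  Models pro-osteogenic appositional growth only.
    """
    field = np.asarray(field, dtype=float)
    if field.ndim != 2 or field.shape[0] != volume.n_slices:
        raise ValueError("field must be (n_slices, n_theta_bins)")
    if np.any(field < 0):
        raise ValueError("thickening field must be non-negative "
                         "(pro-osteogenic model)")

    theta = np.linspace(0.0, 2.0 * np.pi, _N_THETA_DENSE, endpoint=False)
    if volume.polar is not None:
        polar = volume.polar.copy()
    else:
        n = volume.n_slices
        polar = _PolarModel(theta, np.empty((n, theta.size)),
                            np.empty((n, theta.size)), np.empty((n, 2)),
                            volume.z)
        for i, s in enumerate(volume.sections):
            polar.r_out[i], polar.r_in[i], polar.center_um[i] = \
                _polar_from_mask(s, theta)

    nb = field.shape[1]
    bin_centers = (np.arange(nb) + 0.5) * 2.0 * np.pi / nb
    pixels = volume.sections[0].mask.shape[0]
    px = volume.pixel_size
    half_um = 0.5 * pixels * px
    sections = []
    for i, s in enumerate(volume.sections):
        f = np.interp(polar.theta, bin_centers, field[i], period=2.0 * np.pi)
        wall = polar.r_out[i] - polar.r_in[i]
        new_out = polar.r_in[i] + wall * (1.0 + f)
        if np.any(new_out + np.abs(polar.center_um[i]).max() >= half_um):
            raise ValueError("thickening field pushes the outer contour "
                             "beyond the image frame")
        polar.r_out[i] = new_out
        mask = _rasterize_slice(polar.theta, new_out, polar.r_in[i],
                                polar.center_um[i], pixels, px)
        sections.append(CrossSection(mask, px, s.z))
    return BoneVolume(sections, px, volume.slice_spacing_um, polar=polar)


@dataclass
class SurfaceGrid:
    """Periosteal surface sample points on a (Z-slice, theta-bin) lattice.

    All nodal arrays are shaped (n_slices, n_theta_bins).  Positions are in
    micrometres in the global frame (load axis at x = y = 0, z = Z *
    length); ``radius`` is the distance from the slice centre used for the
    polar surrogate updates, ``thickness`` the local wall thickness from
    the pixel-level map, and ``adaptive`` flags nodes inside the
    diaphyseal adaptive region.
    """

    theta_centers: np.ndarray      # (n_theta,)
    z: np.ndarray                  # (n_z,)
    pos: np.ndarray                # (n_z, n_theta, 3) um
    normal: np.ndarray             # (n_z, n_theta, 3) unit
    thickness: np.ndarray          # (n_z, n_theta) um, NaN where missing
    radius: np.ndarray             # (n_z, n_theta) um from slice centre
    center_um: np.ndarray          # (n_z, 2) slice centres (x, y)
    adaptive: np.ndarray           # (n_z, n_theta) bool
    missing: np.ndarray            # (n_z, n_theta) bool

    @property
    def n_nodes(self) -> int:
        return self.thickness.size

    def copy(self) -> "SurfaceGrid":
        return SurfaceGrid(*(getattr(self, f.name).copy()
                             for f in dataclasses.fields(self)))


def build_surface_grid(volume: BoneVolume, n_theta_bins: int = 180,
                       adaptive_z_range: tuple[float, float] = (0.1, 0.9),
                       ) -> SurfaceGrid:
    """Sample the periosteal boundary into one node per (theta-bin, slice).

    Node positions are the mean of member boundary pixels; wall thickness
    is the mean pixel-level shortest distance to the endosteum; outward
    normals come from the cross product of the local circumferential and
    axial surface tangents.  Empty bins are marked missing.
    """
    from . import thickness as _th  # local import: avoid cycle at import time

    if n_theta_bins < 8:
        raise ValueError("n_theta_bins must be >= 8")
    nz, nb = volume.n_slices, n_theta_bins
    edges = np.linspace(0.0, 2.0 * np.pi, nb + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    zs = volume.z
    length = volume.slice_spacing_um * max(nz - 1, 1)

    pos = np.full((nz, nb, 3), np.nan)
    th = np.full((nz, nb), np.nan)
    rad = np.full((nz, nb), np.nan)
    cen = np.empty((nz, 2))
    missing = np.zeros((nz, nb), dtype=bool)

    for i, s in enumerate(volume.sections):
        peri, endo, (cr, cc) = _th._shell_boundaries(s)
        d = _th.pixel_thickness(peri, endo, s.pixel_size)
        c = 0.5 * (s.mask.shape[0] - 1)
        px = s.pixel_size
        cx, cy = (cc - c) * px, (cr - c) * px
        cen[i] = (cx, cy)
        x = (peri[:, 1] - c) * px
        y = (peri[:, 0] - c) * px
        ang = np.mod(np.arctan2(y - cy, x - cx), 2.0 * np.pi)
        which = np.minimum((ang / (2.0 * np.pi) * nb).astype(int), nb - 1)
        counts = np.bincount(which, minlength=nb)
        empty = counts == 0
        missing[i] = empty
        safe = np.maximum(counts, 1)
        mx = np.bincount(which, weights=x, minlength=nb) / safe
        my = np.bincount(which, weights=y, minlength=nb) / safe
        mth = np.bincount(which, weights=d, minlength=nb) / safe
        good = ~empty
        pos[i, good, 0] = mx[good]
        pos[i, good, 1] = my[good]
        pos[i, good, 2] = zs[i] * length
        th[i, good] = mth[good]
        rad[i, good] = np.hypot(mx[good] - cx, my[good] - cy)
    n_missing = int(missing.sum())
    if n_missing:
        import logging
        logging.getLogger(__name__).warning(
            "%d surface bins had no boundary pixels and were marked missing",
            n_missing)

    normal = _surface_normals(pos, missing)
    lo, hi = adaptive_z_range
    adaptive = ((zs >= lo) & (zs <= hi))[:, None] & ~missing
    return SurfaceGrid(centers, zs, pos, normal, th, rad, cen, adaptive,
                       missing)


def _surface_normals(pos: np.ndarray, missing: np.ndarray) -> np.ndarray:
    """Outward unit normals from circumferential x axial tangent vectors.

    Circumferential tangents use periodic central differences over theta
    bins; axial tangents use (clamped) central differences over slices.
    Sign is fixed outward by the in-plane direction from the section mean.
    """
    nz, nb, _ = pos.shape
    t_th = 0.5 * (np.roll(pos, -1, axis=1) - np.roll(pos, 1, axis=1))
    t_z = np.empty_like(pos)
    if nz > 1:
        t_z[1:-1] = 0.5 * (pos[2:] - pos[:-2])
        t_z[0] = pos[1] - pos[0]
        t_z[-1] = pos[-1] - pos[-2]
    else:
        t_z[:] = [0.0, 0.0, 1.0]
    n = np.cross(t_th, t_z)
    # orient outward: positive projection on the radial direction
    center = np.nanmean(pos[..., :2], axis=1, keepdims=True)
    radial = pos[..., :2] - center
    flip = np.sum(n[..., :2] * radial, axis=-1) < 0
    n[flip] *= -1.0
    norm = np.linalg.norm(n, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        n = n / norm
    n[missing] = np.nan
    return n
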