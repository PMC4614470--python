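"""The mechanobiological surface-growth law and its outer iteration loop.

Bone is assumed to respond to the fluid-velocity stimulus Psi in an on-off
manner: at every solver frame the cellular output Lambda is +1 where Psi
reaches the apposition threshold Psi_A, -1 where it falls to the resorption
threshold Psi_R (inactive by default, Psi_R = 0), and 0 in the lazy zone
between.  Time integration of Lambda over the load window gives the nodal
remodelling rate u_dot (um per iteration, at most the rate constant C);
rates are spatially averaged over a 150 um spherical zone of influence (the
average osteon radius) with linearly decaying weights, and the periosteal
surface advances along the node normal.  Iterations repeat -- recomputing
section properties, beam strain, and the poroelastic stimulus on the grown
geometry -- until the maximum relative thickening in the (masked) adaptive
region reaches the stop criterion, or an iteration cap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import BoneVolume, SurfaceGrid, build_surface_grid
from .mechanics import LoadWaveform, beam_strain
from .poroelastic import PoroMaterial, stimulus_for_sectors
from .thickness import SectionProperties

__all__ = ["AdaptationParams", "AdaptationState", "AdaptationTrajectory",
           "cell_response", "remodelling_rate", "influence_weight",
           "smooth_rates", "advance_surface", "run_adaptation"]

log = logging.getLogger(__name__)


@dataclass
class AdaptationParams:
    """Thresholds and rate constants of the adaptation law.

    psi_A / psi_R in um/s, C in um per iteration, R in um; the loop stops
    once max masked Delta-Th/Th >= stop_dth or at max_iterations.
    Defaults: the best-correlating apposition threshold (3e-2 um/s), no
    resorption, C = 4.45 um/iteration, R = 150 um, stop at 0.67.
    """

    psi_a: float = 3.0e-2
    psi_r: float = 0.0
    c_um: float = 4.45
    r_um: float = 150.0
    stop_dth: float = 0.67
    max_iterations: int = 400

    def __post_init__(self) -> None:
        if not (self.psi_a > self.psi_r >= 0.0):
            raise ValueError("require psi_A > psi_R >= 0")
        if self.c_um <= 0 or self.r_um <= 0:
            raise ValueError("C and R must be positive")


def cell_response(psi, psi_a: float, psi_r: float = 0.0):
    """On-off cellular output Lambda in {-1, 0, +1}.

    +1 at or above the apposition threshold, -1 at or below the resorption
    threshold when resorption is active; the threshold value itself
    triggers the response.
    """
    psi = np.asarray(psi, dtype=float)
    lam = np.zeros(psi.shape, dtype=np.int8)
    lam[psi >= psi_a] = 1
    if psi_r > 0.0:
        lam[psi <= psi_r] = -1
    return lam if lam.ndim else int(lam)


def remodelling_rate(lam: np.ndarray, dt: float, window: float,
                     c_um: float) -> np.ndarray:
    """u_dot = C * integral(Lambda dt) / T, um per iteration.

    Normalised by the window duration T so that a signal above threshold
    for the whole window yields exactly C; the rate grows with the time
    the stimulus spends above threshold.
    """
    lam = np.asarray(lam, dtype=float)
    return c_um * dt * lam.sum(axis=-1) / window


def influence_weight(r, r_influence: float):
    """Linearly decaying weight of the zone of influence: 1 - r/R, 0 beyond."""
    r = np.asarray(r, dtype=float)
    w = np.clip(1.0 - r / r_influence, 0.0, None)
    return w if w.ndim else float(w)


def smooth_rates(u_dot: np.ndarray, positions_um: np.ndarray,
                 r_um: float) -> np.ndarray:
    """Mean of each node's rate and the weighted average of its neighbours.

    u_bar(n) = 0.5 * (u(n) + sum_m w(r_nm) u(m) / sum_m w(r_nm)) over the
    3-D Euclidean neighbourhood of radius R excluding the node itself;
    isolated nodes keep their own rate.  A max-norm contraction that
    leaves uniform fields unchanged.
    """
    u = np.asarray(u_dot, dtype=float).ravel()
    pos = np.asarray(positions_um, dtype=float).reshape(-1, 3)
    tree = cKDTree(pos)
    pairs = tree.query_pairs(r_um, output_type="ndarray")
    wsum = np.zeros(u.size)
    wavg = np.zeros(u.size)
    if pairs.size:
        d = np.linalg.norm(pos[pairs[:, 0]] - pos[pairs[:, 1]], axis=1)
        w = influence_weight(d, r_um)
        np.add.at(wsum, pairs[:, 0], w)
        np.add.at(wsum, pairs[:, 1], w)
        np.add.at(wavg, pairs[:, 0], w * u[pairs[:, 1]])
        np.add.at(wavg, pairs[:, 1], w * u[pairs[:, 0]])
    has = wsum > 0
    out = u.copy()
    out[has] = 0.5 * (u[has] + wavg[has] / wsum[has])
    return out.reshape(np.shape(u_dot))


@dataclass
class AdaptationState:
    """Geometry state of one iteration of the growth loop."""

    iteration: int
    grid: SurfaceGrid
    cumulative_um: np.ndarray    # (n_z, n_theta) normal displacement
    dth: np.ndarray              # (n_z, n_theta) vs iteration-0 thickness


def advance_surface(state: AdaptationState,
                    u_bar: np.ndarray,
                    th0: np.ndarray) -> AdaptationState:
    """Displace periosteal nodes outward by u_bar along the (radial) normal.

    Thickness and node radius grow by u_bar (the thin-wall surrogate takes
    the normal as radial in-plane); non-adaptive nodes are forced to zero;
    Delta-Th/Th is recomputed against the iteration-0 thickness.
    """
    grid = state.grid
    u = np.asarray(u_bar, dtype=float).reshape(grid.thickness.shape).copy()
    u[~grid.adaptive] = 0.0
    if np.any(u[np.isfinite(u)] < -1e-12):
        raise ValueError("advance_surface requires non-negative rates on "
                         "adaptive nodes (pro-osteogenic model)")
    u = np.clip(u, 0.0, None)
    new = grid.copy()
    radial = new.pos[..., :2] - new.center_um[:, None, :]
    norm = np.linalg.norm(radial, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        radial = radial / norm
    new.pos[..., :2] += u[..., None] * radial
    new.radius += u
    new.thickness += u
    cum = state.cumulative_um + u
    dth = (new.thickness - th0) / th0
    return AdaptationState(state.iteration + 1, new, cum, dth)


def _section_properties_from_grid(grid: SurfaceGrid
                                  ) -> tuple[list[SectionProperties],
                                             np.ndarray]:
    """Per-slice area/centroid/second moments from the polar surrogate.

    Integrates the annular region between r_in = r_out - Th and r_out over
    theta (missing bins interpolated periodically).  Returns the properties
    and the centroid (x, y) per slice in the global frame; the centroid is
    also the beam eccentricity since the load axis passes through x = y = 0.
    """
    nz, nb = grid.thickness.shape
    theta = grid.theta_centers
    dth_w = 2.0 * np.pi / nb
    props: list[SectionProperties] = []
    centroids = np.empty((nz, 2))
    for i in range(nz):
        ro = grid.radius[i].copy()
        th = grid.thickness[i].copy()
        bad = ~np.isfinite(ro) | ~np.isfinite(th)
        if bad.all():
            raise ValueError(f"slice {i}: no defined surface nodes")
        if bad.any():
            good = ~bad
            ro[bad] = np.interp(theta[bad], theta[good], ro[good],
                                period=2.0 * np.pi)
            th[bad] = np.interp(theta[bad], theta[good], th[good],
                                period=2.0 * np.pi)
        ri = np.clip(ro - th, 0.0, None)
        cx0, cy0 = grid.center_um[i]
        r2 = ro ** 2 - ri ** 2
        r3 = ro ** 3 - ri ** 3
        r4 = ro ** 4 - ri ** 4
        area = 0.5 * np.sum(r2) * dth_w
        sx = np.sum(r3 * np.cos(theta)) * dth_w / 3.0
        sy = np.sum(r3 * np.sin(theta)) * dth_w / 3.0
        cx, cy = cx0 + sx / area, cy0 + sy / area
        ixx_c = 0.25 * np.sum(r4 * np.sin(theta) ** 2) * dth_w
        iyy_c = 0.25 * np.sum(r4 * np.cos(theta) ** 2) * dth_w
        ixy_c = 0.25 * np.sum(r4 * np.sin(theta) * np.cos(theta)) * dth_w
        # shift moments from the slice centre to the area centroid
        dx, dy = cx - cx0, cy - cy0
        ixx = ixx_c - area * dy ** 2
        iyy = iyy_c - area * dx ** 2
        ixy = ixy_c - area * dx * dy
        mean = 0.5 * (ixx + iyy)
        half = np.hypot(0.5 * (ixx - iyy), ixy)
        props.append(SectionProperties(area, (cx, cy), ixx, iyy, ixy,
                                       mean - half, mean + half))
        centroids[i] = (cx, cy)
    return props, centroids


@dataclass
class IterationRecord:
    iteration: int
    max_dth: float
    adapted_fraction: float     # share of masked bins with dth > 0.05
    dth: np.ndarray             # float32 snapshot


@dataclass
class AdaptationTrajectory:
    """Full history of a growth simulation."""

    records: list[IterationRecord]
    final: AdaptationState
    terminated_by: str           # "stop_criterion" | "max_iterations"
    mask: np.ndarray             # bins entering the stop criterion

    @property
    def iterations(self) -> int:
        return self.final.iteration

    @property
    def max_dth(self) -> float:
        return self.records[-1].max_dth if self.records else 0.0

    def adapted_fraction(self, threshold: float = 0.05) -> float:
        dth = self.final.dth[self.mask]
        return float(np.mean(dth > threshold)) if dth.size else 0.0

    def summary(self) -> dict:
        return {"iterations": self.iterations,
                "terminated_by": self.terminated_by,
                "max_dth": self.max_dth,
                "adapted_fraction": self.adapted_fraction(),
                "n_masked_bins": int(self.mask.sum())}


def run_adaptation(geometry: BoneVolume | SurfaceGrid,
                   params: AdaptationParams | None = None,
                   material: PoroMaterial | None = None,
                   waveform: LoadWaveform | None = None,
                   n_x: int = 200,
                   bc: str = "drained",
                   n_theta_bins: int = 180,
                   adaptive_z_range: tuple[float, float] = (0.1, 0.9),
                   mask: np.ndarray | None = None,
                   record_maps: bool = True) -> AdaptationTrajectory:
    """Iterate strain -> consolidation -> stimulus -> growth to the stop rule.

    Accepts a bone volume (the surface grid is built from its rasters) or
    a pre-built grid.  Section properties, eccentricity, and the stimulus
    are recomputed on the grown geometry every iteration.  ``mask``
    optionally restricts the stop criterion and reporting to a subset of
    bins (default: all adaptive bins).
    """
    params = params or AdaptationParams()
    material = material or PoroMaterial()
    waveform = waveform or LoadWaveform.trapezoid()

    if isinstance(geometry, SurfaceGrid):
        grid = geometry.copy()
    else:
        grid = build_surface_grid(geometry, n_theta_bins, adaptive_z_range)
    th0 = grid.thickness.copy()
    region = grid.adaptive if mask is None else (mask & grid.adaptive)
    if not region.any():
        raise ValueError("no adaptive bins selected by the mask")

    state = AdaptationState(0, grid, np.zeros_like(th0),
                            np.zeros_like(th0))
    records: list[IterationRecord] = []
    terminated = "max_iterations"
    dt, window = waveform.dt, waveform.window

    for it in range(1, params.max_iterations + 1):
        try:
            props, centroids = _section_properties_from_grid(state.grid)
            eps_peak = np.full(th0.shape, np.nan)
            for i, pr in enumerate(props):
                pts = state.grid.pos[i, :, :2] - np.asarray(pr.centroid_um)
                # load axis through x = y = 0: its offset from the centroid
                ecc = (-pr.centroid_um[0], -pr.centroid_um[1])
                eps_peak[i] = beam_strain(pr, ecc, waveform.peak,
                                          material.e_z_mpa, pts)
            stim = stimulus_for_sectors(material, state.grid.thickness,
                                        eps_peak, waveform, n_x=n_x, bc=bc)
            lam = cell_response(stim.psi_um_s, params.psi_a, params.psi_r)
            u_dot = remodelling_rate(lam, dt, window, params.c_um)
            u_dot = u_dot.reshape(th0.shape)
            u_dot[~state.grid.adaptive] = 0.0
            ok = ~state.grid.missing
            u_bar = np.zeros_like(u_dot)
            u_bar[ok] = smooth_rates(u_dot[ok], state.grid.pos[ok],
                                     params.r_um)
            state = advance_surface(state, u_bar, th0)
        except Exception as exc:
            raise RuntimeError(f"adaptation iteration {it} failed: {exc}"
                               ) from exc

        dth_region = state.dth[region & np.isfinite(state.dth)]
        max_dth = float(dth_region.max()) if dth_region.size else 0.0
        frac = float(np.mean(dth_region > 0.05)) if dth_region.size else 0.0
        records.append(IterationRecord(
            it, max_dth, frac,
            state.dth.astype(np.float32) if record_maps else None))
        log.info("iteration %d: max dTh/Th=%.4f adapted=%.3f",
                 it, max_dth, frac)
        if max_dth >= params.stop_dth:
            terminated = "stop_criterion"
            break

    return AdaptationTrajectory(records, state, terminated, region)
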