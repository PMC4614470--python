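"""1-D Biot consolidation through the cortical wall and the fluid stimulus.

Each (theta, Z) sector of the wall is treated as an independent 1-D
poroelastic column of length L (the local wall thickness) spanning the
periosteal face (x = 0) to the endosteal face (x = L).  Loading enters as
the uniaxial strain history of the sector, driving the pore-pressure
diffusion equation

    S dp/dt - (k_l / mu) d2p/dx2 = -alpha d(eps_zz)/dt,

with drained faces (p = 0; the membranes are orders of magnitude more
permeable than the lacunar-canalicular porosity) or an optional Robin
membrane-conductance condition.  The Darcy velocity V = -(k_l/mu) dp/dx
evaluated at the periosteal face is the mechanical stimulus Psi = |V|,
reported in um/s.

Discretisation: Crank-Nicolson in time with two backward-Euler startup
steps (damps the spurious oscillations of trapezoidal time stepping on
rough initial data), second-order central differences in space; the scheme
is unconditionally stable and discretely conservative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .mechanics import LoadWaveform

__all__ = ["PoroMaterial", "PoroSolution", "StimulusHistory",
           "storage_coefficient", "solve_consolidation", "surface_stimulus",
           "stimulus_for_sectors"]

log = logging.getLogger(__name__)

_RANNACHER_STEPS = 2


@dataclass
class PoroMaterial:
    """Transversely isotropic poroelastic cortical bone + interstitial fluid.

    Elastic moduli in MPa, permeabilities in m^2, viscosity in Pa s.
    ``gamma_n_m3`` (fluid specific weight) is carried as metadata only.
    ``storage_model`` selects the constitutive closure for the storage
    coefficient: "full" includes solid-grain compressibility via the
    drained bulk modulus, "stiff-grain" keeps only the fluid term phi/K_f.
    """

    e_z_mpa: float = 17.0e3
    e_t_mpa: float = 11.5e3
    nu_t: float = 0.38
    nu_lt: float = 0.41
    g_t_mpa: float = 4.1e3
    g_lt_mpa: float = 5.2e3
    phi: float = 0.05
    k_l_m2: float = 1e-22
    k_t_m2: float = 1e-23
    alpha: float = 0.14
    k_f_mpa: float = 2.3e3
    mu_pa_s: float = 8.9e-4
    gamma_n_m3: float = 9.8e3
    k_membrane_m2: float = 1e-17
    t_membrane_um: float = 10.0
    storage_model: str = "full"

    def __post_init__(self) -> None:
        if not (self.k_l_m2 > 0 and self.mu_pa_s > 0 and self.k_f_mpa > 0):
            raise ValueError("permeability, viscosity, K_f must be positive")
        if not (0.0 < self.phi < 1.0):
            raise ValueError("pore volume fraction must lie in (0, 1)")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("effective stress coefficient must be in (0, 1]")
        if self.storage_model not in ("full", "stiff-grain"):
            raise ValueError("storage_model must be 'full' or 'stiff-grain'")

    @property
    def mobility(self) -> float:
        """k_l / mu in m^2 / (Pa s)."""
        return self.k_l_m2 / self.mu_pa_s

    def consolidation_coefficient(self) -> float:
        """c = (k_l / mu) / S in m^2/s."""
        return self.mobility / storage_coefficient(self)


def storage_coefficient(mat: PoroMaterial) -> float:
    """Storage coefficient S in 1/Pa.

    Full closure: S = phi/K_f + (alpha - phi)/K_s with the solid-grain
    modulus K_s = K_d / (1 - alpha) and the drained bulk modulus K_d taken
    from the isotropic reduction of the longitudinal constants,
    K_d = E_z / (3 (1 - 2 nu_lt)).  Falls back to the stiff-grain form
    phi/K_f when alpha <= phi makes the full form ill-posed.
    """
    k_f = mat.k_f_mpa * 1e6
    s_fluid = mat.phi / k_f
    if mat.storage_model == "stiff-grain":
        return s_fluid
    if mat.alpha <= mat.phi:
        log.warning("alpha <= phi: full storage closure ill-posed, "
                    "falling back to stiff-grain")
        return s_fluid
    k_d = mat.e_z_mpa * 1e6 / (3.0 * (1.0 - 2.0 * mat.nu_lt))
    k_s = k_d / (1.0 - mat.alpha)
    return s_fluid + (mat.alpha - mat.phi) / k_s


@dataclass
class PoroSolution:
    """Pressure and Darcy velocity on the through-wall grid over time.

    x = 0 is the periosteal face, x = L the endosteal face.  ``theta``
    records the time-stepping weight used at each step (1 = backward
    Euler startup, 0.5 = Crank-Nicolson) so that discrete balance checks
    can mirror the scheme exactly.
    """

    x_um: np.ndarray       # (n_x,)
    times: np.ndarray      # (n_frames,)
    p_pa: np.ndarray       # (n_x, n_frames)
    v_um_s: np.ndarray     # (n_x, n_frames)
    theta: np.ndarray      # (n_frames,)


def _solve_tridiag_batch(lower, diag, upper, rhs):
    """Thomas algorithm vectorised over the leading (batch) axis.

    All arrays are (B, N); lower[:, 0] and upper[:, -1] are ignored.
    """
    b, n = rhs.shape
    cp = np.empty_like(rhs)
    dp = np.empty_like(rhs)
    cp[:, 0] = upper[:, 0] / diag[:, 0]
    dp[:, 0] = rhs[:, 0] / diag[:, 0]
    for i in range(1, n):
        denom = diag[:, i] - lower[:, i] * cp[:, i - 1]
        cp[:, i] = upper[:, i] / denom
        dp[:, i] = (rhs[:, i] - lower[:, i] * dp[:, i - 1]) / denom
    x = np.empty_like(rhs)
    x[:, -1] = dp[:, -1]
    for i in range(n - 2, -1, -1):
        x[:, i] = dp[:, i] - cp[:, i] * x[:, i + 1]
    return x


def _consolidation_batch(mat: PoroMaterial, length_m: np.ndarray,
                         strain: np.ndarray, dt: float, n_x: int,
                         bc: str = "drained",
                         p_init_pa: np.ndarray | None = None,
                         rannacher: int = _RANNACHER_STEPS):
    """Solve B independent columns; returns (p, theta_per_step).

    ``length_m`` is (B,); ``strain`` is (B, n_frames) sampled on the frame
    times (strain at t = 0 is taken as 0).  Output p is (B, n_x,
    n_frames + 1) including the initial state at index 0.
    """
    length_m = np.atleast_1d(np.asarray(length_m, dtype=float))
    strain = np.atleast_2d(np.asarray(strain, dtype=float))
    b = length_m.size
    n_frames = strain.shape[1]
    s_coef = storage_coefficient(mat)
    c = mat.mobility / s_coef
    dx = length_m / (n_x - 1)
    r = (c * dt / dx ** 2)[:, None]              # (B, 1)
    alpha_over_s = mat.alpha / s_coef

    robin = bc == "robin"
    if bc not in ("drained", "robin"):
        raise ValueError("bc must be 'drained' or 'robin'")
    beta = mat.k_membrane_m2 / (mat.mu_pa_s * mat.t_membrane_um * 1e-6)

    p = np.zeros((b, n_x, n_frames + 1))
    if p_init_pa is not None:
        p[:, :, 0] = p_init_pa
    thetas = np.empty(n_frames)

    ones = np.ones((b, n_x))
    prev_strain = np.zeros(b)
    state = p[:, :, 0].copy()
    for step in range(n_frames):
        theta = 1.0 if step < rannacher else 0.5
        thetas[step] = theta
        d_eps = strain[:, step] - prev_strain
        prev_strain = strain[:, step]
        source = -alpha_over_s * d_eps              # dt * q, (B,)

        lower = np.zeros((b, n_x))
        upper = np.zeros((b, n_x))
        diag = ones.copy()
        rhs = state.copy()
        # interior rows
        lower[:, 1:-1] = -theta * r
        upper[:, 1:-1] = -theta * r
        diag[:, 1:-1] = 1.0 + 2.0 * theta * r
        lap = state[:, 2:] - 2.0 * state[:, 1:-1] + state[:, :-2]
        rhs[:, 1:-1] = state[:, 1:-1] + (1.0 - theta) * r * lap \
            + source[:, None]
        if robin:
            # half-cell balance at each face with membrane conductance beta
            g = 2.0 * beta * dt / (s_coef * dx)          # (B,)
            for face, inner in ((0, 1), (n_x - 1, n_x - 2)):
                diag[:, face] = 1.0 + theta * (2.0 * r[:, 0] + g)
                coef = -theta * 2.0 * r[:, 0]
                if face == 0:
                    upper[:, 0] = coef
                else:
                    lower[:, -1] = coef
                expl = (2.0 * r[:, 0] * (state[:, inner] - state[:, face])
                        - g * state[:, face])
                rhs[:, face] = state[:, face] + (1.0 - theta) * expl + source
        else:
            rhs[:, 0] = 0.0
            rhs[:, -1] = 0.0
        state = _solve_tridiag_batch(lower, diag, upper, rhs)
        if not np.all(np.isfinite(state)):
            raise FloatingPointError("NaN in consolidation solve")
        p[:, :, step + 1] = state
    return p, thetas


def _darcy_velocity(p: np.ndarray, dx_m: np.ndarray,
                    mobility: float) -> np.ndarray:
    """V = -(k/mu) dp/dx in um/s; one-sided second order at the faces."""
    grad = np.empty_like(p)
    grad[:, 1:-1] = (p[:, 2:] - p[:, :-2]) / 2.0
    grad[:, 0] = (-3.0 * p[:, 0] + 4.0 * p[:, 1] - p[:, 2]) / 2.0
    grad[:, -1] = (3.0 * p[:, -1] - 4.0 * p[:, -2] + p[:, -3]) / 2.0
    grad = grad / dx_m[:, None, None]
    return -mobility * grad * 1e6


def solve_consolidation(mat: PoroMaterial, length_um: float,
                        strain: np.ndarray, times: np.ndarray,
                        n_x: int = 200, bc: str = "drained",
                        p_init_pa: np.ndarray | None = None) -> PoroSolution:
    """Consolidation of a single sector driven by its strain history.

    ``strain`` gives eps_zz at each frame time (zero at t = 0); an optional
    uniform or per-node initial pressure supports relaxation benchmarks.
    """
    if n_x < 50:
        raise ValueError("n_x must be >= 50")
    times = np.asarray(times, dtype=float)
    dt = times[1] - times[0] if times.size > 1 else times[0]
    length_m = np.array([length_um * 1e-6])
    init = None
    if p_init_pa is not None:
        init = np.broadcast_to(np.asarray(p_init_pa, dtype=float),
                               (1, n_x)).copy()
    p, thetas = _consolidation_batch(mat, length_m,
                                     np.atleast_2d(strain), dt, n_x, bc,
                                     p_init_pa=init)
    dx_m = length_m / (n_x - 1)
    v = _darcy_velocity(p, dx_m, mat.mobility)
    x = np.linspace(0.0, length_um, n_x)
    return PoroSolution(x, times, p[0, :, 1:], v[0, :, 1:], thetas)


@dataclass
class StimulusHistory:
    """Psi(node, frame): fluid-velocity magnitude at the periosteal face."""

    psi_um_s: np.ndarray    # (n_nodes, n_frames), >= 0
    times: np.ndarray


def surface_stimulus(solutions: list[PoroSolution]) -> StimulusHistory:
    """Stack the periosteal-face |V| of per-sector solutions."""
    times = solutions[0].times
    for s in solutions[1:]:
        if not np.allclose(s.times, times):
            raise ValueError("solutions must share a common time grid")
    psi = np.vstack([np.abs(s.v_um_s[0]) for s in solutions])
    return StimulusHistory(psi, times)


def stimulus_for_sectors(mat: PoroMaterial, wall_um: np.ndarray,
                         peak_strain: np.ndarray, waveform: LoadWaveform,
                         n_x: int = 200, bc: str = "drained",
                         quantize_um: float = 0.5) -> StimulusHistory:
    """Stimulus for many sectors, batched by quantised wall thickness.

    The consolidation problem is linear and every sector shares the load
    waveform shape, so the solution for a sector equals its peak strain
    times the unit-peak-strain solution for its wall thickness.  Walls are
    quantised to ``quantize_um`` (below raster resolution) and one batch
    solve per unique thickness serves all sectors.  Sectors with
    non-finite wall or strain get zero stimulus.
    """
    wall = np.asarray(wall_um, dtype=float).ravel()
    g = np.asarray(peak_strain, dtype=float).ravel()
    ok = np.isfinite(wall) & np.isfinite(g) & (wall > 0)
    frames = waveform.times.size
    psi = np.zeros((wall.size, frames))
    if ok.any():
        q = np.round(wall[ok] / quantize_um).astype(np.int64)
        uniq, inverse = np.unique(q, return_inverse=True)
        lengths_m = uniq * quantize_um * 1e-6
        unit_strain = np.tile(waveform.normalized(), (uniq.size, 1))
        dt = waveform.dt
        p, _ = _consolidation_batch(mat, lengths_m, unit_strain, dt, n_x, bc)
        dx_m = lengths_m / (n_x - 1)
        v = _darcy_velocity(p, dx_m, mat.mobility)
        v_face = np.abs(v[:, 0, 1:])                     # (U, frames)
        psi[ok] = np.abs(g[ok])[:, None] * v_face[inverse]
    return StimulusHistory(psi, waveform.times)
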