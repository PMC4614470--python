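"""Reduced-order structural response: trapezoidal load cycle and beam strain.

The tibia is treated as a slender beam under eccentric axial compression:
each cross section carries the full axial force applied along the fixed
load axis, which is offset from the section centroid by the local
eccentricity e(Z).  The longitudinal strain at a boundary point follows
from static equivalence -- the internal stress distribution sigma(x, y) =
sigma_0 + a x + b y must integrate to the applied force and to its first
moments about the centroid.  Compression is negative.  The structure is
quasi-static: strain follows the force waveform instantaneously.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .thickness import SectionProperties

__all__ = ["LoadWaveform", "make_time_grid", "trapezoid_force",
           "beam_strain", "strain_gradient"]

#: defaults of the murine axial-loading protocol
PEAK_FORCE_N = 13.0
RAMP_S = 0.025
HOLD_S = 0.05
WINDOW_S = 0.5
DT_S = 0.005


def make_time_grid(window: float = WINDOW_S, dt: float = DT_S) -> np.ndarray:
    """Frame times dt, 2 dt, ..., window (steps after t = 0).

    One 0.5 s window at dt = 0.005 s gives exactly 100 frames: a single
    0.1 s load cycle plus the 0.4 s pressure-relaxation tail.
    """
    if dt <= 0 or window <= 0:
        raise ValueError("window and dt must be positive")
    n = window / dt
    if abs(n - round(n)) > 1e-9 * max(1.0, n):
        raise ValueError(f"dt={dt} does not divide window={window}")
    n = int(round(n))
    return dt * np.arange(1, n + 1)


def trapezoid_force(t, peak: float = PEAK_FORCE_N, ramp: float = RAMP_S,
                    hold: float = HOLD_S):
    """Trapezoidal load cycle: linear ramp up, peak hold, ramp down, rest."""
    t = np.asarray(t, dtype=float)
    up = peak * t / ramp
    down = peak * (2 * ramp + hold - t) / ramp
    f = np.where(t < ramp, up,
                 np.where(t <= ramp + hold, peak,
                          np.where(t <= 2 * ramp + hold, down, 0.0)))
    return np.clip(f, 0.0, peak) if f.ndim else float(np.clip(f, 0.0, peak))


@dataclass
class LoadWaveform:
    """Force samples of one load cycle on the solver time grid."""

    times: np.ndarray
    force: np.ndarray
    peak: float

    @classmethod
    def trapezoid(cls, peak: float = PEAK_FORCE_N, ramp: float = RAMP_S,
                  hold: float = HOLD_S, window: float = WINDOW_S,
                  dt: float = DT_S) -> "LoadWaveform":
        t = make_time_grid(window, dt)
        return cls(t, trapezoid_force(t, peak, ramp, hold), peak)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def window(self) -> float:
        return float(self.times[-1])

    def normalized(self) -> np.ndarray:
        """Force scaled to unit peak (shared shape across all sectors)."""
        return self.force / self.peak


def strain_gradient(props: SectionProperties,
                    eccentricity_um: tuple[float, float],
                    force_n: float, e_z_mpa: float
                    ) -> tuple[float, float, float]:
    """(epsilon_0, d eps/dx, d eps/dy) of the linear strain field, 1/um.

    Static equivalence of sigma = sigma_0 + a x + b y (x, y about the
    centroid) with a compressive force F applied at the eccentricity point:
        int sigma dA = -F,  int sigma x dA = -F e_x,  int sigma y dA = -F e_y
    so sigma_0 = -F/A and (a, b) solve the 2x2 system with the second-
    moment tensor.  e_x > 0 therefore deepens compression on the +x side.
    """
    area = props.area_um2
    if area <= 0:
        raise ValueError("section area must be positive")
    det = props.I_xx * props.I_yy - props.I_xy ** 2
    if det <= 0:
        raise ValueError("second-moment tensor must be positive definite")
    ex, ey = eccentricity_um
    # N/um^2 stress units; E in MPa = N/mm^2 = 1e-6 N/um^2
    e_z = e_z_mpa * 1e-6
    sigma0 = -force_n / area
    m_x = -force_n * ex   # int sigma x dA
    m_y = -force_n * ey   # int sigma y dA
    a = (m_x * props.I_xx - m_y * props.I_xy) / det
    b = (m_y * props.I_yy - m_x * props.I_xy) / det
    return sigma0 / e_z, a / e_z, b / e_z


def beam_strain(props: SectionProperties,
                eccentricity_um: tuple[float, float],
                force_n: float, e_z_mpa: float,
                points_um: np.ndarray) -> np.ndarray:
    """Longitudinal strain at boundary points (x, y in um, centroid frame).

    With zero eccentricity this reduces to uniform compression
    -F / (E_z A); with eccentricity it adds the unsymmetric-bending
    gradient.  Linear in the applied force.
    """
    eps0, dedx, dedy = strain_gradient(props, eccentricity_um, force_n,
                                       e_z_mpa)
    pts = np.asarray(points_um, dtype=float)
    return eps0 + dedx * pts[..., 0] + dedy * pts[..., 1]
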