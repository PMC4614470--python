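"""Versioned YAML run configuration.

Keys carry their units in their names (peak_force_N, psi_A_um_s, ...) to
keep the stimulus-threshold and modulus units unambiguous; unknown keys are
rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import yaml

from .adaptation import AdaptationParams
from .geometry import BoneShapeParams, Landmark
from .mechanics import LoadWaveform
from .poroelastic import PoroMaterial

__all__ = ["RunConfig", "ConfigError", "load_config"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Invalid or malformed run configuration."""


def _take(d: dict, section: str, allowed: dict) -> dict:
    """Pop known keys with defaults; reject unknown ones."""
    unknown = set(d) - set(allowed)
    if unknown:
        raise ConfigError(
            f"unknown key(s) in '{section}': {sorted(unknown)}")
    return {k: d.get(k, v) for k, v in allowed.items()}


@dataclass
class FieldBump:
    """One Gaussian component of the injected ground-truth thickening."""

    theta_deg: float
    z_center: float
    amplitude: float          # Delta-Th/Th at the bump centre
    sigma_theta_deg: float = 25.0
    sigma_z: float = 0.2


@dataclass
class RunConfig:
    seed: int = 0
    geometry: BoneShapeParams = field(default_factory=BoneShapeParams)
    load_peak_n: float = 13.0
    load_ramp_s: float = 0.025
    load_hold_s: float = 0.05
    solver_window_s: float = 0.5
    solver_dt_s: float = 0.005
    solver_n_x: int = 200
    solver_bc: str = "drained"
    material: PoroMaterial = field(default_factory=PoroMaterial)
    adaptation: AdaptationParams = field(default_factory=AdaptationParams)
    n_theta_bins: int = 180
    adaptive_z_range: tuple[float, float] = (0.1, 0.9)
    mask_regions: list[tuple[float, float, float, float]] | None = None
    field_bumps: list[FieldBump] = field(default_factory=list)
    stack_format: str = "png"

    def waveform(self) -> LoadWaveform:
        return LoadWaveform.trapezoid(self.load_peak_n, self.load_ramp_s,
                                      self.load_hold_s, self.solver_window_s,
                                      self.solver_dt_s)


_GEOMETRY_KEYS = dict(
    n_slices=100, pixel_size_um=1.0, pixels=None, length_um=10_000.0,
    outer_radius_prox_um=600.0, outer_radius_dist_um=480.0,
    wall_prox_um=220.0, wall_dist_um=150.0, landmarks=None,
    ecc_amplitude_um=500.0, ecc_azimuth_deg=120.0, ecc_wobble_um=40.0,
    noise_amplitude_um=0.0,
)
_LANDMARK_KEYS = dict(theta_center_deg=None, width_deg=None,
                      amplitude_um=None, z_min=0.0, z_max=1.0)
_LOAD_KEYS = dict(peak_force_N=13.0, ramp_s=0.025, hold_s=0.05)
_SOLVER_KEYS = dict(window_s=0.5, dt_s=0.005, n_x=200, bc="drained")
_MATERIAL_KEYS = dict(
    E_z_MPa=17.0e3, E_t_MPa=11.5e3, nu_t=0.38, nu_lt=0.41, G_t_MPa=4.1e3,
    G_lt_MPa=5.2e3, phi=0.05, k_l_m2=1e-22, k_t_m2=1e-23, alpha=0.14,
    K_f_MPa=2.3e3, mu_Pa_s=8.9e-4, gamma_N_m3=9.8e3, k_membrane_m2=1e-17,
    t_membrane_um=10.0, storage_model="full",
)
_ADAPT_KEYS = dict(psi_A_um_s=3.0e-2, psi_R_um_s=0.0, C_um_per_iter=4.45,
                   R_um=150.0, stop_dth=0.67, max_iterations=400,
                   n_theta_bins=180, adaptive_z_min=0.1, adaptive_z_max=0.9)
_FIELD_KEYS = dict(theta_deg=None, z_center=None, amplitude=None,
                   sigma_theta_deg=25.0, sigma_z=0.2)
_TOP_KEYS = ("schema_version", "seed", "geometry", "load", "solver",
             "material", "adaptation", "mask_regions", "thickening_field",
             "stack_format")


def _default_landmarks() -> list[dict]:
    return [dict(theta_center_deg=300.0, width_deg=50.0, amplitude_um=130.0),
            dict(theta_center_deg=50.0, width_deg=35.0, amplitude_um=100.0,
                 z_max=0.55),
            dict(theta_center_deg=220.0, width_deg=30.0, amplitude_um=60.0,
                 z_min=0.1, z_max=0.7),
            dict(theta_center_deg=160.0, width_deg=30.0, amplitude_um=50.0,
                 z_max=0.4)]


def _default_field() -> list[dict]:
    # ground-truth thickening of the "loaded" limb: growth concentrated on
    # the crest (compressed) sector with a weaker medial (tensile) patch
    return [dict(theta_deg=300.0, z_center=0.5, amplitude=0.6,
                 sigma_theta_deg=30.0, sigma_z=0.25),
            dict(theta_deg=120.0, z_center=0.5, amplitude=0.35,
                 sigma_theta_deg=25.0, sigma_z=0.2)]


def config_from_dict(data: dict) -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigError("configuration must be a mapping")
    unknown = set(data) - set(_TOP_KEYS)
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    version = data.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version {version}")

    try:
        g = _take(dict(data.get("geometry") or {}), "geometry",
                  _GEOMETRY_KEYS)
        lm_specs = g.pop("landmarks")
        if lm_specs is None:
            lm_specs = _default_landmarks()
        landmarks = []
        for spec in lm_specs:
            lk = _take(dict(spec), "geometry.landmarks", _LANDMARK_KEYS)
            if None in (lk["theta_center_deg"], lk["width_deg"],
                        lk["amplitude_um"]):
                raise ConfigError("landmark needs theta_center_deg, "
                                  "width_deg, amplitude_um")
            landmarks.append(Landmark(math.radians(lk["theta_center_deg"]),
                                      math.radians(lk["width_deg"]),
                                      lk["amplitude_um"],
                                      (lk["z_min"], lk["z_max"])))
        geometry = BoneShapeParams(
            n_slices=int(g["n_slices"]), pixel_size=float(g["pixel_size_um"]),
            pixels=g["pixels"], length_um=float(g["length_um"]),
            outer_radius_prox_um=float(g["outer_radius_prox_um"]),
            outer_radius_dist_um=float(g["outer_radius_dist_um"]),
            wall_prox_um=float(g["wall_prox_um"]),
            wall_dist_um=float(g["wall_dist_um"]),
            landmarks=landmarks,
            ecc_amplitude_um=float(g["ecc_amplitude_um"]),
            ecc_azimuth_rad=math.radians(float(g["ecc_azimuth_deg"])),
            ecc_wobble_um=float(g["ecc_wobble_um"]),
            noise_amplitude_um=float(g["noise_amplitude_um"]),
            seed=int(data.get("seed", 0)))
        geometry.validate()

        ld = _take(dict(data.get("load") or {}), "load", _LOAD_KEYS)
        sv = _take(dict(data.get("solver") or {}), "solver", _SOLVER_KEYS)
        mt = _take(dict(data.get("material") or {}), "material",
                   _MATERIAL_KEYS)
        material = PoroMaterial(
            e_z_mpa=mt["E_z_MPa"], e_t_mpa=mt["E_t_MPa"], nu_t=mt["nu_t"],
            nu_lt=mt["nu_lt"], g_t_mpa=mt["G_t_MPa"], g_lt_mpa=mt["G_lt_MPa"],
            phi=mt["phi"], k_l_m2=mt["k_l_m2"], k_t_m2=mt["k_t_m2"],
            alpha=mt["alpha"], k_f_mpa=mt["K_f_MPa"], mu_pa_s=mt["mu_Pa_s"],
            gamma_n_m3=mt["gamma_N_m3"],
            k_membrane_m2=mt["k_membrane_m2"],
            t_membrane_um=mt["t_membrane_um"],
            storage_model=mt["storage_model"])

        ad = _take(dict(data.get("adaptation") or {}), "adaptation",
                   _ADAPT_KEYS)
        adaptation = AdaptationParams(
            psi_a=ad["psi_A_um_s"], psi_r=ad["psi_R_um_s"],
            c_um=ad["C_um_per_iter"], r_um=ad["R_um"],
            stop_dth=ad["stop_dth"],
            max_iterations=int(ad["max_iterations"]))

        regions = data.get("mask_regions")
        mask_regions = None
        if regions is not None:
            mask_regions = []
            for r in regions:
                rk = _take(dict(r), "mask_regions",
                           dict(theta_min_deg=0.0, theta_max_deg=360.0,
                                z_min=0.0, z_max=1.0))
                mask_regions.append((math.radians(rk["theta_min_deg"]),
                                     math.radians(rk["theta_max_deg"]),
                                     rk["z_min"], rk["z_max"]))

        f_specs = data.get("thickening_field")
        if f_specs is None:
            f_specs = _default_field()
        bumps = []
        for spec in f_specs:
            fk = _take(dict(spec), "thickening_field", _FIELD_KEYS)
            if None in (fk["theta_deg"], fk["z_center"], fk["amplitude"]):
                raise ConfigError("field bump needs theta_deg, z_center, "
                                  "amplitude")
            bumps.append(FieldBump(fk["theta_deg"], fk["z_center"],
                                   fk["amplitude"], fk["sigma_theta_deg"],
                                   fk["sigma_z"]))

        fmt = data.get("stack_format", "png")
        if fmt not in ("png", "tiff", "bmp"):
            raise ConfigError("stack_format must be png, tiff or bmp")

        return RunConfig(
            seed=int(data.get("seed", 0)), geometry=geometry,
            load_peak_n=float(ld["peak_force_N"]),
            load_ramp_s=float(ld["ramp_s"]), load_hold_s=float(ld["hold_s"]),
            solver_window_s=float(sv["window_s"]),
            solver_dt_s=float(sv["dt_s"]), solver_n_x=int(sv["n_x"]),
            solver_bc=sv["bc"], material=material, adaptation=adaptation,
            n_theta_bins=int(ad["n_theta_bins"]),
            adaptive_z_range=(float(ad["adaptive_z_min"]),
                              float(ad["adaptive_z_max"])),
            mask_regions=mask_regions, field_bumps=bumps, stack_format=fmt)
    except ConfigError:
        raise
    except (TypeError, ValueError, KeyError) as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})


def evaluate_field(bumps: list[FieldBump], theta_centers, z) -> "np.ndarray":
    """Sample the Gaussian ground-truth field on an (n_z, n_theta) grid."""
    import numpy as np

    theta = np.asarray(theta_centers)
    z = np.asarray(z)
    out = np.zeros((z.size, theta.size))
    for b in bumps:
        d = np.angle(np.exp(1j * (theta - math.radians(b.theta_deg))))
        st = math.radians(b.sigma_theta_deg)
        gt = np.exp(-0.5 * (d / st) ** 2)
        gz = np.exp(-0.5 * ((z - b.z_center) / b.sigma_z) ** 2)
        out += b.amplitude * gz[:, None] * gt[None, :]
    return out
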