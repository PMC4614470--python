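# cortadapt

Predictive simulation of load-induced cortical bone adaptation in the
mouse tibia, at desk scale.

Axial compression of the murine tibia is a standard model for studying how
bone adds mass where it is mechanically needed. `cortadapt` implements the
full in-silico side of that experiment as a reproducible pipeline:

1. **Synthetic geometry** — parametric binary image stacks of a curved,
   hollow tibia-like diaphysis (angular crest landmarks, proximal→distal
   taper, centroid eccentricity that turns axial load into mediolateral
   bending), plus paired "loaded" stacks produced by a known ground-truth
   thickening field.
2. **Thickness mapping** — cortical thickness Th at every periosteal pixel
   as the shortest distance to the endosteal boundary, averaged into 2°
   azimuthal bins, expressed in cylindrical coordinates (Th, θ, Z); paired
   maps give the relative change ΔTh/Th = (Th_R − Th_L)/Th_L.
3. **Mechanics** — a 13 N trapezoidal load cycle (0.025 s ramps, 0.05 s
   hold) resolved at dt = 0.005 s over a 0.5 s window; longitudinal strain
   ε_zz per (θ, Z) sector from unsymmetric beam bending under eccentric
   axial compression.
4. **Poroelasticity** — 1-D Biot consolidation through the cortical wall
   per sector,

       S ∂p/∂t − (k_l/μ) ∂²p/∂x² = −α ∂ε_zz/∂t,

   with drained faces, solved by Crank–Nicolson; the Darcy fluid velocity
   V = −(k_l/μ) ∂p/∂x at the periosteal face is the mechanical stimulus
   Ψ = |V| (µm/s).
5. **Adaptation law** — an on–off cellular response Λ ∈ {−1, 0, +1} with
   thresholds Ψ_A (apposition) and Ψ_R (resorption, off by default),
   integrated over the load window into a remodelling rate
   u̇ = C·∫Λ dt / T (C = 4.45 µm/iteration), spatially averaged over a
   150 µm zone of influence with linearly decaying weights, and applied as
   outward periosteal growth until the maximum masked ΔTh/Th reaches 0.67.
6. **Validation statistics** — Kendall's τ-b rank correlation (with a
   Kolmogorov–Smirnov normality check motivating the non-parametric
   choice) between observed and predicted ΔTh/Th maps.

Material constants default to transversely isotropic cortical bone
(E_z = 17 GPa, k_l = 10⁻²² m², α = 0.14, φ = 5%) with saline-like
interstitial fluid (μ = 8.9·10⁻⁴ Pa·s, K_f = 2.3 GPa).

## Worked example

A reduced-resolution run (50 slices, 2 µm/px rasters, 90 angular sectors)
of the default study conditions:

```python
import numpy as np
from cortadapt import (AdaptationParams, run_adaptation, make_bone_volume,
                       build_surface_grid, default_params)

params = default_params()
params.n_slices = 50          # half axial resolution for a quick run
params.pixel_size = 2.0       # 2 um/px rasters

volume = make_bone_volume(params)
grid = build_surface_grid(volume, n_theta_bins=90,
                          adaptive_z_range=(0.1, 0.9))
traj = run_adaptation(grid, AdaptationParams())

print(f"terminated by : {traj.terminated_by}")
print(f"iterations    : {traj.iterations}")
print(f"max dTh/Th    : {traj.max_dth:.3f}")
print(f"adapted area  : {traj.adapted_fraction():.2f}")
dth = np.nanmean(traj.final.dth, axis=0)
deg = np.degrees(grid.theta_centers)
for a in (120, 300):
    k = np.abs(np.angle(np.exp(1j*np.radians(deg-a)))) < np.radians(25)
    print(f"mean dTh/Th within 25 deg of {a:3d} deg: {dth[k].mean():.3f}")
```

prints

```
terminated by : stop_criterion
iterations    : 100
max dTh/Th    : 0.673
adapted area  : 0.76
mean dTh/Th within 25 deg of 120 deg: 0.122
mean dTh/Th within 25 deg of 300 deg: 0.366
```

The loop stops when a region of the diaphysis reaches the experimental
maximum relative thickening (ΔTh/Th ≥ 0.67). Growth concentrates on the
compressed interosseous-crest sector (300°) and, more weakly, on the
tensile medial-analogue sector (120°) — the two regions where bending
drives high interstitial fluid velocity — while 76% of diaphyseal bins
show appreciable (> 0.05) thickening at this threshold.

## Command-line interface

```sh
cortadapt generate      --config run.yaml --out out/   # stack pair + ground truth
cortadapt map-thickness out/control out/loaded --out maps/
cortadapt simulate      out/control --config run.yaml --out sim/ [--sweep]
cortadapt compare       maps/dth.csv sim/predicted_dth.csv --out report/
```

All parameters live in a versioned YAML config with units embedded in key
names (`peak_force_N`, `psi_A_um_s`, …); unknown keys are rejected. Every
command is deterministic given (config, seed).

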