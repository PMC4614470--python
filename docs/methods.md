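# Methods

## Scope and model outline

`cortadapt` simulates functional adaptation of cortical bone under cyclic
axial compression, using load-induced interstitial fluid velocity as the
mechanical stimulus. The chain per remodelling iteration is:

    geometry → section properties → beam strain ε_zz(θ, Z)
             → 1-D consolidation per sector → Ψ(node, t) = |V| at the
               periosteal face → on–off response Λ → rate u̇ → spatial
               averaging ū̇ → outward surface growth

iterated until the maximum relative thickening in the analysed region
reaches the stop value, or an iteration cap.

The pipeline is a deliberate reduced-order surrogate for a 3-D poroelastic
finite-element treatment: the structure is a beam under eccentric axial
load, and pore-pressure diffusion is solved independently through the wall
of each (θ, Z) sector. Sectors interact only through the shared beam
strain field and the spatial averaging of remodelling rates.

## Synthetic geometry

Real studies image both tibiae of each animal with micro-CT; here a
parametric generator stands in for the scanner. A slice at normalised
axial position Z ∈ [0, 1] is an annulus in polar coordinates about the
slice centre: outer radius = base outer radius (linear proximal→distal
taper, 600 → 480 µm) plus cosine-tapered crest bumps at the angular
positions of the murine landmarks (interosseous crest 300°, tibial ridge
50°, soleal line 220°, proximal crest 160°); the endosteal boundary
follows the base radius offset inward by the wall thickness (220 → 150 µm
taper), so crests are solid ridges that thicken the local wall. Slices are
rasterised at 1 µm/px by default so the pixel-level thickness error is
about 1 µm. Boundaries live on the pixel grid; there is no subpixel
contouring.

The section centre drifts from the load axis by an eccentricity profile
e(Z) with a sin(πZ) bow of 500 µm peak directed towards 120°, plus a small
sin(2πZ) wobble. The bow magnitude was chosen so bending dominates the
axial strain term (ratio ≈ 2.3 at mid-shaft), which reproduces the
characteristic in-vivo strain split of this loading model — peak
compression of a few thousand microstrain on the crest side, genuine
tension on the opposite (medial-analogue) surface. With a substantially
smaller bow the tensile sector would carry less strain than the neutral
flanks and the medial growth pattern would disappear.

A paired "loaded" geometry is produced by `apply_thickening_field`: the
periosteal boundary moves outward so the wall at (θ, Z) becomes
Th·(1 + f), with f ≥ 0 a prescribed ΔTh/Th field and the endosteal
boundary unchanged (the model is purely appositional). This provides
pipeline round-trip ground truth that a real experiment cannot.

What the generator does **not** emulate: trabecular structure, foramina,
cortical porosity, left/right registration error, and landmark
misalignment between limbs (synthetic pairs are born aligned). Tests that
pass on these phantoms therefore validate the measurement and simulation
chain, not robustness to segmentation artefacts; an optional seeded
boundary-roughness term exists but defaults to off.

## Thickness mapping

Per slice: keep the largest connected component (discarding fibula-like
fragments), fill interior porosities except the largest cavity (the
medullary canal), and extract the periosteal boundary (bone pixels
adjacent to the exterior) and the endosteal boundary (canal pixels
adjacent to bone — the mixed convention cancels the two half-pixel
erosions so ring distances are unbiased). Thickness at each periosteal
pixel is the exact Euclidean distance to the nearest endosteal pixel
(distance transform). Values are averaged into half-open azimuthal bins of
π/90 (2°) about the area centroid of the cortical mask. Empty bins are
marked missing and propagate as missing — interpolation would fabricate
adaptation. ΔTh/Th is computed bin-wise between maps on identical grids;
bins missing on either side stay missing, and a rectangular (θ, Z) mask
can exclude artefact-prone regions from analysis.

Second moments of area are pixel sums about the centroid with principal
values from the 2-D eigen-decomposition. A utility selects the specimen
closest (least squared error) to the cohort-mean second-moment profile,
mirroring how a representative animal would be chosen; the synthetic
pipeline itself runs on one pair.

## Structural response

The load cycle is trapezoidal: 13 N peak, 0.025 s ramps, 0.05 s hold,
followed by rest; only a 0.5 s window is simulated (one 0.1 s cycle plus a
0.4 s relaxation tail) at dt = 0.005 s — exactly 100 frames. Frame times
exclude t = 0.

Strain is quasi-static unsymmetric beam bending under eccentric axial
compression. With the compressive force F applied along the fixed load
axis, the internal stress σ(x, y) = σ₀ + a·x + b·y about the section
centroid is fixed by static equivalence: ∫σ dA = −F, ∫σ x dA = −F e_x,
∫σ y dA = −F e_y, where e is the offset of the load axis from the
centroid. The 2×2 system in (a, b) uses the full second-moment tensor, so
e_x > 0 deepens compression on the +x side; ε_zz = σ/E_z with
E_z = 17 GPa. The eccentricity is recomputed every iteration from the
current centroid, so growth feeds back on the bending moment.

## Poroelastic stimulus

Each sector is a 1-D poroelastic column from the periosteal face (x = 0)
to the endosteal face (x = L, the local wall thickness), with uniaxial
strain forcing:

    S ∂p/∂t − (k_l/μ) ∂²p/∂x² = −α ∂ε_zz/∂t.

The storage coefficient closes the constitutive model as
S = φ/K_f + (α − φ)/K_s with K_s = K_d/(1 − α) and the drained bulk
modulus K_d from the isotropic reduction of the longitudinal constants
(E_z, ν_lt); a `stiff-grain` switch keeps only φ/K_f, and the full form
falls back to it with a warning if α ≤ φ. Defaults: k_l = 10⁻²² m²,
α = 0.14, φ = 0.05, μ = 8.9·10⁻⁴ Pa·s, K_f = 2.3 GPa, giving a
consolidation coefficient c = k_l/(μS) ≈ 4.6·10⁻⁹ m²/s.

Both faces are drained (p = 0) by default: measured periosteal membrane
permeability is about five orders of magnitude above the
lacunar–canalicular value, so the membrane conductance is effectively
infinite. A Robin option (conductance k_m/(μ t_m), defaults 10⁻¹⁷ m² over
10 µm) is retained and reduces to the drained solution for permeable
membranes.

The through-wall permeability is taken as the longitudinal value k_l.
Strictly, canaliculi run predominantly longitudinally while the 1-D column
here is radial, so an argument for the 10× smaller transverse value
exists; k_l is used so that stimulus magnitudes match the regime the
reference apposition thresholds (10⁻³–10⁻¹ µm/s) were defined for.
With it, peak face velocities are ~0.1–0.5 µm/s at physiological strains
— inside the threshold decade.

**Numerics.** Crank–Nicolson time stepping with two backward-Euler startup
steps (Rannacher smoothing: trapezoidal stepping alone rings on rough
initial data such as a uniform initial pressure), second-order central
differences on an n_x-point grid (default 200, minimum 50). The scheme is
unconditionally stable, discretely conservative (the interior-sum balance
holds to machine precision), and second-order in space (halving dx cuts
the analytic-series benchmark error ~4×). The Darcy velocity uses
one-sided second-order gradients at the faces; pressure is in Pa
internally and Ψ is reported in µm/s to match the threshold units.

**Linearity batching.** The problem is linear and all sectors share the
load waveform shape, so the solution of a sector is its peak strain times
the unit-peak-strain solution for its wall thickness. Inside the
adaptation loop, walls are quantised to 0.5 µm (below raster resolution)
and one batched solve per unique thickness serves all 18 000 sectors; the
batched path agrees with the single-sector solver to solver precision.

**Residual pressure.** With the default constants and a 200 µm wall the
slowest drained mode decays at (π/L)²c ≈ 1.1 s⁻¹, so the pressure
remaining at the end of the 0.5 s window is a few percent of the cycle
maximum (measured ≈ 6%), not strictly zero; it decays monotonically after
unload. The corresponding tail velocities are two to three orders below
the apposition thresholds, so iteration-to-iteration carry-over is
negligible and each iteration starts from p = 0.

The 1-D reduction cannot reproduce one documented 3-D effect: in the full
structural problem, compressed regions can draw fluid inward (low pore
pressure) during loading. The surrogate yields the textbook sign
(compression → overpressure → efflux). The adaptation law consumes only
the stimulus magnitude |V|, which is preserved.

## Adaptation law

Per frame, the cellular output is a step function: Λ = +1 where
Ψ ≥ Ψ_A, Λ = −1 where Ψ ≤ Ψ_R and resorption is active, else 0; the
threshold value itself triggers the response. The nodal rate integrates
the response over the window: u̇ = C·(dt ΣΛ)/T, normalised by the window
duration T so that a signal above threshold for the whole window yields
exactly C = 4.45 µm/iteration and u̇ ∈ [0, C]. One representative load
cycle is simulated per iteration; the in-vivo schedule (40 cycles/day,
3 days/week) is absorbed into C.

Rates are then averaged over a spherical zone of influence of radius
R = 150 µm (the average osteon radius): ū̇(n) is the mean of u̇(n) and the
w-weighted average over neighbours within R (3-D Euclidean distance,
excluding the node), with w(r) = 1 − r/R. The weighted average is
normalised by Σw — the choice pinned by requiring uniform fields to be
invariant; the operator is a max-norm contraction. On the default grid
(180 × 100 nodes, ~21 µm circumferential and 100 µm axial spacing) a node
has ~45 neighbours within R.

Nodes outside the diaphyseal adaptive region (Z ∈ [0.1, 0.9] by default)
are clamped to zero. Growth is applied along the outward normal, taken as
radial in-plane for this thin-wall surrogate: node radius and local wall
thickness increase by ū̇, positions move radially, and ΔTh/Th is
recomputed against the iteration-0 thickness field. The geometry update is
a polar-radius/thickness-field update — not a volume remesh — and image
stacks are regenerated from the updated radius functions only when
needed. Resorption is implemented but inactive by default (Ψ_R = 0), so
thickness is non-decreasing; Ψ is evaluated at the periosteal face only
and endosteal adaptation is out of scope.

The loop recomputes section properties, centroid eccentricity, strain and
stimulus on the grown geometry every iteration, and stops when the
maximum ΔTh/Th over masked, adaptive bins reaches `stop_dth` (default
0.67, the experimental maximum thickening of this loading model) or at
`max_iterations` (default 400, a generous cap well above the expected
termination of the default conditions).

Raising Ψ_A confines adaptation to ever-smaller high-stimulus regions and
delays termination; sweeping the five reference thresholds
(10⁻³ … 10⁻¹ µm/s) reproduces this pattern monotonically. Iteration
counts themselves are geometry-specific and are not comparable across
geometries.

## Validation statistics

Observed and predicted ΔTh/Th maps are compared over co-defined,
masked-in bins with Kendall's τ-b (tie-corrected; binned, quantised maps
are heavily tied). The p-value is the exact permutation value for small
tie-free samples and the normal approximation otherwise — the regime of
real map comparisons. A one-sample Kolmogorov–Smirnov test of the
standardised values against N(0, 1) documents the non-normality that
motivates the rank-based choice. Bins are treated as independent; spatial
autocorrelation is noted but not corrected.

## Problem sizes used in the shipped checks

The default study conditions are 100 slices × 180 sectors at 1 µm/px with
200-point through-wall grids. The test suite exercises the full default
simulation once; the threshold sweep and the observed-vs-predicted
comparison run at a reduced resolution of 50 slices × 90 sectors at
2 µm/px, which preserves every qualitative property while keeping the
whole suite desk-scale. Unit and property tests use miniature phantoms
(hundreds of pixels) with brute-force oracles: all-pairs distances for the
thickness map, pixel quadrature for static equivalence, analytic series
and harmonic closed forms for consolidation, an O(n²) double loop for the
rate smoothing, and concordance counting for τ-b.

## Known limitations

- The beam + 1-D consolidation surrogate ignores axial and circumferential
  pressure diffusion, condyle contact, growth-plate compliance and the
  fibular load path.
- Strain-field fidelity near the bone ends is limited: where the bow
  vanishes the tensile sector sits on the neutral axis, so medial growth
  is a mid-shaft phenomenon in this model.
- No cellular desensitisation, saturation, or rest-insertion recovery;
  the on–off response with a fixed threshold is homogeneous in space.
- No woven-bone response, endosteal adaptation or trabecular remodelling.
- Thickness maps use the periosteal-pixel convention; thinning can be
  reported (as negative ΔTh/Th) but never simulated with the default
  Ψ_R = 0.
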