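# Methods

## Model

The floating image is treated as a homogeneous, isotropic hyperelastic
sheet tiled by a uniform triangular P1 mesh over the pixel rectangle
`[0, W−1] × [0, H−1]` (x = column, y = row, pixel centers at integer
coordinates; each grid cell split along its lower-left-to-upper-right
diagonal — on a uniform grid both diagonals satisfy the Delaunay
criterion, so one is fixed for reproducibility).

The material is St. Venant–Kirchhoff: the linear constitutive law
σ = Dε applied to the Green–St.Venant strain
e = ½(∇u + ∇uᵀ + ∇uᵀ∇u).  With the displacement-gradient 4-vector
g = [∂u_X/∂X, ∂u_Y/∂X, ∂u_X/∂Y, ∂u_Y/∂Y], the engineering strain is
ε_m = h_m·g + ½ g·H_m g with constant selectors h_m and sparse symmetric
H_m.  D is the plane-strain matrix for Young's modulus E and Poisson
ratio ν, with unit thickness.  Because the strain is constant on each
P1 triangle, every element integral is exactly area × density; no
quadrature rule enters.

The elastic nodal force is defined as the exact analytic gradient of
the implemented energy, per element

    F_el = A · Bᵀ Σ_m (Dε)_m (h_m + H_m g),

assembled over elements.  This polynomial (linear + quadratic + cubic
in u) is validated against central-difference energy gradients to
< 1e−5 relative error; the finite-difference oracle is treated as the
normative definition wherever a printed index convention is ambiguous.
The linearized operator K (h_m terms only) serves the two linear
comparators: the static solve K·u = R̂ (LFEM, with a Tikhonov shift
1e−8·tr(K)/2n fixing the rigid modes) and the linear dynamic model
(DFEM).

## External force: spatially encoded mutual information

Intensities are rescaled to [0, 1] at the I/O boundary, making the
intensity-domain parameters bit-depth independent.  The intensity
domain is discretized on `n_bins = 32` bin centers; each pixel carries
a Parzen kernel response vector (Gaussian, width β = 1/32 — β is
standard Parzen-MI practice; the source analysis tunes only the region
diameter) normalized to unit mass, so every local joint density sums to
one by construction.

Local joint densities are evaluated at mesh-node centers over square
windows of diameter d = 15 px (the value found optimal in the
underlying study) with Gaussian spatial weights of std γ = 0.25·d,
normalized by the in-domain weight sum (border-aware).  The MI weight
surface L_s = 1 + log(p_s/(p_s(r′)p_s(m′))) is computed per node and
shared by the pixels nearest to that node; each pixel's force carries
its own spatial weight relative to its center.

Two choices here deserve emphasis:

- **Orientation.** The force is implemented as an ascent direction of
  the discretized SEMI similarity and verified by a direct
  ascent-direction property test, rather than trusting a printed sign.
- **Self-matched debiasing.** At the small effective sample size of a
  15-px window (~90 effective pixels against 32² bins) the exact
  gradient of local Parzen MI is strongly non-zero even at perfect
  alignment: the marginal-entropy terms push intensities toward
  locally rare values (a histogram-equalization artifact), measured at
  ~70 % of the force magnitude of a 5-px misregistration.  The force
  therefore subtracts the same kernel-derivative contraction evaluated
  at the reference intensity, making it exactly zero wherever the
  warped intensity equals the reference while preserving the
  misregistration signal.  With this term the aligned-pair force is
  < 5 % of the misregistered force, and in the uniform-weight limit
  (γ → ∞, window covering the image) the field still collapses to the
  classical global Parzen MI gradient.

Nodal forces R̂_i = ∫ R(x) N_i(x) dx are assembled by pixel-sum
quadrature with trapezoidal border weights (exact for uniform fields).
The scalar `force_weight` balancing image against elastic units is
auto-calibrated per level: the initial maximum nodal external force is
scaled to 10× the elastic force of a one-pixel single-node test
displacement.  The underlying study never reconciles kPa against
intensity-gradient units; this ratio is the package's single
dimensionless coupling knob.

## Units and dynamics

Table-style defaults: E = 100 kPa, ν = 0.45, ρ = 1000, α = 5 (C = αM),
Δt = 0.004.  The constitutive matrix is kept in kPa (D₁₁ ≈ 379.31 kPa);
the dynamic solver converts elastic forces to base units (× 10³, i.e.
E in Pa with lengths in pixels and unit thickness).  In this unit
system the default set is self-consistent: the damped modes contract by
exp(−αΔt/2) = 0.990 per step — a spectral radius of 0.99 — the explicit
central-difference scheme has a ~25× stability margin on the default
meshes, and ~500 steps reduce a transient by > 99 %, matching the
per-level step budget.  Keeping D in kPa instead makes the same
defaults either unstable or orders of magnitude too slow; the ×10³ is
therefore a unit convention, not a tuning parameter.

The lumped mass assigns ρ·A_el/3 to each element node (both dofs share
the nodal mass).  Relaxation iterates the central-difference update
with the external force refreshed every 10 steps (refreshing every step
doubles cost for negligible change at these Δt), starting at rest
(u_{t−1} = u_t = u₀ — initialization is unstated in the source and
immaterial after damping).  Convergence is declared when the maximum
nodal increment falls below 1e−3 px, with at most 500 steps per level.
The sub-pixel image-force landscape is rough, so the underdamped
trajectory often keeps oscillating (~0.1 px/step) around equilibrium
instead of meeting the tolerance; in that case the returned
displacement is the time average over the trailing 30 % of steps, which
cancels the zero-mean oscillatory component.  Rigid-body modes are
handled by the mass-proportional damping (an interpretation; the source
is silent on whether they are damped or constrained).

LFEM in the pipeline is a fixed-point iteration of static solves with
force refresh (under-relaxation ½, per-iteration update trust-region
capped at half the node spacing): a single static solve of the raw
balanced force field overshoots by orders of magnitude, and the
dead-load static problem has no other self-consistent discretization.

A related physical caveat: under a constant (dead) external load the
VK body's rigid-rotation orbit is neutrally unstable, and VK's
well-known compressive softening admits collapsed spurious equilibria.
In the registration pipeline the force refresh provides the stabilizing
feedback; the manufactured-solution test anchors the three rigid modes
explicitly.

## Pipeline

Optional global stage: derivative-free Powell maximization of 64-bin
mutual information over rigid (tx, ty, θ) or affine (6) parameters on a
3-level image pyramid, never returning a transform with lower MI than
the identity.  Whether the source's global stage is rigid or affine is
unstated; affine is the default.  Then per mesh level: Gaussian-smooth
both images (σ = 2 px coarse, 1 px fine — the source names only "a
Gaussian low pass filter"), build the mesh, relax the configured model
against the SEMI force, and interpolate the nodal displacements at the
next level's node positions (both levels live in pixel coordinates, so
no rescaling).  Defaults are two levels of 32×32 and 64×64 nodes for
256×256 images; a level may widen the SEMI window (`semi_d`) to gain
capture range — the large-deformation protocol uses d = 31 px on the
coarse level, since an 18-px displacement is invisible to a 15-px
window.  The final dense field composes the FEM displacement with the
global transform; the warped image is the floating image resampled by
backward mapping with bilinear interpolation and border clamping.
Everything is deterministic: identical inputs, config and seed give
bit-identical fields.

## Synthetic protocol

The generator stands in for clinical CT slices, which cannot be
redistributed.  Phantoms are smooth multi-structure images: a
super-elliptical body, 6–9 oriented soft blobs, a bright rib-like arc,
and — essentially — body-wide granular texture (amplitude 0.15,
σ = 1.5 px).  The texture emulates CT granularity and is what makes the
deformation observable away from structure edges; without it much of a
smooth warp lies in the aperture-problem null space (flat regions,
motion along contours) and no intensity-driven method can recover it.
Foreground (Otsu threshold, largest connected component, 5-px erosion
and border margin) covers 30–43 % of the image across seeds.

Deformations are stored as the forward reference→floating
correspondence field; the floating image is the reference resampled
through the fixed-point inverse of that field, so
`landmarks_flt = landmarks_ref + field(landmarks_ref)` holds exactly
and perfect registration recovers the forward field.  Categories:

- **small** — cubic B-spline field, 6 px peak, control spacing size/8;
- **large** — B-spline field, 18 px peak (> 15 px defines "large"),
  control spacing size/4 so the map stays diffeomorphic (det J > 0);
- **nonuniform** — 3–6 Gaussian bumps whose amplitudes scale with their
  radii (|∇u| ≲ 0.8) and span ≥ 2× in severity, plus a mild affine part.

B-spline fields are exactly scaled to the requested peak magnitude and
tapered to zero on a border margin (C² quintic window over one control
spacing).  Landmarks are 40 uniform draws from the eroded foreground.
Reports give per-axis mean/max landmark distances under the recovered
mapping plus MSD/NC/NMI before and after; model comparisons use a
two-sided paired Student t-test.

## Problem sizes and what the tests show

The shipped experiments run on 128×128 phantoms with 17- and 33-node
mesh levels — the same 8/4-px node spacing as 256×256 images with
32/64-node meshes — ten small-deformation seeds and five
large-deformation fixtures (the protocol's comparison at half the
source's fixture count).  The acceptance suite checks: exactness of the
analytic force (< 1e−5 vs central differences), rotation invariance
(< 1e−8), an O(s) linear limit, density normalization (±1e−3) and the
ascent property (≥ 90 % of points), global recovery of a 7-px
translation (< 0.5 px) and 10° rotation (< 0.5°), sub-pixel per-axis
mean landmark error on ≥ 8/10 small-deformation experiments, the
NFEM < DFEM and NFEM < LFEM error ordering with p < 0.05 (NFEM vs
LFEM), and bit-identical reruns.

Passing these shows the mechanics, the metric machinery and the
model ordering behave as designed **on phantoms with observable,
diffeomorphic synthetic warps**.  It does not certify clinical
accuracy: real CT/MRI pairs add intensity inhomogeneity, contrast
change, sliding interfaces and out-of-plane motion that the generator
deliberately does not simulate, and absolute error levels on real data
will differ from phantom numbers.

## Known limitations

- 2D only; no tetrahedral/3D path.
- Homogeneous material: one (E, ν) everywhere; no spatially varying or
  anisotropic maps.
- Large-deformation recovery is capture-range limited: displacements
  far beyond the SEMI window at every level are only partially
  recovered (the model ordering is still reproduced).
- The explicit scheme's cost is dominated by SEMI force refreshes;
  adaptive time stepping and implicit integration are out of scope.
- MI discretization (32 bins, β = 1/32) assumes intensities fill a
  reasonable part of [0, 1]; degenerate near-constant images raise
  explicit undefined-metric errors instead of guessing.
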