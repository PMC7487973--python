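# Methods

## Model

Muscle (and aponeurosis) tissue is modelled as a nearly incompressible,
transversely isotropic, fibre-reinforced hyperelastic continuum undergoing
large quasi-static deformations.  Equilibrium states make the total strain
energy stationary over three fields — nodal displacements **u**, element
pressures *p* and element dilations *J* — following the classical
Hu–Washizu / mean-dilatation treatment of near-incompressibility.  With
element-constant *p* and *J* (Q1–P0–P0) both local fields condense in closed
form: the element dilation is the volume average of det F and the pressure is
the derivative of the volumetric penalty there,

    J̄ₑ = ⟨det F⟩ₑ ,    pₑ = κ (J̄ₑ − 1),

leaving a nonlinear system in **u** alone.

The strain-energy density is the sum of four components.

**Active fibre.**  A Hill-type contractile element along the local fibre
direction a₀.  The nominal fibre stress is σ_max · a · f_act(λ̄) with
activation a ∈ [0, 1] and a force–length curve f_act normalised to peak 1 at
the optimal stretch.  Its energy density is the path integral of the nominal
stress from λ = 1, so it is *negative* when fibres shorten below optimal
length: energies are reported relative to the undeformed state.  The curve is
a C¹ piecewise raised cosine with a plateau at 1 on stretch ∈ [0.95, 1.05],
an ascending limb from 0.5 and a descending limb to 1.6, following the shape
of published mammalian force–length data.  Force–velocity effects and
activation dynamics are deliberately absent — the activation ramp is
quasi-static.

**Passive fibre.**  A parallel elastic element, zero at or below optimal
length, with a quadratic toe (to λ = 1.4 for muscle) and a C¹ linear
continuation, reaching the maximum isometric stress at λ = 1.6.  The
aponeurosis variant is tendon-like: a 3% toe and a normalised linear
stiffness of 4000 (≈ 0.8 GPa at σ_max = 200 kPa).

**Base material.**  An isotropic cubic Yeoh law s_base · Σ cᵢ (Ī₁ − 3)ⁱ
representing everything that is not myofilament: cytoskeleton, ECM, vessels.
The coefficients are a non-negative least-squares fit of the incompressible
uniaxial Yeoh response to digitised across-fibre tensile control points
(shipped in `constitutive.py`; a test re-runs the fit): muscle
c₁ = 14.44 kPa, c₂ = 138.3 kPa, c₃ = 0 (the NNLS leaves the cubic term
inactive for these points).  The small-strain shear modulus is 2c₁ ≈ 29 kPa,
in the range reported for skeletal muscle.  s_base scales all three
coefficients.

**Volumetric.**  U(J) = (κ/2)(J − 1)², the simplest strictly convex penalty
consistent with a stated bulk modulus; κ = 10⁶ Pa for muscle and 10⁸ Pa for
aponeurosis.

### Isochoric split — a deliberate design decision

The fibre and base energies act on *isochoric* deformation measures,
λ̄ = J^(−1/3) λ and Ī₁ = J^(−2/3) tr C, so their Cauchy stresses are
deviatoric and the κ-term alone carries hydrostatic stress.  This choice is
load-bearing, not cosmetic.  If the fibre energy instead acts on the full
stretch λ, the active stress carries a hydrostatic tension: fixed-end
contraction then *decreases* tissue volume, the parallel-fibred block stays
exactly at its reference state (no bulging, F_x = σ_max·CSA), and the z-face
strain is negative at every pennation angle.  With the isochoric split the
model reproduces the experimentally grounded behaviours this package exists
to study: transverse bulging of parallel-fibred blocks during fixed-end
contraction, a small activation-induced volume gain (≈ 0.9% at 20%
activation), a sub-maximal longitudinal force, and a sign change of the
z-face strain at a moderate pennation angle.  The *reported* fibre stretch
λ_tot = √(a₀ᵀ C a₀) remains the physical (full) stretch.

## Protocols

**Fixed-end contraction.**  Both x-faces clamped in all three directions,
all other faces traction-free; activation ramped linearly 0 → a_max in
`ramp_steps` (default 10) steps, each step converged by Newton's method.
The ramp doubles as load continuation.

**Length change, then hold.**  A uniform dead nominal x-traction on the +x
face (−x face clamped) is adjusted by a secant iteration until the
area-weighted mean face separation reaches the target normalized length
l̂ ∈ [0.7, 1.3]; the face displacements are then frozen as Dirichlet data
("held") for the subsequent activation ramp.

**Block campaigns.**  The default sweep crosses β₀ ∈ {0, 5, 10, 15, 20, 25,
30, 37}° at the standard 30×10×10 mm size plus ±15% CSA (at constant volume)
and ±15% volume (at constant CSA) variants at β₀ ∈ {0, 20, 30}°, i.e. 20
blocks.  Blocks with β₀ ≤ 5° use s_base = 1.5: with the physiological base
stiffness the near-parallel-fibred problems lose convergence before full
activation, consistent with the known behaviour of this class of model.

## Numerics

* Trilinear hexahedra, 2×2×2 Gauss quadrature (8 points per element).
* The tangent matrix is assembled by complex-step differentiation of the
  element residual (step 10⁻¹⁰⁰): exact to machine precision and
  automatically consistent with the mean-dilatation condensation, including
  the dp/du coupling.  Piecewise constitutive branches switch on the real
  part, so a perturbation never changes branch.
* Newton with backtracking line search on the residual norm; default
  tolerance 10⁻⁸ N.  Non-convergence raises an error carrying the states
  converged so far; sweeps record such blocks and continue.
* Bulk moduli well above ~10⁸ Pa defeat plain Newton far from the root (the
  quadratic penalty residual overshoots as κ‖δu‖²); `kappa_continuation_solve`
  ramps activation at κ = 10⁶ Pa and then stiffens κ geometrically,
  re-converging warm-started at each level (3–4 iterations per level).
* With Q1–P0 interpolation only the element-average dilation is penalised;
  pointwise det F retains an intra-element spread at any κ.  Incompressibility
  diagnostics therefore use the dilation field J̄, which decreases ∝ 1/κ.
* Element inversion (det F ≤ 0) raises a dedicated error naming the element.

**Post-processing.**  Face forces are sums of constrained-node reactions
(equal to the deformed-surface traction integral at equilibrium); face
stresses divide by the deformed face area.  Face strains use area-weighted
mean face-node coordinates, the definition adopted for deformed, non-planar
faces.  Mean fibre stretch and pennation are unweighted means over
quadrature points (the weighting is not otherwise determined; the dilation
field stays within ~2% of 1, so the distinction is below reporting
precision).  Energy potentials are reference-volume integrals; overall
energy *densities* are means over quadrature points weighted by the local
dilation.  The centre-plane stress decomposition samples quadrature points
within half an element width of the plane through the deformed block centre
normal to the mean deformed fibre direction, and reports each component's
fibre-normal Cauchy traction, positive when acting to shorten the fibres.

**Surface metrics.**  Signed distance maps use exact point-to-triangle
distances (vectorised barycentric clamping) with containment decided by the
generalised winding number; grids default to 0.5 mm spacing with 5 spacings
of padding, and interpolation is trilinear.  PCA alignment rotates the
moving surface's principal axes onto the reference's, resolving axis signs
by minimising nearest-vertex distance over the four proper rotations
(reflections are never applied; near-degenerate axes trigger a warning —
e.g. square-section blocks, whose transverse axes are genuinely ambiguous).
Width/depth profiles intersect the surface with yz planes at 10 stations;
width is the y-extent of the section and depth its area over the width, the
section area coming from quantised segment chaining and the shoelace
formula.

## Synthetic data and what the tests show

All geometries are generated programmatically; no biological data enters the
tests.  The blocks emulate homogeneous unipennate muscle tissue with uniform
fibre fields — they deliberately omit aponeuroses, fibre curvature and
heterogeneity, intramuscular fat, and the external boundary constraints of a
muscle in situ.  Passing tests therefore demonstrate the internal mechanics
of the constitutive model and solver (energy consistency, objectivity,
equilibrium, mesh convergence) and the qualitative physiology of fixed-end
contraction (fibre shortening and rotation, transverse strain anisotropy,
energy redistribution into the base material with pennation); they do not
validate the model against any individual muscle's imaging data.

Because the exact force–length and base-material coefficients behind the
reference results are not published, the shipped coefficient sets are this
package's own documented fits to the same classes of published data, and the
quantitative reference values are matched only to within tolerance bands.
At the shipped coefficients the desk-scale model reproduces the parallel
block force (19.2 N), the 30° block's mean stretch (0.850) and pennation
(34.0°), the z-strain sign transition (≈ 12.3°), the energy-density
linearity (r² = 0.98) and the 20%-activation volume gain (0.86%); the 30°
block's force (8.8 N, mesh-converged) sits ~18% below its reference value,
which we attribute to the base material being softer at large strains than
the unpublished original fit (the same softness shows up as slightly more
fibre shortening).

## Problem sizes

Default desk resolution is 12×4×4 elements (1 536 quadrature points,
≈ 1 000 displacement dofs), for which a 10-step ramp takes a few seconds;
doubling to 24×8×8 changes the pennate block force by < 0.3%, so desk scale
is effectively mesh-converged for the reported scalars.  The full 40×20×20
resolution (128 000 quadrature points) is available through `BlockSpec` for
users who want it.

## Known limitations

* Quasi-static only: no tissue inertia, no force–velocity relation, no
  activation dynamics.
* The base material is isotropic; endomysial anisotropy and
  tension/compression asymmetry are not represented.
* Q1–P0–P0 elements are modestly soft in bending/shear; absolute forces can
  shift by a few percent relative to higher-order discretisations.
* Aponeurosis material is implemented and tested at the constitutive level,
  but composite muscle–aponeurosis meshes are out of scope.
* MRI/DTI-derived geometries and their registration pipelines are out of
  scope; the surface metrics are exercised on simulated geometries.
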