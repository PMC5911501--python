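# Methods

## Model

One incompressible continuum covers blood and leaflet tissue.  On the
moving domain Ω(t) with ALE mesh velocity **m**,

    ρ (u̇ + ((u − m)·∇) u) = ∇·τ,      ∇·u = 0,

with the stress selected per cell by a binary phase function θ
(1 = fluid, 0 = solid):

    τ   = τ_D − p I
    τ_D = θ τ_f + (1 − θ) τ_s
    τ_f = 2 μ_f ε(u)
    D_t τ_s = 2 μ_s ε(u) + ∇u τ_s + τ_s ∇uᵀ
    ε(u) = (∇u + ∇uᵀ)/2

Because θ is binary, the blend is exact phase selection — there is no
interpolation region.  The solid is an incompressible neo-Hookean material
written in rate form; incompressibility of both phases is carried by the
shared continuity equation, so no separate strain-energy functional is
needed.  The kinematic interface condition is satisfied by construction
(one continuous velocity field); the dynamic condition is enforced weakly
by integrating the stress term by parts and dropping the boundary
integral.

In solid cells the mesh velocity is the material velocity (Lagrangian);
in fluid cells it comes from the smoothing algorithms below.

Assumptions: Newtonian blood (μ_f = 0.0027 Pa·s, ρ = 1060 kg/m³);
homogeneous isotropic leaflets (ρ = 1000 kg/m³); no non-Newtonian
rheology, no fiber anisotropy, rigid outer walls, velocity-driven inflow
with a homogeneous Dirichlet outlet pressure.  The default leaflet shear
moduli (3.3·10⁹ Pa native, 6.5·10¹¹ Pa mechanical) are stand-in
stiffnesses, not measured tissue moduli; every config may override them,
and the desk-scale demo uses 10⁶ Pa so that a leaflet visibly flexes at
centimeter scale.

## Discretization

Continuous piecewise-linear (P1) velocity and pressure on simplicial
meshes (triangles/tetrahedra), velocity piecewise linear in time and
pressure piecewise constant per step.  Midpoint quadrature in time yields
a Crank–Nicolson scheme in the slab-average velocity
Ū = (Uⁿ + Uⁿ⁻¹)/2.  Equal-order elements are stabilized by a simplified
Galerkin/least-squares (streamline-diffusion) term in which the time
derivative and diffusion are dropped:

    SD = (δ₁ [ρ((Ū − M)·∇)Ū + ∇P], ρ((Ū − M)·∇)v + ∇q)
       + (δ₂ ∇·Ū, ∇·v)

    δ₁ = κ₁ ρ⁻¹ (k⁻² + |U − M|² h⁻²)^(−1/2),   δ₂ = κ₂ ρ h |U|

with κ₁ = κ₂ = 1 by default (any O(1) constants are admissible, both
exposed in the config), per-cell diameters h (the per-cell h generalizes a
global mesh constant and reduces to it on uniform meshes), and
previous-step velocity fields inside δ₁, δ₂.  The mesh velocity entering
the advective terms is the one of the previous step: in the operator-split
loop the current step's mesh velocity is known only after the momentum
solve.  The Galerkin continuity term (∇·Ū, q) completes the weak form.

Each step is linearized by Picard (fixed-point) iteration: the advective
velocity and the solid-stress transport terms are frozen at the previous
iterate, making every sweep a single sparse linear solve in (Uⁿ, Pⁿ).
Tolerance 10⁻⁶ on the relative velocity update, at most 50 sweeps;
divergence or budget exhaustion rejects the step and the caller halves dt.

Solid stiffness inside a step: the incremental stress γ·dt·2μ_s ε(Ū) is
kept implicit (linear in the unknown) while the stored τ_s and its
transport terms enter the right-hand side explicitly.  The weight γ
(`SolverConfig.solid_implicitness`) interpolates between the
energy-conserving midpoint value γ = ½ and a backward-Euler-like γ = 1.
The default is γ = 1: the midpoint variant conserves the elastic energy of
cell-scale modes exactly, and in strongly coupled leaflet problems those
undamped oscillations interact with the moving mesh and can grow; the
over-implicit weight damps precisely those modes at the cost of first-order
(in dt) extra dissipation in the solid.  The committed end-of-step stress
update is always the explicit midpoint-velocity step

    τ_sⁿ = τ_sⁿ⁻¹ + dt (2 μ_s ε(Ū) + ∇Ū τ_sⁿ⁻¹ + τ_sⁿ⁻¹ ∇Ūᵀ),

symmetrized, one value per cell (P1 velocity ⇒ constant ∇u per cell),
first-order consistent with the stress rate equation (verified against a
high-order ODE oracle).

Time steps follow a CFL criterion, dt = C·min_K h_K / max(|U − M|, ε),
with target C = 0.5, a floor of C = 0.01 under step rejection, and
recovery by doubling after ten accepted steps.  The linear systems are
solved by Bi-CGStab with an ILU(0)-style preconditioner or, for the small
desk-scale systems where it is both faster and failure-free, a sparse
direct factorization (config `krylov = "direct"`; the demo uses it).

Boundary conditions: flat-profile inlet velocity along the domain axis,
no-slip walls, strong nodal P = 0 at the outlet combined with the dropped
viscous boundary term (the simplest faithful reading of a homogeneous
outlet pressure; a weak traction form would be the alternative).  Wall
values override inlet values on shared rim vertices.  A body-force hook
exists solely to enable manufactured-solution testing and defaults to
zero.

Verified properties: uniform flow with M = U is an exact steady state
(assembled residual < 10⁻¹⁰ relative); plane Couette flow is reproduced to
solver tolerance (the linear profile is in the P1 space); the spatial L2
velocity error of a steadily forced Taylor–Green vortex decreases by
factors ≈ 4 per mesh halving over 8→16→32 subdivisions.

## Mesh smoothing

The linear smoother solves a componentwise Poisson problem for the mesh
velocity on the fluid vertices, Dirichlet: structure velocity on the
fluid–structure interface and on all solid vertices, zero on fixed outer
boundaries.  It runs every step.

The nonlinear smoother descends the quality-weighted elastic energy
E = Σ_K vol_K · Q(K) by analytic vertex-gradient steps on interior fluid
vertices.  Q(K) = ‖F‖²_F / (d det(F)^{2/d}) is itself the isochoric
neo-Hookean energy density tr(C̄)/d of the cell-to-reference deformation,
so E is a nonlinear elasticity functional whose stiffness grows with
distortion; its gradient vanishes identically on equilateral patches, so a
perfect patch is an exact fixed point (an energy with a separate
volumetric term would not have this property and would drift cell sizes).
Pseudo-time steps that would invert a cell or raise the worst quality are
rejected with a halved pseudo step, making Q_max non-increasing by
construction and inversion impossible to commit.  It is triggered only
when Q_max exceeds a threshold (default 8 in the library, 3 in the demo
config) to limit cost, with a pseudo-step budget (default 5; 30 in the
demo).  The reference cell is the unit-measure equilateral simplex — Q is
invariant to the reference scale, so unit measure is canonical.

The committed mesh velocity of a step is (x_new − x_old)/dt including the
nonlinear correction, keeping the ALE advective velocity consistent with
the actual mesh motion.

## Contact and hinge kinematics

Native-valve closure: the minimal distance between leaflet surfaces
(or leaflet and facing wall in the single-leaflet channel) is monitored;
when it falls below a threshold the fluid cells directly attached to the
upstream side of the pre-embedded closure surface switch θ 1→0 in a single
step (whole-orifice closure at once — the closing moment of a healthy
valve is short), are recorded, and revert at the next systole-start event
with their solid stress reset to zero.  Switched cells start stress-free:
they represent coapted blood volume, not strained tissue.  The default
threshold is twice the minimal cell diameter (config-overridable in
absolute units); detection is armed only after the systolic pulse has
passed, since a valve closes under decelerating or reversed flow and the
rest configuration of a desk-scale fixture may already sit within one
threshold of its counter-surface.  Closure switches exactly one cell layer
under the surface; pocket flood-filling is not implemented.

Distances come in two grades: an exact geometric point-to-facet minimum
(the reference oracle, used by default) and a finite-element
vanishing-viscosity Eikonal solve — a shortest-edge-path field initializes
the transport direction and a few fixed-point sweeps of
(εh ∇φ, ∇v) + ((w·∇)φ, v) = (1, v) with w = ∇φ/|∇φ| relax it toward the
Euclidean distance; both overestimate the metric slightly and agree within
twice the mesh size on the fixtures.

The mechanical valve uses hinge-angle locking instead of phase switching:
each leaflet's angle α is the dihedral angle of its best-fit plane about
the hinge axis (two fixed edge points) relative to the closed plane.
Exceeding the opening barrier (45° default) or the closing barrier (0°)
locks the leaflet via zero-velocity constraints; release rules run before
lock checks (fully open releases when the mean pressure above exceeds the
mean pressure below; fully closed releases when a new cycle starts), and a
leaflet released in a step is exempt from re-locking in that same step, so
lock/release cannot oscillate within one step.

## Cardiac cycle and pre-stress

One cycle lasts 1.124 s with only systole and diastole modeled.  The
inflow magnitude is not tabulated anywhere usable, so the default waveform
is an interpretation: a half-sine forward pulse (T_sys = 0.4 s, peak
1.0 m/s library default; 0.5 m/s in the 2D demo) followed by a half-sine
reversal lobe of 0.05 s (the small reversed-flow window that completes
closure) and zero inflow in diastole.  All values are configurable; this
waveform is the largest numerical interpretation in the package.  Phase
events (cycle/systole start, reversal start, diastole start) are emitted
exactly once per crossing, in order.

Leaflet pre-stress: τ_s = σ_r (e_r ⊗ e_r) with e_r the cylindrical radial
direction and σ_r = 4 Pa by default, relaxed pseudo-dynamically with zero
inflow until the per-step vertex displacement stalls, then reset.  Known
limitation: on the wall-conforming open leaflets this package generates, a
constant radial *normal* stress relaxes through a thickness-scale
contraction only — the large inward "contracting balloon" sweep of a
stretched leaflet requires in-surface (membrane/hoop) tension or leaflets
that overhang the orifice.  The operation is faithful to its definition,
equilibrates, and scales linearly with σ_r, but it does not produce a
visibly swept start configuration at desk scale.

## Geometry generators

All meshes are structured and fully programmatic (no external mesher):
extruded triangulated disks split into tetrahedra with a globally
consistent smallest-global-index diagonal rule, so shared prism faces
always conform.

*Aortic root*: truncated cone from the annulus radius R_A (z = 0) to the
sinotubular radius R_S (z = h_l), plus a fixed axisymmetric sinus bulge
(amplitude 0.25·R_S, a single sine lobe vanishing at both rims — the sinus
shape is deliberately not parameterized), plus an ascending-aorta cylinder.
Three leaflets of thickness t_l line the sinus wall in the fully open
position between an attachment curve and the free edge at z = h_l.  The
cutting-plane construction is realized as that attachment curve: flat on
the annulus across the belly (|φ| ≤ β/2 of each 120° sector) and rising
quadratically to the commissure height h_c at the sector edges — a
documented interpretation of a pictorial definition (β defaults to 60°).
The azimuthal resolution is a multiple of six, so threefold symmetry holds
to round-off.  The closure surface is the interior facet layer spanning
the orifice at z = h_l.  Rim radii reproduce R_A and R_S exactly.

*Bileaflet mechanical valve*: a straight tube with two semicircular-disc
leaflets in the valve plane, hinged on axes at x = ±hinge_offset with a
central gap so the leaflets can never touch.  Tilt to the initial angle is
an exact rigid rotation of the leaflet vertices about the hinge axis
(hence angles recomputed from coordinates are exact) with an axially
tapered axial-only blend for neighbouring fluid vertices, valid up to the
45° limit.

*2D channel*: structured triangulated rectangle with one or two leaflet
strips whose faces and tip heights are exact grid lines; the closure line
is the full column of interior vertical edges at the leaflet's upstream
face — the 2D surface covering the entire valve opening.

Units: generator parameters are millimeters (the natural scale of the
anatomical parameters); meshes and everything downstream are SI.

## Post-processing

*Geometric orifice area*: the measure of the closure surface not occluded
by the projection of the leaflet surfaces along the valve axis, by
deterministic per-facet sampling (barycentric grids; axis-projected
point-in-triangle tests in 3D, transverse interval unions per leaflet in
2D).  Facets adjacent to a phase-switched solid cell count as fully
occluded, so a closed valve reports exactly zero.  Projection was chosen
over the instantaneous free-edge polygon because it is well defined for
bent and overlapping leaflets.

*λ₂*: per cell, the middle eigenvalue of S² + Ω² from the P1 velocity
gradient, volume-averaged to vertices; 3D only (the criterion is not
defined in 2D and the implementation refuses).  Thresholding is left to
visualization.  Galilean invariance and the rigid-rotation identity
λ₂ = −|ω|² are asserted in tests.

*von Mises*: √(Σ|τ_ij − δ_ij tr τ/3|²) of the composite stress; 2D states
embed with the out-of-plane normal stress −p (a planar incompressible flow
carries the full isotropic pressure), so a quiescent pressurized state
reports exactly zero.

## Problem sizes and what the tests show

The verification suite runs at deliberate desk scale: unit squares at
8–32 subdivisions, a coarse root (≈3·10³ vertices; ≈200 for the golden
I/O fixture), and a 2D channel of ≈570 vertices for the full-cycle demo
(≈900 steps, a few minutes on one CPU).  The synthetic fixtures emulate
the structure of the real problem — pulsatile driving, flexible leaflet,
contact, ALE mesh motion — but not its 3D geometry, physiological
stiffness, Reynolds number or mesh resolution; passing tests demonstrate
correctness of the discrete operators and the qualitative valve-dynamics
pattern (the four-phase orifice-area trace, closure under reversed flow,
no remeshing over a cycle), not clinical fidelity.  Production-scale 3D
runs of the kind the model ultimately targets require cluster resources
and are out of scope here.

## Known limitations

- The solid is dissipative at first order in dt with the default γ = 1
  stress weighting; set `solid_implicitness = 0.5` for the conservative
  midpoint variant on problems where mesh motion is mild.
- Thin P1 leaflets lock in bending; effective stiffness is higher than a
  beam estimate, so demo stiffnesses are tuning choices of the fixture.
- The Eikonal distance inherits a first-arrival overestimate of order h
  from its graph initialization.
- Pre-stress produces thickness-scale motion on wall-conforming leaflets
  (see above).
- Closure switches one cell layer; no pocket flood-fill.
- No turbulence model, no non-Newtonian rheology, no patient-specific
  geometry, no parallelism.
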