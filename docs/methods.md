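# Methods

## Model

The organ is a voxelized domain Ω_B (a binary mask with voxel sizes in mm)
carrying two parallel porous compartments, arterial (a) and venous (v).
Stationary, incompressible, pressure-driven flow is assumed throughout; the
blood is Newtonian with constant viscosity μ, and permeabilities are
isotropic.

**Tissue.** Each compartment obeys Darcy's law u_β = −(k_β/μ)∇p_β with
no-flow (Neumann) conditions on ∂Ω_B.  The compartments exchange volume at
the perfusion rate P = α(p_a − p_v), a sink for the arterial and a source
for the venous side.  α(x) [m s kg⁻¹] lumps capillary density and
microstructure; P is in s⁻¹ and is multiplied by 6000 for the clinical unit
ml/min/100ml.

**Network.** The segmented arterial and venous trees are undirected graphs
whose edges are straight tubes with medial-axis length L and mean radius R;
laminar tube flow gives the edge conductance κ = πR⁴/(8μL).  Interior
junctions satisfy Kirchhoff balance.  Degree-1 nodes on the organ's
convex-hull boundary are *root terminals* and carry Dirichlet pressures
(p_a0 at arterial, p_v0 at venous roots); degree-1 nodes inside the organ
are *interior terminals* and exchange flow with the tissue.

**Coupling.** A terminal acting as a point source would make the elliptic
problem singular.  Instead each terminal's flow is distributed with the
bump kernel η(x) = C exp(1/(|x|²−1)) on |x| < 1 scaled to a support radius
ε, which is C^∞, positive, and integrates to one.  On the grid the kernel
is evaluated at voxel centres (physical, anisotropy-aware distances),
clipped to Ω_B and renormalised so its *discrete* integral is exactly one —
terminal mass balance therefore holds to machine precision even when the
support is truncated by the organ boundary.  (The continuous normalisation
constant C is computed once per dimension by adaptive radial quadrature; no
closed form exists.  It cancels in the discrete renormalisation and is kept
for the continuous-level API.)  The system is closed by pressure
continuity: q̃_k = (γ/μ)(p̃_k − Σ_j w_k(x_j)|Ω_j| p_j), where γ [m³] is the
effective conductance of the unresolved tree beyond the terminal — larger γ
forces the terminal pressure toward the kernel-weighted mean tissue
pressure.

## Discretisation and linear algebra

The Darcy operator is discretised by the two-point flux approximation:
each interior face between masked voxels carries the transmissibility
t = A_face / (d_i/λ_i + d_j/λ_j), the harmonic mean of the half-cell
conductivities λ = k/μ; faces to unmasked voxels carry none.

The coupled unknown vector is [p_a voxels, p_v voxels, node pressures,
terminal flows].  Terminal flows are kept as explicit unknowns with the
Hagen-Poiseuille flow definition and the continuity closure as their
defining rows: substituting the closure into the voxel rows (the eliminated
block form) creates a dense block over every voxel pair inside a terminal's
support — prohibitive for supports of thousands of voxels — while the
explicit form is algebraically identical and stays sparse.

Because voxel-balance rows (~10⁻¹³), network rows (~10⁻¹⁰) and unit
Dirichlet rows live on very different scales, the matrix is equilibrated by
three alternating sweeps of geometric-mean (√ of max-abs) row and column
scaling before any solve; this brings the condition number down by roughly
four orders of magnitude relative to a single one-sided pass and is what
lets the direct and iterative paths agree to ~10⁻⁹.  Desk-scale problems
are solved by a complete sparse LU with two steps of iterative refinement.
Large 3D problems use GMRES (restart 150, relative tolerance 10⁻⁶ on the
flow solution, tighter internally) preconditioned by the complete LU of a
twin system in which every kernel is collapsed onto its peak voxel: the
twin has the sparsity of the pure TPFA + network problem, factorises
quickly, and is spectrally close to the full operator (typically ~10 GMRES
iterations).  `simulate_flow(method="auto")` switches to this path on 3D
grids above a few thousand masked voxels.  Global mass balance — arterial
root inflow = venous root outflow = ∫P dx — is audited on every solve and
holds to ~10⁻¹² relative.

## Vessel extraction

Arrival-time fields T (|∇T| = 1/S) are computed by Dijkstra-type front
propagation on the voxel graph with upwind travel costs (step length ×
slowness of the entered cell, seeds zero-costed) over the primitive
max-norm-2 offset stencil; the wide stencil keeps the metrication error
under one voxel on a 50-voxel grid where the plain 26-neighbourhood errs by
up to 8%.  The exact discrete minimum-time path (`traceback`) serves as the
backtracing operation; it is deterministic and terminates on the seed set
by construction.

*Reconnection:* adaptive thresholding (local-window mean + k × a global
robust MAD noise scale; the local standard deviation would be inflated by
the vessel itself) yields candidate components; satellites are joined to
the largest (root) structure by backtracing least-time paths with speed =
image intensity, each bridge dilated to a tube of the mean radius of the
two structures, farthest-first by default.

*Graph extraction:* with speed = (distance-to-background + ξ), ξ = 0.1 mm,
fronts grown from the root points (mask ∩ organ convex-hull boundary) are
fastest along the medial axis; leaves are regional maxima of T (one per
connected plateau, at its centroid-nearest member), and backtracing each
leaf, farthest first, traces the centerlines.  A node is created where a
path meets a previously traced path — 26-adjacency counts as meeting, since
parallel branches of a two-voxel-wide medial ridge can otherwise slide past
each other — or a root point, splitting the met edge.  Terminal twigs
shorter than twice the local tube radius are pruned (they are rim artefacts
of the leaf detector, e.g. at the far side of the root cross-section) and
pass-through junctions are merged.  Edge length is the geodesic medial-axis
length; edge radius the mean distance-to-background along the axis.

## Tracer transport

Every advective coupling is a directed volumetric link (donor, receiver,
flow rate): upwind fluxes across voxel faces, perfusion exchange donating
from the upstream compartment (c_a when p_a ≥ p_v), kernel-weighted
exchange between terminals and tissue donating from the upstream side,
plug-flow chains of per-edge subsegments (one per medial-axis voxel, the
remaining vessel voxels assigned to the nearest axis point, ordered
downstream by the solved flow), gamma-variate AIF inflow at arterial roots,
and free outflow at venous roots.  Node and subsegment volumes use full
porosity.  The operator built from links is conservative by construction,
so the step-wise mass audit (inflow − outflow = change of stored mass)
holds to solver precision; it is an M-matrix, so backward Euler preserves
positivity for any step size.  The step is 10× the strictest explicit CFL
bound (capacity/outflux over all control volumes), the simulation window
120 s, and the factorisation of (I − δt B) is computed once and reused.

TTP is the argmax over time of the observable concentration
C = (c_a φ_a + c_v φ_v)(1 − Hct) per voxel (nan where the curve stays
flat); MTT is the kinetic identity (φ_a + φ_v)/P where P > 0.  The AIF
delay t₀ defaults to 7.5 s so the bolus falls inside the 120 s window; C₀
defaults to 1 mol m⁻³ and scales all concentrations linearly.

## Parameters

Two presets ship with the package (YAML-overridable, units validated on
load):

| parameter | quasi-2D (`frog`) | 3D (`brain`) | unit |
|---|---|---|---|
| μ | 3.00e-3 | 3.00e-3 | Pa s |
| ε (support radius) | 10.0 | 30.0 | mm |
| Hct | 0.40 | 0.40 | — |
| α | 1.00e-6 | 1.00e-5 | m s kg⁻¹ |
| k_a, k_v | 1.0, 5.0 ×10⁻¹² | 12.5, 25.0 ×10⁻¹² | m² |
| φ_a, φ_v | 0.05, 0.10 | 0.05, 0.10 | — |
| p_a0, p_v0 | 10.6, 1.60 | 13.3, 0.66 | kPa |
| γ_a, γ_v | 0.01 ×10⁻¹² | 0.20 ×10⁻¹² | m³ |

In the 3D preset the grey-matter α is 1.6× the white-matter base, and the
piecewise-constant tissue parameter maps are smoothed by a truncated
Gaussian (radius 2.5 mm, σ 1.5 mm) renormalised over the organ mask,
emulating partial-volume mixing at tissue interfaces.  The kernel dimension
follows the grid (2 for single-slice, 3 otherwise); it only affects the
continuous prefactor, which cancels in the discrete renormalisation.

## Synthetic geometry

`make_paired_scenario` builds the canonical end-to-end fixtures.
*frog-like*: a 40 × 33 × 1 mm elliptical slab (single-voxel thickness, the
quasi-2D convention) with one arterial and one venous recursive binary tree
entering from the bottom boundary, interdigitated; default depth 3, first
branch 11 mm, length decay 0.65, radius decay 0.72, root radii 0.8/1.0 mm,
±5° seeded jitter.  *brain-like*: a 96 × 96 × 80 mm two-tissue ellipsoid
(inner "white" core at 0.6 of the semi-axes, outer "grey" shell with 1.6×
α) whose trees penetrate shallowly and spread tangentially (depth 4, 12 mm
branches, decay 0.85, 65° bifurcations) so that most terminals lie in the
shell — the way pial arteries supply real cortex; with terminals in the
core the core would win a supply advantage and invert the grey/white
perfusion contrast, which is physiologically wrong for brain.  Tubes are
rasterised by physical distance-to-segment ≤ radius, radii floored at half
a voxel so every branch survives rasterisation; the exact graph used for
rasterisation is returned as ground truth.  All generators are
deterministic given their seed.  A resolution-scale argument refines the
grid while keeping the physical geometry, parameters and graphs fixed —
the scale-invariance experiment: ROI-mean perfusion moves by < 1% between
scales 1, 2 and 4 and converges monotonically.

What the generator does *not* emulate: real angiographic intensity
statistics (vesselness, flow-related enhancement, susceptibility contrast),
anatomically realistic tortuosity and space-filling tree growth, venous
sinuses, or co-registration error between modalities.  Passing tests on
these fixtures therefore validates the numerics and the geometric
operations, not segmentation quality on clinical data.

## Problem sizes

Default study sizes are chosen for single-core desk runs: the quasi-2D
scenario runs at 120 × 100 (test fixtures 96 × 80, scale series 80 × 66 ×
{1,2,4}), the 3D scenario at 36 × 36 × 32 (~16k masked voxels).  These are
scaled-down versions of the native grids the model targets (hundreds of
voxels per axis in 2D, ~14M masked voxels for a full human brain at
0.49 mm, which the same code addresses through the GMRES path given
cluster-scale memory and hours of runtime).

## Numerical choices and edge cases

* Dirichlet rows are identity-substituted; root-terminal classification
  tolerates one voxel diagonal of distance to the discrete boundary.
* Node volumes |N_k| (needed by the tracer): vessel-mask voxels nearer the
  node centre than any edge-interior medial-axis point, floored at one
  voxel; without a mask, a sphere of the mean incident edge radius.
* Edges with exactly zero solved flow keep their j→k subsegment order and
  are flagged with a warning; they carry no tracer links.
* A kernel whose support contains no masked voxel raises ("orphan
  terminal"); a support smaller than one voxel degenerates to the nearest
  masked voxel (the Dirac limit).
* Sensitivity derivatives default to forward differences at 1%
  (central optional); fields are perturbed by a single global factor.
  Outputs near zero are flagged undefined (nan) rather than divided by.

## Known limitations

Constant μ and Hct (no Fåhræus–Lindqvist radius dependence), rigid vessel
walls, no pulsatility, no tracer diffusion, no blood-brain-barrier leakage,
isotropic permeability.  The quasi-2D treatment represents single-slice
data as 3D arrays of thickness one voxel.  Extraction assumes co-registered
axis-aligned volumes; rotated NIfTI affines are rejected rather than
resampled.
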