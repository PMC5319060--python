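# Methods

## Model

The organ is discretized as a uniform hexahedral mesh built directly from
the labeled segmentation: every foreground voxel becomes one axis-aligned
8-node element carrying exactly one tissue label (background, parenchyma,
vessel, tumor). This avoids surface reconstruction entirely; the price is
a jagged voxel boundary, which is intrinsic to the representation.

Deformation follows total-Lagrangian explicit dynamics (TLED): stresses
and strains are referred to the rest configuration, so element
shape-function derivatives (identical for all box elements of one mesh)
are computed once. The equations of motion

    M ẍ + α M ẋ + f_int(x) = R

use a lumped mass matrix and mass-proportional damping, integrated by the
damped central-difference scheme. The material is compressible
Neo-Hookean, W = μ/2 (I₁ − 3) − μ ln J + λ/2 (ln J)², so the second
Piola–Kirchhoff stress is S = μ(I − C⁻¹) + λ ln J C⁻¹. Element inversion
(det F ≤ 0) aborts with the element id.

Quadrature is one-point (reduced) with stiffness-type hourglass control,
the standard hexahedral choice at near-incompressible Poisson ratios
where full integration locks volumetrically; the hourglass base vectors
are exactly orthogonal to affine fields on unwarped box elements, so the
stabilization never pollutes patch-test states. Full 2×2×2 Gauss
quadrature is available as a config option and is what the verification
problems (patch test, bar-vs-linear-FEM oracle) use, since their fields
make locking irrelevant there.

## Tissue–tissue coupling

Vertices shared by parenchyma and lesion elements are split into a
parenchyma-side copy bp and a lesion-side copy bq at the same rest
position. Split vertices are massless slaves: they are never integrated;
each side's position is the moving-least-squares (MLS) reconstruction
from its own tissue's non-boundary nodes (linear basis, cubic-spline
kernel, support radius 1.5× the grid spacing, grown by 1.3× — up to five
times — when the captured node set is too small or degenerate). Linear
consistency of MLS makes both reconstructions exact at rest, so the rest
gap is identically zero.

The pair is coupled by a penalty spring on the gap δ = bp − bq with force
f = −k_c δ, where k_c is k_{c,s-t} (parenchyma–tumor) or k_{c,s-v}
(parenchyma–vessel), in N/m. The parenchyma-side support nodes receive f
(pulling the parenchyma boundary back toward the lesion) and the
lesion-side nodes −f, each spread by the transposed shape functions; by
partition of unity the total coupling force is exactly zero. Element
forces assembled at slave rows are redistributed to the masters the same
way (master–slave condensation), and the slaves' lumped mass follows
their stiffness onto the masters — dropping it destabilizes the explicit
loop, because a small lesion's entire interface stiffness condenses onto
a handful of interior nodes.

The Signorini complementarity between gap and contact force holds only in
the penalty limit k_c → ∞; the implementation therefore reports the
per-pair complementarity residual |f·δ| = k_c|δ|² and gap magnitudes
rather than enforcing the exact law.

A deliberate consequence of same-tissue support domains: a lesion needs
at least four non-coplanar interior (non-shared) vertices, i.e. roughly
three elements across. A single-element lesion is rejected with the
offending vertex named; at the default phantom resolution both lesions
are comfortably above the limit.

## Solver settings

- **Damping.** The library default is α = 5 s⁻¹. For registration only
  the equilibrium matters and it is independent of α and ρ, so the
  phantom pipeline uses dynamic relaxation: `alpha: "auto"` sets
  α ≈ 2ω₁, with ω₁ estimated from the softest shear wave speed and the
  largest mesh extent. This converges in 1–2 thousand steps instead of
  tens of thousands.
- **Mass scaling.** For the same reason the per-tissue densities are
  rescaled (default on) so all materials share the slowest dilatational
  wave speed; the Courant limit is then set by the soft parenchyma, not
  the 25× stiffer tumor. Equilibria are unchanged; only the (unused)
  transient is.
- **Time step.** The per-element Courant estimate dt = safety·h/c_dil is
  refined by a power iteration on the true linearized operator (assembly,
  hourglass modes, slave condensation and coupling springs all shift the
  largest eigenfrequency; boundary nodes with few incident elements push
  it a few percent above the element formula). The refined dt is cached
  per coupling-coefficient pair.
- **Convergence.** Equilibrium is declared when the maximum nodal speed
  stays below `tol` (default 1e-4 m/s; the phantom pipeline uses
  3e-4 m/s) for 100 consecutive steps after the load ramp. At α ≈ 2ω₁
  the residual displacement error at this threshold is ~tol/ω₁, well
  below 0.001 mm on the test phantom — verified by comparing equilibria
  at tolerances an order of magnitude apart.
- **Warm starts.** Repeated solves of the same scenario at different
  coupling coefficients restart from the previous equilibrium with the
  ramp skipped; the converged state is unaffected (checked against cold
  starts to 1e-4 mm) within the single-equilibrium regime below.

## Boundary conditions

A compression scenario is a rigid-plate push on a top-surface patch: the
plate first touches the locally highest contacted node and, after
travelling the scenario magnitude m, has displaced every node of depth d
below that crown by (m − d) along the push direction; deeper nodes are
untouched. Bottom-facing surface nodes are fixed (the phantom rests in a
form-fitting cradle). All three displacement components are prescribed at
contacted nodes (the surface sticks to the plate).

At deep compressions the quasi-static problem can lose uniqueness: on the
default phantom, a 12 mm central push develops two stable bulging
branches (snap-through), making results path-dependent. The generator's
magnitude range therefore stops at 10 mm, where warm- and cold-started
equilibria agree to 1e-4 mm.

## Data-driven coupling-coefficient estimation

The objective is the summed squared landmark residual over the training
compressions, each evaluation being a full forward equilibrium. Search:
log-spaced grid over [50, 5000] N/m per coefficient (default 7×7),
followed by Nelder–Mead refinement in log-space from the best cell
(xatol 0.005 ≈ 1% in k). The grid phase may use a looser equilibrium
tolerance (it only ranks cells); the refinement re-solves at the solver's
own tolerance. Forward failures at extreme corners (element inversion at
very soft coupling under deep compression) score +inf instead of
aborting. With noiseless self-generated ground truth the objective
vanishes at the generating coefficients and the estimator recovers them
to a fraction of a percent; identifiability under noise is set by the
lesion-landmark sensitivity ∂x/∂ln k (about 0.3 mm per ln-unit at
centimeter-scale compressions on the default phantom).

## Coarse-to-fine detail enrichment

The fine mesh is coarsened onto an aligned lower-resolution grid (blocks
must divide the fine grid exactly): a coarse element exists iff its block
contains a foreground fine cell, its label is the majority foreground
label with ties preferring tumor > vessel > parenchyma (so coarsening
never erases heterogeneity), and coincident coarse/fine nodes are
recorded. On jagged boundaries some coarse corner nodes have no
coincident fine node; the correspondence is the partial map over those
that do. The low-resolution model assigns per-element materials directly
(no vertex splitting) — heterogeneous stiffness, direct force
transmission.

For each stored compression condition, both models are run to
equilibrium; every fine vertex (including both copies of split vertices)
is assigned to its containing coarse element in the rest configuration
(lowest element id on shared faces, nearest element for vertices outside
all coarse boxes) and fitted with MLS weights over the 8 deformed coarse
vertices at the fine vertex's deformed position. The element-level fit
uses an interpolating MLS variant (regularized singular kernel with an
exact-node shortcut) so fine vertices coincident with coarse vertices
track them exactly; linear reproduction makes every record
self-consistent at fit time, bounded at 1e-8 m by the single-precision
weight storage. Lookup picks the record minimizing
w_p·‖Δpatch-centroid‖ + w_a·angle + w_m·|Δmagnitude| (defaults 100 m⁻¹,
1 rad⁻¹, 100 m⁻¹), ties broken by smaller magnitude difference then
lowest record id; a single nearest record is used, no blending.

## Synthetic phantom

The generator emulates the physical study object: a parenchyma ellipsoid
(default 16×8×12 cells at 5 mm ≈ an 7×4×5 cm organ) with one tumor
sphere (radius 1.9 cells) and one vessel tube (radius 1.8 cells), labeled
by analytic membership of voxel centers with precedence
tumor > vessel > parenchyma, and lesions validated to sit strictly inside
the organ. Landmarks are sampled (seeded) on boundary voxels: 11 on the
organ surface, 7 on the tumor boundary, 7 on the vessel boundary — the
25-landmark, 11-surface/14-internal protocol. Compression scenarios are
plate pushes: patches ~3 cm across at positions spread along the organ,
magnitudes 5–10 mm, orientations inside a 15° cone about the inward
normal (the first orientation is the exact normal). These magnitudes are
chosen to produce landmark displacements of a few millimeters — the
regime in which registration errors of the reported scale arise at all;
materials are E = 2×10⁵ / 1×10⁶ / 5×10⁶ Pa for parenchyma / vessel /
tumor with ν = 0.49, and ground-truth coupling coefficients default to
(600, 500) N/m. Observation noise is isotropic Gaussian per landmark
coordinate (0.1 mm in the shipped protocol, emulating sub-voxel landmark
localization error).

What the phantom does **not** emulate: real liver geometry (lobes,
surface concavities), multiple or branching vessels, segmentation errors,
MR intensity artifacts, rig–phantom friction, or any model mismatch —
ground truth is generated by the same forward model, so registration
errors measure noise and the coarse-to-fine approximation, not model
error. Passing tests therefore demonstrate internal consistency,
convergence and recoverability, not clinical accuracy.

## Problem sizes

The shipped protocol uses the 16×8×12 phantom (592 elements, 889 nodes,
196 split vertices) coarsened to 8×4×6 (112 elements), five compression
positions, three training / two validation datasets, a 15-condition
enrichment database in the acceptance pipeline (5 positions × 3
magnitudes) and a 12-condition database (2×3×2) in the fidelity tests.
These sizes keep a full calibrate/enrich/register cycle in the
minutes range on one CPU; the meshing, coupling and database code are
resolution-agnostic and accept the larger grids the formats allow.

## Known limitations

- The penalty coupling satisfies gap–force complementarity only
  approximately; residuals are reported, not constrained.
- The split-vertex MLS reconstruction constrains interface vertices to
  affine fits of their neighborhoods, an O(h²) model discrepancy against
  a directly connected mesh; it falls below 2% of peak displacement only
  once a lesion is resolved by ≥3 elements across on an adequately fine
  grid.
- Very deep compressions can produce multiple equilibria (snap-through);
  the explicit solver then returns a path-dependent branch. The scenario
  generator stays below the threshold observed on the default phantom.
- Single-element lesions cannot be split (no interior support); they
  require mesh refinement.
- Frame rates and speed-up factors are hardware-bound and are not part of
  this package's contracts.
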