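# hexreg

Biomechanical volumetric registration for soft organs with embedded
heterogeneities (tumors, vessels), built on voxel-derived hexahedral meshes.

Pre-operative images look inside the patient; during an intervention the
organ deforms and that link is lost. Surface registration aligns what is
visible, but the structures a surgeon must hit — or avoid — are internal.
`hexreg` predicts the volumetric deformation of a segmented organ under a
known surface load with a personalized heterogeneous finite-element model,
so that internal target positions can be registered, and provides a
coarse-to-fine scheme that trades a pre-computed database for most of the
runtime cost.

## The model

**Dynamics.** The organ is a total-Lagrangian explicit-dynamics (TLED) FEM
on a uniform hexahedral mesh built directly from the labeled voxels (one
element per foreground voxel, one tissue label per element):

```
M ẍ + D ẋ + f_int(x) = R,        D = α M
```

with lumped mass `M`, mass-proportional damping, and a compressible
Neo-Hookean material, `S = μ(I − C⁻¹) + λ ln J · C⁻¹` (second
Piola–Kirchhoff stress, `C = FᵀF`, `J = det F`). All rest-configuration
shape derivatives are precomputed; quadrature is one-point with hourglass
stabilization (full 2×2×2 Gauss available for verification). Registration
uses the damped equilibrium (dynamic relaxation).

**Tissue–tissue coupling.** Each mesh vertex shared by parenchyma and a
lesion is split into two massless copies `bp_i` (parenchyma side) and
`bq_i` (lesion side). Each copy is reconstructed by moving least squares
(MLS) from its own tissue's interior nodes,

```
bp_i = Φ_p,i · P_i ,     bq_i = Φ_q,i · Q_i ,
```

and the pair is tied by a penalty spring on the gap `δ = bp_i − bq_i`:

```
f_i = −k_c δ ,      k_c ∈ {k_{c,s-t}, k_{c,s-v}}   [N/m]
```

with separate coefficients for parenchyma–tumor and parenchyma–vessel
interfaces. Spring forces are spread over the support domains through the
transposed shape functions, so the net coupling force is exactly zero.

**Personalization.** The two coupling coefficients are estimated from
landmark ground truth by minimizing the summed squared landmark residual
over training compressions (log-grid search + Nelder–Mead refinement, each
evaluation a full forward equilibrium):

```
argmin_{k}  Σ_cases ‖ X_g − K(k_{c,s-t}, k_{c,s-v}) X ‖²
```

**Coarse-to-fine.** Offline, the high-resolution heterogeneous model and a
majority-label-coarsened low-resolution model are both run over a grid of
compression conditions; for every condition, each fine vertex is expressed
through interpolating-MLS weights `Φ_j,t` over the 8 deformed vertices of
its coarse element and stored in an HDF5 database. At runtime only the
cheap coarse model is solved; the nearest stored condition synthesizes the
fine microstructure as `x_j = Φ_j,tᵀ P_i`.

Because no imaging data ships with the package, a synthetic phantom module
generates the full study setup — a labeled organ (parenchyma ellipsoid,
tumor sphere, vessel tube), 25 landmarks (11 surface / 14 internal), and
plate-compression scenarios — reproducibly from a seed.

## Worked example

```python
import numpy as np
from hexreg import (Config, CouplingParams, HeterogeneousModel,
                    build_hex_mesh, build_interface, compute_tre,
                    reconstruct_boundary_positions)
from hexreg.phantom import (PhantomSpec, generate_phantom,
                            generate_scenarios, generate_ground_truth)

volume, landmarks = generate_phantom(PhantomSpec(seed=0))
mesh = build_hex_mesh(volume)
interface = build_interface(mesh)
print(f"mesh: {mesh.n_elements} elements, {mesh.n_nodes} nodes, "
      f"{interface.n_pairs} split boundary vertices")

config = Config({"solver": {"alpha": "auto", "tol": 3e-4, "ramp_steps": 400}})
model = HeterogeneousModel(mesh, config, interface=interface)
scenario = generate_scenarios(volume, n_positions=5, seed=7)[2]  # 10 mm push
state = model.solve(scenario, params=CouplingParams(600.0, 500.0))
gaps = np.linalg.norm(
    reconstruct_boundary_positions(interface, state.u).delta, axis=1)
print(f"equilibrium after {state.steps} steps; "
      f"max nodal displacement {np.abs(state.u).max()*1e3:.2f} mm; "
      f"max interface gap {gaps.max()*1e3:.3f} mm")

truth = generate_ground_truth(model, landmarks, scenario,
                              CouplingParams(600.0, 500.0),
                              sigma=1e-4, seed=42)
pred = model.predict_landmarks(state, model.embed(landmarks), landmarks)
report = compute_tre(pred, truth.observed)
print(f"TRE vs noisy observations: mean {report.mean_mm:.3f} mm "
      f"(surface {report.surface_mean_mm:.3f}, "
      f"internal {report.internal_mean_mm:.3f})")
```

prints

```
mesh: 592 elements, 889 nodes, 196 split boundary vertices
equilibrium after 1239 steps; max nodal displacement 5.13 mm; max interface gap 1.491 mm
TRE vs noisy observations: mean 0.126 mm (surface 0.129, internal 0.124)
```

The 10 mm plate compression displaces nodes by up to ~5 mm; the penalty
coupling leaves a sub-1.5 mm residual gap at the stiff-lesion interfaces;
and the model's landmark predictions agree with noisy observations of its
own ground truth at the 0.1 mm observation-noise floor.

A command-line interface wraps the same pipeline
(`hexreg phantom generate`, `hexreg mesh build/coarsen`, `hexreg simulate`,
`hexreg calibrate`, `hexreg evaluate-tre`, `hexreg enrich build/register`);
every output embeds the config hash and seed.

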