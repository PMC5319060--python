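"""High-resolution heterogeneous forward model, data-driven estimation of
the coupling coefficients, and target-registration-error evaluation.

The forward model composes the explicit TLED solver with the penalty
coupling: every step reconstructs the split boundary vertices by MLS,
evaluates the pair springs, spreads the coupling forces over the support
domains, condenses slave-row element forces onto their masters, and
advances the mass-carrying nodes.  Compression scenarios prescribe
displacements on a surface patch of the parenchyma while the base of the
organ is held fixed.

The two coupling coefficients (k_tumor, k_vessel) are estimated from
landmark ground truth by minimizing the summed squared landmark residual
over the training scenarios — a coarse logarithmic grid search followed by
Nelder-Mead refinement, every evaluation being a full forward run to
equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .coupling import (CouplingInterface, CouplingParams,
                       compute_coupling_forces, distribute_forces,
                       reconstruct_boundary_positions)
from .errors import HexregError, ValidationError
from .io import Config, LandmarkSet
from .mesh import HexMesh, embed_landmarks, interpolate_embedded
from .tled import (SimulationState, BoundaryCondition, auto_alpha,
                   critical_time_step, precompute_tled, run_to_equilibrium)

MM = 1e-3


@dataclass
class Scenario:
    """A compression condition: push a top-surface patch inward."""

    position_index: int
    patch_center: np.ndarray   # (3,) m; z component is informational
    patch_half: np.ndarray     # (3,) half extents of the x/y selection box, m
    direction: np.ndarray      # (3,) unit vector
    magnitude: float           # m

    def __post_init__(self):
        self.patch_center = np.asarray(self.patch_center, float)
        self.patch_half = np.asarray(self.patch_half, float)
        self.direction = np.asarray(self.direction, float)
        nrm = np.linalg.norm(self.direction)
        if abs(nrm - 1.0) > 1e-12:
            raise ValidationError(f"direction must be unit norm, got {nrm}")
        if self.magnitude < 0:
            raise ValidationError("magnitude must be >= 0")

    @property
    def displacement(self):
        return self.magnitude * self.direction

    def to_dict(self):
        return {
            "position_index": int(self.position_index),
            "patch_center": [float(v) for v in self.patch_center],
            "patch_half": [float(v) for v in self.patch_half],
            "direction": [float(v) for v in self.direction],
            "magnitude": float(self.magnitude),
        }

    @classmethod
    def from_dict(cls, d):
        return cls(position_index=d["position_index"],
                   patch_center=np.asarray(d["patch_center"]),
                   patch_half=np.asarray(d["patch_half"]),
                   direction=np.asarray(d["direction"]),
                   magnitude=d["magnitude"])


def scenario_boundary_condition(mesh: HexMesh, scenario: Scenario,
                                ramp_steps=300) -> BoundaryCondition:
    """Translate a scenario into nodal constraints.

    The compression emulates a rigid plate: among the nodes on
    upward-facing boundary faces inside the patch box, the plate first
    touches the locally highest point (the crown) and, after travelling
    the scenario magnitude m, has displaced every node whose depth d below
    the crown is smaller than m by (m - d) along the push direction.
    Nodes deeper than the travel are never contacted.  Nodes on
    downward-facing boundary faces are fixed (the organ rests in a
    form-fitting cradle)."""
    faces, _owners, axis_code = mesh.boundary_faces()
    top_nodes = np.unique(faces[axis_code == 5])
    bottom_nodes = np.unique(faces[axis_code == 4])
    pos = mesh.nodes[top_nodes]
    inside = (np.abs(pos[:, 0] - scenario.patch_center[0]) <= scenario.patch_half[0] + 1e-12) & \
             (np.abs(pos[:, 1] - scenario.patch_center[1]) <= scenario.patch_half[1] + 1e-12)
    if scenario.magnitude > 0 and not inside.any():
        raise ValidationError(
            f"scenario position {scenario.position_index}: empty surface patch")
    box = top_nodes[inside]
    depth = mesh.nodes[box, 2].max() - mesh.nodes[box, 2] if len(box) else \
        np.zeros(0)
    travel = scenario.magnitude - depth
    contacted = travel > 1e-12
    patch = box[contacted]
    disp = travel[contacted, None] * scenario.direction
    fixed = np.setdiff1d(bottom_nodes, patch)
    return BoundaryCondition(fixed=fixed.astype(np.int64),
                             prescribed=patch.astype(np.int64),
                             prescribed_disp=disp, ramp_steps=ramp_steps)


@dataclass
class TrainingCase:
    scenario: Scenario
    truth: LandmarkSet         # observed (possibly noisy) deformed landmarks


@dataclass
class TREReport:
    ids: list
    errors_mm: np.ndarray
    categories: list

    def _mean(self, mask):
        mask = np.asarray(mask, bool)
        return float(self.errors_mm[mask].mean()) if mask.any() else float("nan")

    @property
    def mean_mm(self):
        return float(self.errors_mm.mean())

    @property
    def surface_mean_mm(self):
        return self._mean([c == "surface" for c in self.categories])

    @property
    def internal_mean_mm(self):
        return self._mean([c != "surface" for c in self.categories])

    @property
    def tumor_mean_mm(self):
        return self._mean([c == "internal-tumor" for c in self.categories])

    @property
    def vessel_mean_mm(self):
        return self._mean([c == "internal-vessel" for c in self.categories])

    def summary(self):
        return {
            "mean_mm": self.mean_mm,
            "surface_mean_mm": self.surface_mean_mm,
            "internal_mean_mm": self.internal_mean_mm,
            "tumor_mean_mm": self.tumor_mean_mm,
            "vessel_mean_mm": self.vessel_mean_mm,
        }


def compute_tre(predicted: LandmarkSet, truth: LandmarkSet) -> TREReport:
    """Per-landmark Euclidean error (mm) with category means."""
    pred_idx = {i: k for k, i in enumerate(predicted.ids)}
    missing = [i for i in truth.ids if i not in pred_idx]
    if missing or len(predicted) != len(truth):
        extra = [i for i in predicted.ids if i not in set(truth.ids)]
        raise ValidationError(
            f"landmark id mismatch (missing from prediction: {missing}, "
            f"unmatched in prediction: {extra})")
    order = [pred_idx[i] for i in truth.ids]
    err = np.linalg.norm(predicted.positions[order] - truth.positions, axis=1)
    return TREReport(ids=list(truth.ids), errors_mm=err / MM,
                     categories=list(truth.categories))


class HeterogeneousModel:
    """Forward simulator for one mesh/interface pair.

    With an interface this is the split-vertex penalty-coupled model; with
    ``interface=None`` it degenerates to a plain (possibly heterogeneous-
    material) TLED model with directly shared nodes.  ``homogeneous=True``
    additionally assigns the parenchyma material to every element — the
    no-coupling comparator.
    """

    def __init__(self, mesh: HexMesh, config: Config = None, interface=None,
                 homogeneous=False):
        self.mesh = mesh
        self.config = config or Config()
        self.interface = interface
        solver = self.config["solver"]
        materials = self.config.materials()
        if homogeneous:
            materials = {lab: materials[1] for lab in materials}
        self.materials = materials
        if solver.get("mass_scaling", True):
            # quasi-static runs only use the equilibrium, which is
            # density-independent: scale each tissue's density so every
            # material shares the slowest dilatational wave speed, which
            # lifts the Courant limit to the parenchyma's
            from .tled import lame_from_youngs
            cmin2 = min((lambda ml: (ml[1] + 2 * ml[0]))(
                lame_from_youngs(E, nu)) / rho
                for E, nu, rho in materials.values())
            scaled = {}
            for lab, (E, nu, rho) in materials.items():
                mu, lam = lame_from_youngs(E, nu)
                scaled[lab] = (E, nu, (lam + 2 * mu) / cmin2)
            materials = scaled
        alpha = solver["alpha"]
        if alpha == "auto":
            alpha = auto_alpha(mesh, materials)
        if interface is not None and interface.n_pairs > 0:
            elements, n_nodes = interface.elements, interface.n_nodes
        else:
            elements, n_nodes = mesh.elements, mesh.n_nodes
        self.precomp = precompute_tled(
            mesh, materials, quadrature=solver["quadrature"],
            hourglass=solver["hourglass"], alpha=float(alpha),
            elements=elements, n_nodes=n_nodes)
        self.dt = critical_time_step(mesh, materials,
                                     safety=solver["dt_safety"])
        self.active_mask = np.ones(n_nodes, bool)
        if interface is not None and interface.n_pairs > 0:
            # master-slave condensation: slave vertices carry no mass of
            # their own, but the inertia of the elements they bound must
            # follow their stiffness onto the masters or the explicit loop
            # loses its stability margin
            m = self.precomp.mass
            m += abs(interface.W_p).T @ m[interface.bp_rows]
            m += abs(interface.W_q).T @ m[interface.bq_rows]
            self.active_mask[interface.slave_rows] = False
            m[interface.slave_rows] = 0.0
        self._solver_cfg = solver
        self._dt_cache = {}
        self._dt_element = self.dt

    def _stable_dt(self, params):
        """Per-element Courant estimate refined by the true largest
        eigenfrequency of the linearized operator (assembly, hourglass
        modes, slave condensation and the coupling springs all shift it)."""
        key = (None if params is None
               else (round(params.k_tumor, 9), round(params.k_vessel, 9)))
        dt = self._dt_cache.get(key)
        if dt is None:
            dt = min(self._dt_element,
                     0.9 * self._solver_cfg["dt_safety"] * 2.0 /
                     self._omega_max(params))
            self._dt_cache[key] = dt
        return dt

    def _omega_max(self, params=None, iters=40, eps=1e-8):
        """Largest eigenfrequency of M^-1 K at rest (power iteration on a
        finite-difference linearization of the full per-step force path)."""
        from .tled import internal_forces
        iface = self.interface
        coupled = iface is not None and iface.n_pairs > 0
        if params is None:
            cp = self.config["coupling"]
            params = CouplingParams(cp["k_tumor"], cp["k_vessel"])

        def K(u):
            if coupled:
                u = iface.update_slaves(u.copy())
            f = -internal_forces(self.precomp, u)
            if coupled:
                iface_state = reconstruct_boundary_positions(iface, u)
                fp = compute_coupling_forces(iface_state, params, iface.kinds)
                f = iface.condense(f + distribute_forces(iface, fp))
            return -f

        rng = np.random.default_rng(0)
        v = rng.normal(size=(self.n_nodes, 3))
        v[~self.active_mask] = 0.0
        v /= np.linalg.norm(v)
        lam = 0.0
        for _ in range(iters):
            w = K(eps * v) / eps
            w[self.active_mask] /= self.precomp.mass[self.active_mask, None]
            w[~self.active_mask] = 0.0
            lam = np.linalg.norm(w)
            if lam <= 0:
                return 2.0 / self._dt_element  # degenerate mesh; fall back
            v = w / lam
        return float(np.sqrt(lam))

    @property
    def n_nodes(self):
        return self.precomp.n_nodes

    @property
    def elements(self):
        return self.precomp.elements

    def node_positions(self, state):
        if self.interface is not None and self.interface.n_pairs > 0:
            return self.interface.nodes + state.u
        return self.mesh.nodes + state.u

    def solve(self, scenario: Scenario, params: CouplingParams = None,
              state=None, tol=None, max_steps=None) -> SimulationState:
        """Run the scenario to equilibrium; returns the converged state.

        ``state`` warm-starts from a previous equilibrium (the boundary
        condition ramp then acts on the remaining difference only).
        """
        solver = self._solver_cfg
        tol = solver["tol"] if tol is None else tol
        max_steps = solver["max_steps"] if max_steps is None else max_steps
        # a warm start already satisfies (nearly) the same boundary
        # condition, so the ramp would only re-introduce a transient
        ramp = solver["ramp_steps"] if state is None else 0
        bc = scenario_boundary_condition(self.mesh, scenario, ramp_steps=ramp)
        iface = self.interface
        coupled = iface is not None and iface.n_pairs > 0
        if state is None:
            state = SimulationState.zeros(self.n_nodes)
        else:
            state = state.copy()
            state.steps = 0
            state.v[:] = 0.0
        if not coupled:
            return run_to_equilibrium(
                self.precomp, bc, self._stable_dt(None), tol=tol,
                max_steps=max_steps, state=state)
        if params is None:
            cp = self.config["coupling"]
            params = CouplingParams(cp["k_tumor"], cp["k_vessel"])

        def external_force(st, _step):
            iface_state = reconstruct_boundary_positions(iface, st.u)
            f_pairs = compute_coupling_forces(iface_state, params, iface.kinds)
            return distribute_forces(iface, f_pairs)

        def post_step(st):
            iface.update_slaves(st.u)

        post_step(state)
        return run_to_equilibrium(
            self.precomp, bc, self._stable_dt(params), tol=tol,
            max_steps=max_steps, state=state, external_force=external_force,
            active_mask=self.active_mask, condense=iface.condense,
            post_step=post_step)

    def embed(self, landmarks: LandmarkSet):
        return embed_landmarks(self.mesh, landmarks)

    def predict_landmarks(self, state, embedded, landmarks: LandmarkSet
                          ) -> LandmarkSet:
        """Deformed landmark positions by trilinear interpolation on the
        (possibly split) element connectivity."""
        pos = interpolate_embedded(self.mesh, embedded,
                                   self.node_positions(state),
                                   elements=self.elements)
        return LandmarkSet(ids=list(landmarks.ids), positions=pos,
                           categories=list(landmarks.categories))


def simulate_heterogeneous(model: HeterogeneousModel, scenario: Scenario,
                           params: CouplingParams = None, **kw):
    """Functional wrapper over :meth:`HeterogeneousModel.solve`."""
    return model.solve(scenario, params=params, **kw)


@dataclass
class EstimationResult:
    params: CouplingParams
    objective: float            # summed squared landmark residual, m^2
    trace: list = field(default_factory=list)  # (k_t, k_v, objective)


def estimate_coupling_parameters(model: HeterogeneousModel, training_cases,
                                 landmarks: LandmarkSet, bounds=(50.0, 5000.0),
                                 grid_size=7, refine=True, nm_maxiter=60,
                                 warm_start=True, grid_tol=None
                                 ) -> EstimationResult:
    """Fit (k_tumor, k_vessel) to landmark ground truth.

    Coarse log-spaced ``grid_size`` x ``grid_size`` search over ``bounds``
    followed by Nelder-Mead refinement in log-space; the objective sums the
    squared landmark residuals over all training cases, each evaluated at a
    fresh forward equilibrium.  Forward runs warm-start from the previous
    equilibrium of the same case, which shrinks the transient without
    changing the converged state.
    """
    cases = list(training_cases)
    if not cases:
        raise ValidationError("empty training set")
    if len(landmarks) == 0:
        raise ValidationError("no landmarks to fit against")
    embedded = model.embed(landmarks)
    lo, hi = bounds
    warm = {}
    trace = []
    # the grid phase only has to rank cells; a looser equilibrium
    # tolerance there is cheaper and the refinement re-solves tightly
    phase_tol = {"tol": grid_tol}

    def objective(log10_k):
        k = 10.0 ** np.clip(log10_k, np.log10(lo), np.log10(hi))
        params = CouplingParams(float(k[0]), float(k[1]))
        total = 0.0
        for ci, case in enumerate(cases):
            try:
                state = model.solve(case.scenario, params=params,
                                    state=warm.get(ci) if warm_start else None,
                                    tol=phase_tol["tol"])
            except HexregError:
                # e.g. element inversion at an extreme corner of the search
                # box; score it out of contention instead of aborting
                total = np.inf
                break
            if warm_start:
                warm[ci] = state
            pred = model.predict_landmarks(state, embedded, landmarks)
            order = {i: j for j, i in enumerate(pred.ids)}
            idx = [order[i] for i in case.truth.ids]
            total += float(np.sum(
                (pred.positions[idx] - case.truth.positions) ** 2))
        trace.append((float(k[0]), float(k[1]), total))
        return total

    grid = np.linspace(np.log10(lo), np.log10(hi), grid_size)
    best_val, best_pt = np.inf, None
    for gt in grid:
        for gv in grid:
            val = objective(np.array([gt, gv]))
            if val < best_val:
                best_val, best_pt = val, np.array([gt, gv])
    if best_pt is None:
        raise ValidationError("all objective evaluations failed")
    phase_tol["tol"] = None  # refinement at the solver's own tolerance
    if refine:
        best_val = objective(best_pt)
        step = float(grid[1] - grid[0]) if grid_size > 1 else 0.2
        res = minimize(objective, best_pt, method="Nelder-Mead",
                       options={"maxiter": nm_maxiter,
                                "xatol": 0.005, "fatol": 0.0,
                                "initial_simplex": np.array([
                                    best_pt,
                                    best_pt + [0.5 * step, 0.0],
                                    best_pt + [0.0, 0.5 * step]])})
        if res.fun < best_val:
            best_val, best_pt = float(res.fun), res.x
    k = 10.0 ** np.clip(best_pt, np.log10(lo), np.log10(hi))
    return EstimationResult(params=CouplingParams(float(k[0]), float(k[1])),
                            objective=best_val, trace=trace)
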