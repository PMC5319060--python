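"""Total-Lagrangian explicit-dynamics FEM on uniform hexahedral meshes.

The semi-discrete equations of motion

    M x'' + D x' + f_int(x) = R,      D = alpha * M

are integrated with the damped central-difference scheme on a lumped mass
matrix.  Stresses and strains are referred to the rest configuration, so
the element shape-function derivatives (identical for every axis-aligned
box element) are precomputed once.  The material is compressible
Neo-Hookean,

    W = mu/2 (I1 - 3) - mu ln J + lambda/2 (ln J)^2
    S = mu (I - C^-1) + lambda ln J C^-1,

with S the second Piola-Kirchhoff stress, C = F^T F and J = det F.

Quadrature is one-point (reduced) with perturbation hourglass
stabilization by default — the standard choice for this element at
near-incompressible Poisson ratios, where full integration locks
volumetrically.  Full 2x2x2 Gauss quadrature is available as a config
alternative for verification problems.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import _kernels
from .errors import (ConvergenceError, DivergenceError, ElementInversionError,
                     ValidationError)
from .mesh import NATURAL_SIGNS, HexMesh

_GAUSS = 1.0 / np.sqrt(3.0)


def lame_from_youngs(E, nu):
    """Lame parameters (mu, lambda) from Young's modulus and Poisson ratio."""
    if E <= 0:
        raise ValidationError(f"Young's modulus must be > 0, got {E}")
    if not 0 <= nu < 0.5:
        raise ValidationError(
            f"Poisson ratio must be in [0, 0.5); got {nu} "
            "(the incompressible limit is unsupported by this material form)")
    mu = E / (2.0 * (1.0 + nu))
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    return mu, lam


def dilatational_wave_speed(E, nu, rho):
    mu, lam = lame_from_youngs(E, nu)
    return np.sqrt((lam + 2.0 * mu) / rho)


def pk2_neo_hookean(F, mu, lam):
    """Second Piola-Kirchhoff stress of the compressible Neo-Hookean
    material for a single deformation gradient."""
    F = np.asarray(F, float)
    J = np.linalg.det(F)
    if J <= 0:
        raise ElementInversionError(f"element inversion: det F = {J:.4g} <= 0")
    C = F.T @ F
    Cinv = np.linalg.inv(C)
    return mu * (np.eye(3) - Cinv) + lam * np.log(J) * Cinv


def _shape_derivatives(spacing, quadrature):
    """dN_a/dX at each quadrature point for an axis-aligned box element.

    Returns (B, wvol): B has shape (ngp, 8, 3); wvol (ngp,) are quadrature
    volume fractions (summing to 1)."""
    h = np.asarray(spacing, float)
    if quadrature == "1pt":
        gps = np.zeros((1, 3))
        wvol = np.array([1.0])
    elif quadrature == "8pt":
        gps = NATURAL_SIGNS * _GAUSS
        wvol = np.full(8, 1.0 / 8.0)
    else:
        raise ValidationError(f"unknown quadrature {quadrature!r}")
    B = np.empty((len(gps), 8, 3))
    s = NATURAL_SIGNS  # (8, 3)
    for g, xi in enumerate(gps):
        for a in range(8):
            terms = 1.0 + s[a] * xi  # per-axis factors
            for d in range(3):
                other = [0, 1, 2]
                other.remove(d)
                B[g, a, d] = (s[a, d] / 8.0 * terms[other[0]] * terms[other[1]]
                              ) * 2.0 / h[d]
    return B, wvol


# hourglass base vectors for the 8-node hex (modes xi*eta, eta*zeta,
# xi*zeta, xi*eta*zeta evaluated at the corners); for unwarped box elements
# these are orthogonal to all affine fields.
_S = NATURAL_SIGNS
HOURGLASS_GAMMA = np.stack([
    _S[:, 0] * _S[:, 1],
    _S[:, 1] * _S[:, 2],
    _S[:, 0] * _S[:, 2],
    _S[:, 0] * _S[:, 1] * _S[:, 2],
], axis=1)  # (8, 4)


@dataclass
class TLEDPrecomp:
    mesh: HexMesh
    elements: np.ndarray       # (E, 8) possibly re-indexed (split interfaces)
    n_nodes: int
    B: np.ndarray              # (ngp, 8, 3) rest shape derivatives
    wvol: np.ndarray           # (ngp,) volume fractions
    volume: np.ndarray         # (E,) rest element volumes
    mu: np.ndarray             # (E,)
    lam: np.ndarray            # (E,)
    rho: np.ndarray            # (E,)
    mass: np.ndarray           # (N,) lumped nodal mass
    scatter: sp.csr_matrix     # (N, E*8) assembly operator
    kappa: np.ndarray          # (E,) hourglass stiffness (0 for 8pt)
    alpha: float = 5.0         # mass-proportional damping, 1/s

    @property
    def n_elements(self):
        return len(self.elements)


def precompute_tled(mesh: HexMesh, materials: dict, quadrature="1pt",
                    hourglass=0.1, alpha=5.0, elements=None, n_nodes=None
                    ) -> TLEDPrecomp:
    """Precompute rest-configuration quantities for the explicit loop.

    ``materials`` maps tissue label -> (E_pa, nu, rho).  ``elements`` /
    ``n_nodes`` override the mesh connectivity when boundary vertices have
    been split onto duplicated nodes.
    """
    if elements is None:
        elements = mesh.elements
    if n_nodes is None:
        n_nodes = int(elements.max()) + 1
    labels = mesh.element_label
    missing = sorted(set(int(l) for l in np.unique(labels)) - set(materials))
    if missing:
        raise ValidationError(f"no material for label(s) {missing}")
    E_arr = np.empty(len(labels))
    nu_arr = np.empty(len(labels))
    rho = np.empty(len(labels))
    for lab, (E, nu, r) in materials.items():
        m = labels == lab
        E_arr[m], nu_arr[m], rho[m] = E, nu, r
    mu = np.empty(len(labels))
    lam = np.empty(len(labels))
    for e in range(len(labels)):
        mu[e], lam[e] = lame_from_youngs(E_arr[e], nu_arr[e])
    B, wvol = _shape_derivatives(mesh.spacing, quadrature)
    V = np.full(len(labels), mesh.cell_volume)
    mass = np.zeros(n_nodes)
    np.add.at(mass, elements.ravel(),
              np.repeat(rho * V / 8.0, 8))
    rows = elements.ravel()
    cols = np.arange(elements.size)
    scatter = sp.csr_matrix((np.ones(elements.size), (rows, cols)),
                            shape=(n_nodes, elements.size))
    if quadrature == "1pt":
        # stiffness-type perturbation control: f = kappa * Gamma (Gamma . u)
        h_mean = float(np.mean(mesh.spacing))
        kappa = hourglass * mu * V / h_mean ** 2 / 8.0
    else:
        kappa = np.zeros(len(labels))
    return TLEDPrecomp(mesh=mesh, elements=np.asarray(elements, np.int64),
                       n_nodes=n_nodes, B=B, wvol=wvol, volume=V, mu=mu,
                       lam=lam, rho=rho, mass=mass, scatter=scatter,
                       kappa=kappa, alpha=alpha)


def _batched_inv_det_sym(C):
    """Inverse and determinant of a batch of symmetric 3x3 matrices via the
    adjugate (faster than np.linalg.inv for many small matrices)."""
    c00, c01, c02 = C[:, 0, 0], C[:, 0, 1], C[:, 0, 2]
    c11, c12, c22 = C[:, 1, 1], C[:, 1, 2], C[:, 2, 2]
    a00 = c11 * c22 - c12 * c12
    a01 = c02 * c12 - c01 * c22
    a02 = c01 * c12 - c02 * c11
    a11 = c00 * c22 - c02 * c02
    a12 = c02 * c01 - c00 * c12
    a22 = c00 * c11 - c01 * c01
    det = c00 * a00 + c01 * a01 + c02 * a02
    inv = np.empty_like(C)
    inv[:, 0, 0], inv[:, 0, 1], inv[:, 0, 2] = a00, a01, a02
    inv[:, 1, 0], inv[:, 1, 1], inv[:, 1, 2] = a01, a11, a12
    inv[:, 2, 0], inv[:, 2, 1], inv[:, 2, 2] = a02, a12, a22
    inv /= det[:, None, None]
    return inv, det


def internal_forces(precomp: TLEDPrecomp, u):
    """Nodal internal (elastic + hourglass) forces for displacements ``u``
    (N, 3); total-Lagrangian assembly over all quadrature points."""
    u = np.asarray(u, float).reshape(precomp.n_nodes, 3)
    if _kernels.HAVE_NUMBA:
        f, bad = _kernels.assemble_internal_forces(
            precomp.elements, u, precomp.B, precomp.wvol, precomp.volume,
            precomp.mu, precomp.lam, precomp.kappa, HOURGLASS_GAMMA,
            precomp.n_nodes)
        if bad >= 0:
            raise ElementInversionError(
                f"element inversion in element {bad}", element=bad)
        return f
    ue = u[precomp.elements]                       # (E, 8, 3)
    fe = np.zeros_like(ue)
    eye = np.eye(3)
    for g in range(len(precomp.B)):
        Bg = precomp.B[g]                          # (8, 3)
        F = eye + np.matmul(ue.transpose(0, 2, 1), Bg)   # (E, 3, 3)
        detF = (F[:, 0, 0] * (F[:, 1, 1] * F[:, 2, 2] - F[:, 1, 2] * F[:, 2, 1])
                - F[:, 0, 1] * (F[:, 1, 0] * F[:, 2, 2] - F[:, 1, 2] * F[:, 2, 0])
                + F[:, 0, 2] * (F[:, 1, 0] * F[:, 2, 1] - F[:, 1, 1] * F[:, 2, 0]))
        if np.any(detF <= 0):
            bad = int(np.argmax(detF <= 0))
            raise ElementInversionError(
                f"element inversion in element {bad} (det F = "
                f"{detF[bad]:.4g})", element=bad)
        C = np.matmul(F.transpose(0, 2, 1), F)
        Cinv, detC = _batched_inv_det_sym(C)
        lnJ = 0.5 * np.log(detC)
        S = (precomp.mu[:, None, None] * (eye - Cinv)
             + (precomp.lam * lnJ)[:, None, None] * Cinv)
        P = np.matmul(F, S)                        # first Piola-Kirchhoff
        Vg = precomp.volume * precomp.wvol[g]
        fe += Vg[:, None, None] * np.matmul(Bg, P.transpose(0, 2, 1))
    if precomp.kappa.any():
        q = np.matmul(HOURGLASS_GAMMA.T, ue)       # (E, 4, 3)
        fe += precomp.kappa[:, None, None] * np.matmul(HOURGLASS_GAMMA, q)
    return precomp.scatter @ fe.reshape(-1, 3)


def strain_energy(precomp: TLEDPrecomp, u):
    """Total stored energy (elastic + hourglass), J."""
    u = np.asarray(u, float).reshape(precomp.n_nodes, 3)
    ue = u[precomp.elements]
    eye = np.eye(3)
    W = 0.0
    for g in range(len(precomp.B)):
        H = np.einsum("eai,aj->eij", ue, precomp.B[g])
        F = eye + H
        C = np.einsum("eki,ekj->eij", F, F)
        I1 = np.trace(C, axis1=1, axis2=2)
        detC = np.linalg.det(C)
        lnJ = 0.5 * np.log(detC)
        Wd = (0.5 * precomp.mu * (I1 - 3.0) - precomp.mu * lnJ
              + 0.5 * precomp.lam * lnJ ** 2)
        W += float(np.sum(precomp.volume * precomp.wvol[g] * Wd))
    if precomp.kappa.any():
        q = np.einsum("am,eai->emi", HOURGLASS_GAMMA, ue)
        W += float(np.sum(0.5 * precomp.kappa * np.sum(q ** 2, axis=(1, 2))))
    return W


def critical_time_step(mesh: HexMesh, materials: dict, safety=0.8):
    """Courant-limited time step: safety * min(edge / dilatational wave
    speed) over elements/materials."""
    if not 0 < safety <= 1:
        raise ValidationError(f"safety factor must be in (0, 1], got {safety}")
    edge = float(np.min(mesh.spacing))
    dt = np.inf
    for lab in np.unique(mesh.element_label):
        E, nu, rho = materials[int(lab)]
        dt = min(dt, edge / dilatational_wave_speed(E, nu, rho))
    return safety * dt


@dataclass
class SimulationState:
    u: np.ndarray              # (N, 3) displacements, m
    v: np.ndarray              # (N, 3) velocities, m/s
    time: float = 0.0
    steps: int = 0

    @classmethod
    def zeros(cls, n_nodes):
        return cls(u=np.zeros((n_nodes, 3)), v=np.zeros((n_nodes, 3)))

    def copy(self):
        return SimulationState(u=self.u.copy(), v=self.v.copy(),
                               time=self.time, steps=self.steps)


@dataclass
class BoundaryCondition:
    """Fixed (zero) and prescribed nodal displacements with a linear ramp."""

    fixed: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int64))
    prescribed: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int64))
    prescribed_disp: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    ramp_steps: int = 1

    def factor(self, step):
        if self.ramp_steps <= 0:
            return 1.0
        return min(1.0, step / self.ramp_steps)

    def apply(self, state, step):
        f = self.factor(step)
        state.u[self.fixed] = 0.0
        state.v[self.fixed] = 0.0
        state.u[self.prescribed] = f * self.prescribed_disp
        state.v[self.prescribed] = 0.0

    def constrained(self):
        return np.concatenate([self.fixed, self.prescribed])


def advance_step(precomp: TLEDPrecomp, state: SimulationState, external_forces,
                 bc: BoundaryCondition, dt, active_mask=None, condense=None):
    """One damped central-difference step of M x'' + alpha M x' + f_int = R.

    ``active_mask`` marks mass-carrying integrated nodes (split boundary
    vertices are massless slaves, excluded here and updated by the caller);
    ``condense`` optionally redistributes the net force at slave rows onto
    their masters before integration.  Mutates and returns ``state``.
    """
    f_net = -internal_forces(precomp, state.u)
    if external_forces is not None:
        f_net = f_net + external_forces
    if condense is not None:
        f_net = condense(f_net)
    if active_mask is None:
        m = precomp.mass
        if np.any(m <= 0):
            raise ValidationError("zero-mass node outside active_mask")
        a = f_net / m[:, None]
    else:
        a = np.zeros_like(f_net)
        m = precomp.mass[active_mask]
        a[active_mask] = f_net[active_mask] / m[:, None]
    c = 0.5 * precomp.alpha * dt
    if active_mask is None:
        state.v = ((1.0 - c) * state.v + dt * a) / (1.0 + c)
        state.u = state.u + dt * state.v
    else:
        state.v[active_mask] = (((1.0 - c) * state.v[active_mask]
                                 + dt * a[active_mask]) / (1.0 + c))
        state.u[active_mask] += dt * state.v[active_mask]
    state.steps += 1
    state.time += dt
    if bc is not None:
        bc.apply(state, state.steps)
    if not (np.all(np.isfinite(state.u)) and np.all(np.isfinite(state.v))):
        raise DivergenceError(
            "divergence: NaN/Inf in state; reduce the time step")
    return state


def run_to_equilibrium(precomp: TLEDPrecomp, bc: BoundaryCondition, dt,
                       tol=1e-4, max_steps=200000, state=None,
                       external_force=None, active_mask=None, condense=None,
                       post_step=None, settle_window=100):
    """Step until the maximum nodal speed stays below ``tol`` (m/s) for
    ``settle_window`` consecutive steps after the load ramp completes.

    ``external_force(state, step)`` may supply per-step applied/coupling
    forces; ``post_step(state)`` runs after each update (e.g. to refresh
    slave-vertex positions).  Returns the converged state.
    """
    if tol <= 0:
        raise ValidationError("tol must be > 0")
    if state is None:
        state = SimulationState.zeros(precomp.n_nodes)
    below = 0
    start = state.steps
    ramp_end = start + (bc.ramp_steps if bc is not None else 0)
    for _ in range(max_steps):
        f_ext = external_force(state, state.steps) if external_force else None
        advance_step(precomp, state, f_ext, bc, dt, active_mask=active_mask,
                     condense=condense)
        if post_step is not None:
            post_step(state)
        if active_mask is None:
            vmax = float(np.abs(state.v).max()) if state.v.size else 0.0
        else:
            vmax = float(np.abs(state.v[active_mask]).max())
        if state.steps >= ramp_end and vmax < tol:
            below += 1
            if below >= settle_window:
                return state
        else:
            below = 0
    raise ConvergenceError(
        f"no equilibrium after {max_steps} steps (max speed {vmax:.3g} m/s "
        f"vs tol {tol:.3g})", residual=vmax)


def auto_alpha(mesh: HexMesh, materials: dict):
    """Near-critical mass-proportional damping estimate for dynamic
    relaxation: alpha ~ 2 * omega_1 with omega_1 from the softest shear
    wave speed and the largest mesh extent."""
    mu_min = np.inf
    rho_of = 1000.0
    for lab in np.unique(mesh.element_label):
        E, nu, rho = materials[int(lab)]
        mu, _ = lame_from_youngs(E, nu)
        if mu < mu_min:
            mu_min, rho_of = mu, rho
    c_s = np.sqrt(mu_min / rho_of)
    L = float(np.max(mesh.nodes.max(axis=0) - mesh.nodes.min(axis=0)))
    omega1 = np.pi * c_s / (2.0 * L)
    return 2.0 * omega1
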