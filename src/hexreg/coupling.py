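"""Penalty-based tissue-tissue coupling across split boundary vertices.

Every mesh node shared by a parenchyma element and a lesion (tumor or
vessel) element is split into a parenchyma-side copy bp_i and a lesion-side
copy bq_i at the same rest position.  Split vertices carry no mass and are
never integrated: each side's position is reconstructed by MLS from its own
tissue's non-boundary nodes (its *support domain*),

    bp_i = Phi_p,i . P_i,      bq_i = Phi_q,i . Q_i.

The two copies are tied by a penalty spring acting on the gap
delta = bp - bq,

    f_i = -k_c delta,       k_c in N/m,

with separate coefficients for parenchyma-tumor and parenchyma-vessel
interfaces.  The spring force is transmitted to the support-domain nodes
through the transposed shape functions: the parenchyma side receives
f_i * Phi_p,i (a restoring pull back toward the lesion) and the lesion side
-f_i * Phi_q,i, so the total coupling force vanishes identically.  Any
element-internal force assembled at a split vertex is redistributed to its
masters the same way (master-slave condensation).

At a converged state the pair gap and force satisfy the penalty relaxation
of the Signorini complementarity condition; `verify_signorini` reports the
residuals instead of enforcing the exact law, which a penalty formulation
can only approach.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ValidationError
from .io import PARENCHYMA, TUMOR, VESSEL
from .mesh import HexMesh
from .mls import build_support_domain, compute_shape_functions


@dataclass
class CouplingParams:
    k_tumor: float = 600.0    # k_c for parenchyma-tumor pairs, N/m
    k_vessel: float = 500.0   # k_c for parenchyma-vessel pairs, N/m

    def __post_init__(self):
        if self.k_tumor <= 0 or self.k_vessel <= 0:
            raise ValidationError("coupling coefficients must be > 0")

    def per_kind(self, kinds):
        return np.where(np.asarray(kinds) == TUMOR, self.k_tumor, self.k_vessel)


@dataclass
class BoundaryPair:
    node: int                 # original mesh node id = parenchyma-side bp row
    dup: int                  # duplicated node id = lesion-side bq row
    kind: int                 # TUMOR or VESSEL
    rest: np.ndarray          # (3,) shared rest position


@dataclass
class CouplingInterface:
    pairs: list               # of BoundaryPair
    n_base_nodes: int
    n_nodes: int              # base + duplicated
    elements: np.ndarray      # (E, 8) with lesion corners re-indexed to dups
    nodes: np.ndarray         # (n_nodes, 3) rest positions incl. duplicates
    W_p: sp.csr_matrix        # (nb, n_nodes) parenchyma-side MLS weights
    W_q: sp.csr_matrix        # (nb, n_nodes) lesion-side MLS weights
    bp_rows: np.ndarray       # (nb,) original node ids
    bq_rows: np.ndarray       # (nb,) duplicate node ids
    kinds: np.ndarray         # (nb,)
    W_p_T: sp.csr_matrix = None   # cached transposes (hot path)
    W_q_T: sp.csr_matrix = None

    def __post_init__(self):
        if self.W_p_T is None:
            self.W_p_T = self.W_p.T.tocsr()
        if self.W_q_T is None:
            self.W_q_T = self.W_q.T.tocsr()

    @property
    def n_pairs(self):
        return len(self.pairs)

    @property
    def slave_rows(self):
        return np.concatenate([self.bp_rows, self.bq_rows])

    def update_slaves(self, u):
        """Overwrite split-vertex displacement rows from their masters."""
        u[self.bp_rows] = self.W_p @ u
        u[self.bq_rows] = self.W_q @ u
        return u

    def condense(self, f):
        """Redistribute net forces at split vertices onto their masters and
        zero the slave rows (transposed shape-function pattern)."""
        fp = f[self.bp_rows]
        fq = f[self.bq_rows]
        f[self.bp_rows] = 0.0
        f[self.bq_rows] = 0.0
        return f + self.W_p_T @ fp + self.W_q_T @ fq


@dataclass
class InterfaceState:
    bp: np.ndarray            # (nb, 3) parenchyma-side positions, m
    bq: np.ndarray            # (nb, 3) lesion-side positions, m
    delta: np.ndarray         # (nb, 3) gap bp - bq, m
    forces: np.ndarray = None  # (nb, 3) f = -k_c delta, N


def _node_label_touch(mesh: HexMesh):
    """Boolean (N, 4) table: node touches an element of label L."""
    touch = np.zeros((mesh.n_nodes, 4), dtype=bool)
    for lab in (PARENCHYMA, VESSEL, TUMOR):
        sel = mesh.elements[mesh.element_label == lab]
        touch[np.unique(sel), lab] = True
    return touch


def _side_shape_functions(rest, nodes, masters, radius, cfg, vertex, side):
    """Same-tissue MLS shape functions for one side of a split vertex.

    The radius grows past the minimum-count fallback when the captured
    nodes are degenerate (e.g. coplanar interior vessel nodes), until the
    moment matrix is well conditioned."""
    from .errors import SingularMomentMatrixError
    r = radius
    last = None
    for _ in range(cfg["max_growth"] + 1):
        try:
            dom = build_support_domain(
                rest, nodes[masters], r, min_nodes=cfg["requested_nodes"],
                candidate_indices=masters, growth=cfg["growth"],
                max_growth=cfg["max_growth"])
            return compute_shape_functions(dom, kernel=cfg["kernel"])
        except SingularMomentMatrixError as exc:
            last = exc
            r *= cfg["growth"]
        except ValidationError as exc:
            raise ValidationError(
                f"boundary vertex {vertex} ({side} side): {exc}") from exc
    raise ValidationError(
        f"boundary vertex {vertex} ({side} side): {last}")


def build_interface(mesh: HexMesh, mls_cfg=None,
                    build_supports=True) -> CouplingInterface:
    """Split every parenchyma/lesion shared vertex and build per-side MLS
    support domains over same-tissue non-boundary nodes.

    Returns an empty interface (no pairs, unchanged connectivity) for a
    homogeneous mesh.  ``build_supports=False`` enumerates the split pairs
    and re-indexed connectivity only (topology inspection; such an
    interface cannot drive a simulation).  A lesion so small that it has
    no well-posed interior support (e.g. a single-element lesion, whose
    vertices are all shared) raises an error naming the vertex.
    """
    cfg = {"radius_factor": 1.5, "min_nodes": 4, "requested_nodes": 8,
           "growth": 1.3, "max_growth": 5, "kernel": "cubic_spline"}
    if mls_cfg:
        cfg.update(mls_cfg)
    touch = _node_label_touch(mesh)
    lesion_touch = touch[:, VESSEL] | touch[:, TUMOR]
    boundary = touch[:, PARENCHYMA] & lesion_touch
    b_nodes = np.flatnonzero(boundary)
    n = mesh.n_nodes
    if len(b_nodes) == 0:
        return CouplingInterface(
            pairs=[], n_base_nodes=n, n_nodes=n, elements=mesh.elements.copy(),
            nodes=mesh.nodes.copy(),
            W_p=sp.csr_matrix((0, n)), W_q=sp.csr_matrix((0, n)),
            bp_rows=np.zeros(0, np.int64), bq_rows=np.zeros(0, np.int64),
            kinds=np.zeros(0, np.int64))

    # master candidates per side: same tissue, not split
    par_masters = np.flatnonzero(touch[:, PARENCHYMA] & ~boundary)
    lesion_masters = np.flatnonzero(lesion_touch & ~touch[:, PARENCHYMA])
    radius = cfg["radius_factor"] * float(np.max(mesh.spacing))

    dup_ids = np.arange(n, n + len(b_nodes))
    nodes_ext = np.vstack([mesh.nodes, mesh.nodes[b_nodes]])
    n_ext = len(nodes_ext)

    # re-index lesion-element corners at boundary nodes onto the duplicates
    dup_of = np.full(n, -1, np.int64)
    dup_of[b_nodes] = dup_ids
    elements = mesh.elements.copy()
    lesion_el = np.isin(mesh.element_label, (VESSEL, TUMOR))
    sub = elements[lesion_el]
    remap = dup_of[sub]
    elements[lesion_el] = np.where(remap >= 0, remap, sub)

    pairs = []
    rows, cols, vals = [], [], []
    rows_q, cols_q, vals_q = [], [], []
    for row, (b, d) in enumerate(zip(b_nodes, dup_ids)):
        kind = TUMOR if touch[b, TUMOR] else VESSEL
        rest = mesh.nodes[b]
        for side, masters, (rr, cc, vv) in (
                ("parenchyma", par_masters, (rows, cols, vals)),
                ("lesion", lesion_masters, (rows_q, cols_q, vals_q))):
            if not build_supports:
                continue
            shp = _side_shape_functions(rest, mesh.nodes, masters, radius,
                                        cfg, b, side)
            rr.extend([row] * len(shp.indices))
            cc.extend(int(i) for i in shp.indices)
            vv.extend(shp.weights)
        pairs.append(BoundaryPair(node=int(b), dup=int(d), kind=kind,
                                  rest=rest.copy()))
    nb = len(pairs)
    W_p = sp.csr_matrix((vals, (rows, cols)), shape=(nb, n_ext))
    W_q = sp.csr_matrix((vals_q, (rows_q, cols_q)), shape=(nb, n_ext))
    return CouplingInterface(
        pairs=pairs, n_base_nodes=n, n_nodes=n_ext, elements=elements,
        nodes=nodes_ext, W_p=W_p, W_q=W_q,
        bp_rows=b_nodes.astype(np.int64), bq_rows=dup_ids,
        kinds=np.array([p.kind for p in pairs], np.int64))


def reconstruct_boundary_positions(interface: CouplingInterface, u
                                   ) -> InterfaceState:
    """MLS reconstruction of both sides of every split vertex from the
    current displacement field (positions, not displacements)."""
    rest = np.array([p.rest for p in interface.pairs]).reshape(-1, 3)
    bp = rest + interface.W_p @ u
    bq = rest + interface.W_q @ u
    return InterfaceState(bp=bp, bq=bq, delta=bp - bq)


def compute_coupling_forces(iface_state: InterfaceState,
                            params: CouplingParams, kinds) -> np.ndarray:
    """Per-pair penalty forces f = -k_c * delta (N); also stored on the
    state."""
    k = np.asarray(params.per_kind(kinds), float)
    iface_state.forces = -k[:, None] * iface_state.delta
    return iface_state.forces


def distribute_forces(interface: CouplingInterface, pair_forces) -> np.ndarray:
    """Spread pair forces onto support-domain nodes via the transposed
    shape functions: parenchyma side receives +f (restoring), lesion side
    -f.  Net force is exactly zero by partition of unity."""
    f = np.asarray(pair_forces, float).reshape(-1, 3)
    return interface.W_p_T @ f - interface.W_q_T @ f


def verify_signorini(iface_state: InterfaceState, params: CouplingParams,
                     kinds, tol=None, gap_max=None) -> pd.DataFrame:
    """Report per-pair complementarity residuals |f . delta| and gap
    magnitudes against the penalty bounds; report-only, never enforcing."""
    delta = iface_state.delta
    if iface_state.forces is None:
        compute_coupling_forces(iface_state, params, kinds)
    f = iface_state.forces
    gap = np.linalg.norm(delta, axis=1)
    fmag = np.linalg.norm(f, axis=1)
    resid = np.abs(np.sum(f * delta, axis=1))
    df = pd.DataFrame({
        "pair": np.arange(len(gap)),
        "kind": ["tumor" if k == TUMOR else "vessel" for k in kinds],
        "gap_m": gap,
        "force_N": fmag,
        "complementarity_Nm": resid,
    })
    df["pass"] = True
    if tol is not None:
        df["pass"] &= df["complementarity_Nm"] <= tol
    if gap_max is not None:
        df["pass"] &= df["gap_m"] <= gap_max
    return df
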