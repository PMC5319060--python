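"""Coarse-to-fine detail enrichment.

The expensive high-resolution heterogeneous model is run offline over a
grid of compression conditions.  For every condition the deformed fine
vertices are expressed through per-coarse-element MLS shape sets over the
8 deformed vertices of their coarse element,

    Phi_j,t = (phi_j,1, ..., phi_j,8)^(t),    x_j = Phi_j,t^T P_i,

and the sets are stored in a condition-indexed database.  At runtime only
the cheap low-resolution model is solved; the nearest stored condition's
shape sets then synthesize the high-resolution microstructure from the
deformed coarse vertices.

The element-level fit uses the interpolating (singular-kernel) MLS variant
so fine vertices coincident with coarse vertices follow them exactly; the
fit is evaluated at the fine vertex's deformed position with the deformed
coarse vertices as nodes, so linear reproduction makes every record
self-consistent at fit time to machine precision.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import h5py
import numpy as np

from .errors import HexregError, ValidationError
from .mesh import HexMesh, interpolate_embedded
from .mls import mls_weights
from .model import HeterogeneousModel, Scenario

log = logging.getLogger(__name__)


@dataclass
class EnrichmentRecord:
    condition: Scenario
    assignment: np.ndarray      # (nf,) coarse element id per fine vertex
    weights: np.ndarray         # (nf, 8) float32 shape sets Phi_j,t
    coarse_u: np.ndarray        # (Nc, 3) coarse equilibrium displacements
    fine_positions: np.ndarray  # (nf, 3) fine equilibrium positions (audit)


@dataclass
class EnrichmentDatabase:
    records: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)  # mesh hashes, config hash, seed

    def __len__(self):
        return len(self.records)

    def save(self, path):
        with h5py.File(path, "w") as fh:
            g = fh.create_group("meta")
            for k, v in self.meta.items():
                g.attrs[k] = v
            recs = fh.create_group("records")
            for i, r in enumerate(self.records):
                gr = recs.create_group(str(i))
                gr.attrs["condition"] = json.dumps(r.condition.to_dict())
                gr.create_dataset("assignment", data=r.assignment)
                gr.create_dataset("weights", data=r.weights.astype(np.float32))
                gr.create_dataset("coarse_u", data=r.coarse_u)
                gr.create_dataset("fine_positions", data=r.fine_positions)

    @classmethod
    def load(cls, path):
        db = cls()
        with h5py.File(path, "r") as fh:
            db.meta = dict(fh["meta"].attrs)
            recs = fh["records"]
            for key in sorted(recs, key=int):
                gr = recs[key]
                db.records.append(EnrichmentRecord(
                    condition=Scenario.from_dict(
                        json.loads(gr.attrs["condition"])),
                    assignment=gr["assignment"][()],
                    weights=gr["weights"][()].astype(float),
                    coarse_u=gr["coarse_u"][()],
                    fine_positions=gr["fine_positions"][()],
                ))
        return db


def fit_element_shapefuns(fine_vertex, element_vertices):
    """Phi_j,t over one coarse element's 8 (deformed) vertices.

    Interpolating MLS with a linear basis; the support radius spans the
    whole element so every vertex contributes.  Raises for collapsed
    elements (degenerate vertex sets).
    """
    pts = np.asarray(element_vertices, float).reshape(8, 3)
    q = np.asarray(fine_vertex, float)
    radius = 2.0 * max(float(np.max(np.linalg.norm(pts - q, axis=1))), 1e-12)
    return mls_weights(q, pts, radius, kernel="singular")


def assign_fine_vertices(fine_nodes, coarse: HexMesh, tol=1e-9):
    """Containing coarse element per fine vertex (rest configuration).

    Vertices on shared faces take the lowest containing element id; a
    vertex outside every coarse box (possible at jagged boundaries where
    the coarse block is occupied elsewhere) takes the nearest element by
    center distance."""
    lookup = {tuple(c): e for e, c in enumerate(coarse.cells)}
    centers = coarse.origin + (coarse.cells + 0.5) * coarse.spacing
    out = np.empty(len(fine_nodes), np.int64)
    for i, p in enumerate(np.asarray(fine_nodes, float)):
        rel = (p - coarse.origin) / coarse.spacing
        base = np.floor(rel - tol).astype(int)
        cands = []
        for di in (0, 1):
            for dj in (0, 1):
                for dk in (0, 1):
                    c = (base[0] + di, base[1] + dj, base[2] + dk)
                    e = lookup.get(c)
                    if e is None:
                        continue
                    lo = coarse.origin + np.asarray(c) * coarse.spacing
                    hi = lo + coarse.spacing
                    if np.all(p >= lo - tol) and np.all(p <= hi + tol):
                        cands.append(e)
        if cands:
            out[i] = min(cands)
        else:
            out[i] = int(np.argmin(np.linalg.norm(centers - p, axis=1)))
    return out


def build_enrichment_database(high_model: HeterogeneousModel,
                              low_model: HeterogeneousModel,
                              conditions, params=None, meta=None
                              ) -> EnrichmentDatabase:
    """Run both models to equilibrium per condition and store the fitted
    per-fine-vertex shape sets.  Failed conditions are skipped with a
    logged reason; an entirely failed build raises."""
    conditions = list(conditions)
    if not conditions:
        raise ValidationError("no compression conditions given")
    coarse = low_model.mesh
    if high_model.interface is not None and high_model.interface.n_pairs:
        fine_rest = high_model.interface.nodes
    else:
        fine_rest = high_model.mesh.nodes
    assignment = assign_fine_vertices(fine_rest, coarse)
    db = EnrichmentDatabase(meta=dict(meta or {}))
    db.meta.setdefault("fine_mesh_hash", high_model.mesh.hash())
    db.meta.setdefault("coarse_mesh_hash", coarse.hash())
    for cond in conditions:
        try:
            hi_state = high_model.solve(cond, params=params)
            lo_state = low_model.solve(cond)
        except HexregError as exc:
            log.warning("condition %s skipped: %s", cond.to_dict(), exc)
            continue
        fine_pos = fine_rest + hi_state.u
        coarse_pos = coarse.nodes + lo_state.u
        elem_pos = coarse_pos[coarse.elements]          # (Ec, 8, 3)
        weights = np.empty((len(fine_pos), 8))
        for j, (p, e) in enumerate(zip(fine_pos, assignment)):
            weights[j] = fit_element_shapefuns(p, elem_pos[e])
        db.records.append(EnrichmentRecord(
            condition=cond, assignment=assignment.copy(),
            weights=weights.astype(np.float32), coarse_u=lo_state.u.copy(),
            fine_positions=fine_pos))
    if not db.records:
        raise ValidationError("all enrichment conditions failed")
    return db


def condition_distance(a: Scenario, b: Scenario, w_position=100.0,
                       w_angle=1.0, w_magnitude=100.0):
    """Weighted condition metric: patch-centroid distance (m), angle
    between directions (rad), and magnitude difference (m)."""
    dp = float(np.linalg.norm(a.patch_center - b.patch_center))
    cosang = float(np.clip(np.dot(a.direction, b.direction), -1.0, 1.0))
    ang = float(np.arccos(cosang))
    dm = abs(a.magnitude - b.magnitude)
    return w_position * dp + w_angle * ang + w_magnitude * dm


def lookup_condition(db: EnrichmentDatabase, query: Scenario,
                     weights=None) -> EnrichmentRecord:
    """Record with the smallest condition distance; ties broken by smaller
    magnitude difference, then lowest record id."""
    if not db.records:
        raise ValidationError("empty enrichment database")
    w = {"w_position": 100.0, "w_angle": 1.0, "w_magnitude": 100.0}
    if weights:
        w.update(weights)
    keys = []
    for i, rec in enumerate(db.records):
        d = condition_distance(query, rec.condition, **w)
        keys.append((d, abs(query.magnitude - rec.condition.magnitude), i))
    keys.sort()
    return db.records[keys[0][2]]


def synthesize_fine(record: EnrichmentRecord, coarse: HexMesh, coarse_u
                    ) -> np.ndarray:
    """High-resolution vertex positions x_j = Phi_j,t^T P_i from the
    current deformed coarse element vertices."""
    coarse_pos = coarse.nodes + np.asarray(coarse_u, float)
    elem_pos = coarse_pos[coarse.elements]              # (Ec, 8, 3)
    P = elem_pos[record.assignment]                     # (nf, 8, 3)
    return np.einsum("ja,jai->ji", record.weights.astype(float), P)


def register_coarse_to_fine(low_model: HeterogeneousModel,
                            db: EnrichmentDatabase, scenario: Scenario,
                            landmarks, embedded, fine_mesh: HexMesh,
                            fine_elements=None, lookup_weights=None):
    """Fast registration: low-resolution equilibrium -> nearest stored
    condition -> microstructure synthesis -> landmark interpolation.

    Returns (fine vertex positions, predicted LandmarkSet, record used).
    """
    lo_state = low_model.solve(scenario)
    record = lookup_condition(db, scenario, weights=lookup_weights)
    fine_pos = synthesize_fine(record, low_model.mesh, lo_state.u)
    pred = interpolate_embedded(fine_mesh, embedded, fine_pos,
                                elements=fine_elements)
    from .io import LandmarkSet
    pred_set = LandmarkSet(ids=list(landmarks.ids), positions=pred,
                           categories=list(landmarks.categories))
    return fine_pos, pred_set, record
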