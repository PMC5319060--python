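"""Uniform hexahedral meshes built directly from labeled voxels.

Every foreground voxel becomes one 8-node axis-aligned hexahedral element
(VTK ordering); nodes on the shared voxel-corner grid are deduplicated, so
face-adjacent elements share exactly four nodes and the mesh is watertight.
Each element carries exactly one tissue label.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .errors import MeshError, ValidationError
from .io import BACKGROUND, PARENCHYMA, TUMOR, VESSEL, LabeledVolume

# VTK hexahedron corner offsets: bottom face CCW, then top face CCW.
VTK_OFFSETS = np.array([
    (0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
    (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1),
], dtype=np.int64)

# Natural (xi, eta, zeta) corner signs matching VTK_OFFSETS.
NATURAL_SIGNS = 2.0 * VTK_OFFSETS - 1.0

# Majority-vote tie-break priority: lesions beat parenchyma, tumor beats
# vessel, so coarsening never erases the heterogeneity it should preserve.
_TIE_PRIORITY = (TUMOR, VESSEL, PARENCHYMA)


@dataclass
class HexMesh:
    nodes: np.ndarray           # (N, 3) world coords, m
    elements: np.ndarray        # (E, 8) node indices, VTK ordering
    element_label: np.ndarray   # (E,) tissue label
    resolution: tuple           # cells per axis of the generating grid
    spacing: np.ndarray         # (3,) cell edge lengths, m
    origin: np.ndarray = None
    cells: np.ndarray = None    # (E, 3) integer cell coords on the grid

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, float)
        self.elements = np.asarray(self.elements, np.int64)
        self.element_label = np.asarray(self.element_label, np.int64)
        self.spacing = np.asarray(self.spacing, float)
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, float)

    @property
    def n_nodes(self):
        return len(self.nodes)

    @property
    def n_elements(self):
        return len(self.elements)

    @property
    def cell_volume(self):
        return float(np.prod(self.spacing))

    def hash(self) -> str:
        h = hashlib.sha256()
        for arr in (self.nodes, self.elements, self.element_label):
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()[:16]

    def boundary_faces(self):
        """(face_nodes (F,4), owning element (F,), outward axis code (F,)).

        Axis code is 0..5 for -x,+x,-y,+y,-z,+z.  A face is on the boundary
        iff exactly one element owns it.
        """
        # local corner ids of each of the 6 faces, consistent with VTK order
        local = np.array([
            (0, 3, 7, 4),  # -x
            (1, 2, 6, 5),  # +x
            (0, 1, 5, 4),  # -y
            (3, 2, 6, 7),  # +y
            (0, 1, 2, 3),  # -z
            (4, 5, 6, 7),  # +z
        ])
        faces = self.elements[:, local]             # (E, 6, 4)
        flat = faces.reshape(-1, 4)
        key = np.sort(flat, axis=1)
        _, inverse, counts = np.unique(key, axis=0, return_inverse=True,
                                       return_counts=True)
        on_boundary = counts[inverse] == 1
        owners = np.repeat(np.arange(self.n_elements), 6)
        axis_code = np.tile(np.arange(6), self.n_elements)
        return flat[on_boundary], owners[on_boundary], axis_code[on_boundary]


@dataclass
class VertexCorrespondence:
    """Coincident-node map from coarse-mesh node index to fine-mesh node
    index (rest-coordinate distance exactly zero)."""

    coarse_to_fine: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.coarse_to_fine)


@dataclass
class EmbeddedLandmark:
    landmark_id: str
    element: int
    natural: np.ndarray  # (xi, eta, zeta) in [-1, 1]^3

    def trilinear_weights(self):
        xi = np.asarray(self.natural, float)
        return np.prod(1.0 + NATURAL_SIGNS * xi, axis=1) / 8.0


def build_hex_mesh(volume: LabeledVolume, target_resolution=None) -> HexMesh:
    """One element per foreground voxel, nodes deduplicated on the corner
    grid.  If ``target_resolution`` differs from the volume grid the volume
    is first downsampled by per-block majority vote."""
    vol = volume
    if target_resolution is not None and tuple(target_resolution) != vol.dims:
        vol = downsample_volume(vol, target_resolution)
    labels = vol.labels
    nx, ny, nz = vol.dims
    fg = np.argwhere(labels > 0)
    if len(fg) == 0:
        raise MeshError("volume has no foreground voxels")
    # node grid is (nx+1, ny+1, nz+1); flat index encodes (i, j, k)
    strides = np.array([(ny + 1) * (nz + 1), nz + 1, 1], dtype=np.int64)
    corner = fg[:, None, :] + VTK_OFFSETS[None, :, :]      # (E, 8, 3)
    flat = corner @ strides                                 # (E, 8)
    uniq, inverse = np.unique(flat, return_inverse=True)
    elements = inverse.reshape(flat.shape)
    grid_idx = np.stack(np.unravel_index(uniq, (nx + 1, ny + 1, nz + 1)), axis=1)
    nodes = vol.origin + grid_idx * vol.spacing
    return HexMesh(
        nodes=nodes,
        elements=elements,
        element_label=labels[fg[:, 0], fg[:, 1], fg[:, 2]],
        resolution=vol.dims,
        spacing=vol.spacing.copy(),
        origin=vol.origin.copy(),
        cells=fg.astype(np.int64),
    )


def _majority_label(block_labels):
    """Majority foreground label of a flat label array; ties prefer the
    lesion (tumor > vessel > parenchyma).  Returns 0 if all background."""
    fg = block_labels[block_labels > 0]
    if fg.size == 0:
        return 0
    counts = np.bincount(fg, minlength=4)
    best = counts.max()
    for label in _TIE_PRIORITY:
        if counts[label] == best:
            return label
    return 0  # unreachable


def _block_shape(fine_dims, coarse_dims, what):
    fine_dims = np.asarray(fine_dims, int)
    coarse_dims = np.asarray(coarse_dims, int)
    if np.any(coarse_dims < 1):
        raise MeshError(f"{what}: resolution must be >= 1 per axis")
    if np.any(coarse_dims > fine_dims):
        raise MeshError(
            f"{what}: target resolution {tuple(coarse_dims)} exceeds grid "
            f"{tuple(fine_dims)}")
    if np.any(fine_dims % coarse_dims):
        raise MeshError(
            f"{what}: {tuple(coarse_dims)} must divide the grid "
            f"{tuple(fine_dims)} exactly per axis")
    return fine_dims // coarse_dims


def downsample_volume(volume: LabeledVolume, target_resolution) -> LabeledVolume:
    """Majority-vote downsampling of a labeled volume onto an aligned
    coarser grid (same rule as mesh coarsening)."""
    block = _block_shape(volume.dims, target_resolution, "downsample_volume")
    nx, ny, nz = np.asarray(target_resolution, int)
    out = np.zeros((nx, ny, nz), dtype=volume.labels.dtype)
    lab = volume.labels
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                blk = lab[i * block[0]:(i + 1) * block[0],
                          j * block[1]:(j + 1) * block[1],
                          k * block[2]:(k + 1) * block[2]]
                out[i, j, k] = _majority_label(blk.ravel())
    return LabeledVolume(labels=out, spacing=volume.spacing * block,
                         origin=volume.origin.copy())


def coarsen_mesh(fine: HexMesh, coarse_resolution):
    """Numerically coarsen ``fine`` onto an aligned lower-resolution grid.

    A coarse element exists iff its block contains at least one foreground
    fine cell; its label is the majority foreground label of the block
    (lesion-priority tie-break).  Every coarse node that coincides with a
    fine node enters the returned :class:`VertexCorrespondence`.
    """
    if fine.cells is None:
        raise MeshError("fine mesh lacks cell coordinates; build it from a volume")
    block = _block_shape(fine.resolution, coarse_resolution, "coarsen_mesh")
    # reconstruct the fine label grid from the element list
    grid = np.zeros(fine.resolution, dtype=np.int64)
    grid[fine.cells[:, 0], fine.cells[:, 1], fine.cells[:, 2]] = fine.element_label
    coarse_vol = downsample_volume(
        LabeledVolume(labels=grid, spacing=fine.spacing, origin=fine.origin),
        coarse_resolution)
    coarse = build_hex_mesh(coarse_vol)

    # coincident-node correspondence: coarse grid node (I,J,K) sits at fine
    # grid node (I*bx, J*by, K*bz)
    fine_dims = np.asarray(fine.resolution, int)
    fine_strides = np.array([(fine_dims[1] + 1) * (fine_dims[2] + 1),
                             fine_dims[2] + 1, 1], dtype=np.int64)
    fine_grid_idx = np.rint((fine.nodes - fine.origin) / fine.spacing).astype(np.int64)
    fine_flat = fine_grid_idx @ fine_strides
    fine_lookup = {int(f): i for i, f in enumerate(fine_flat)}
    coarse_grid_idx = np.rint((coarse.nodes - coarse.origin) / coarse.spacing
                              ).astype(np.int64)
    corr = VertexCorrespondence()
    for ci, gidx in enumerate(coarse_grid_idx):
        flat = int((gidx * block) @ fine_strides)
        fi = fine_lookup.get(flat)
        if fi is not None:
            corr.coarse_to_fine[ci] = fi
    return coarse, corr


def locate_point(mesh: HexMesh, point, tol=1e-9):
    """(element index, natural coords) of the element whose rest box
    contains ``point``; raises MeshError if outside all elements."""
    if mesh.cells is None:
        raise MeshError("mesh lacks cell coordinates")
    p = np.asarray(point, float)
    rel = (p - mesh.origin) / mesh.spacing
    base = np.floor(rel).astype(int)
    # cell lookup map built lazily and cached on the mesh object
    lookup = getattr(mesh, "_cell_lookup", None)
    if lookup is None:
        lookup = {tuple(c): e for e, c in enumerate(mesh.cells)}
        mesh._cell_lookup = lookup
    candidates = [tuple(base)]
    for a in range(3):
        for d in (-1, 1):
            c = base.copy()
            c[a] += d
            candidates.append(tuple(c))
    best = None
    for cand in candidates:
        e = lookup.get(cand)
        if e is None:
            continue
        lo = mesh.origin + np.asarray(cand) * mesh.spacing
        hi = lo + mesh.spacing
        if np.all(p >= lo - tol) and np.all(p <= hi + tol):
            xi = np.clip(2.0 * (p - lo) / mesh.spacing - 1.0, -1.0, 1.0)
            if best is None:
                best = (e, xi)
    if best is None:
        raise MeshError(f"point {p} lies outside all elements")
    return best


def embed_landmarks(mesh: HexMesh, landmarks) -> list:
    """Locate each landmark in its containing element and record trilinear
    natural coordinates; reconstruction reproduces the position to 1e-10 m."""
    out = []
    for lid, pos in zip(landmarks.ids, landmarks.positions):
        try:
            element, xi = locate_point(mesh, pos)
        except MeshError as exc:
            raise MeshError(f"landmark {lid!r}: {exc}") from exc
        out.append(EmbeddedLandmark(landmark_id=lid, element=int(element),
                                    natural=np.asarray(xi, float)))
    return out


def interpolate_embedded(mesh: HexMesh, embedded, node_positions, elements=None):
    """World positions of embedded landmarks given current node positions
    (rest + displacement), via trilinear interpolation; shape (L, 3).

    ``elements`` overrides the connectivity (used when interface splitting
    re-indexes lesion-element corners onto duplicated nodes)."""
    node_positions = np.asarray(node_positions, float)
    if elements is None:
        elements = mesh.elements
    out = np.empty((len(embedded), 3))
    for i, emb in enumerate(embedded):
        w = emb.trilinear_weights()
        out[i] = w @ node_positions[elements[emb.element]]
    return out
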