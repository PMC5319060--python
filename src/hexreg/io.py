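"""Labeled-volume, landmark, mesh and config I/O.

Internal units are SI (meters); files carry millimeters, the convention of
the medical-imaging formats this package reads.  All conversions happen at
the file boundary, never inside the solvers.

Label convention for segmentations: 0 = background, 1 = parenchyma,
2 = vessel, 3 = tumor.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

MM = 1e-3  # file unit (mm) -> internal unit (m)

BACKGROUND, PARENCHYMA, VESSEL, TUMOR = 0, 1, 2, 3
VALID_LABELS = (BACKGROUND, PARENCHYMA, VESSEL, TUMOR)
LABEL_NAMES = {PARENCHYMA: "parenchyma", VESSEL: "vessel", TUMOR: "tumor"}

CATEGORIES = ("surface", "internal-tumor", "internal-vessel")


# ---------------------------------------------------------------------------
# Labeled volumes
# ---------------------------------------------------------------------------

@dataclass
class LabeledVolume:
    """A segmentation on a uniform voxel grid.

    ``labels`` is indexed ``[i, j, k]`` with x fastest-varying in memory
    order irrelevant; axis 0 is x, axis 1 is y, axis 2 is z.  Voxel
    ``(i, j, k)`` occupies the half-open box
    ``[origin + i*spacing, origin + (i+1)*spacing)`` per axis (0-based,
    corner convention).
    """

    labels: np.ndarray          # (nx, ny, nz) integer
    spacing: np.ndarray         # (3,) meters per voxel
    origin: np.ndarray = None   # (3,) world position of voxel (0,0,0) corner, m

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=float)
        self.validate()

    @property
    def dims(self):
        return tuple(int(d) for d in self.labels.shape)

    def validate(self):
        if self.labels.ndim != 3:
            raise ValidationError("labels must be a 3-D grid")
        if any(d < 1 for d in self.labels.shape):
            raise ValidationError("dims must be >= 1 per axis")
        if not np.all(self.spacing > 0):
            raise ValidationError(f"spacing must be strictly positive, got {self.spacing}")
        bad = ~np.isin(self.labels, VALID_LABELS)
        if bad.any():
            idx = tuple(int(v) for v in np.argwhere(bad)[0])
            raise ValidationError(
                f"unknown label {int(self.labels[idx])} at voxel {idx}"
            )

    def label_counts(self):
        """Voxel count per label value, as a plain dict."""
        vals, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}

    def voxel_centers(self):
        """World coordinates (m) of all voxel centers, shape (nx, ny, nz, 3)."""
        axes = [self.origin[a] + (np.arange(self.dims[a]) + 0.5) * self.spacing[a]
                for a in range(3)]
        xx, yy, zz = np.meshgrid(*axes, indexing="ij")
        return np.stack([xx, yy, zz], axis=-1)


def read_labeled_volume(path, spacing_override=None) -> LabeledVolume:
    """Read a segmentation from NIfTI (.nii/.nii.gz), NRRD (.nrrd) or the
    raw+JSON test dialect (.json header next to a .raw grid).

    File spacings/origins are in mm and converted to meters.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    low = path.lower()
    if low.endswith((".nii", ".nii.gz")):
        labels, spacing_mm, origin_mm = _read_nifti(path)
    elif low.endswith(".nrrd"):
        labels, spacing_mm, origin_mm = _read_nrrd(path)
    elif low.endswith(".json"):
        labels, spacing_mm, origin_mm = _read_rawjson(path)
    else:
        raise FormatError(f"unsupported volume format: {path}")
    if spacing_mm is None:
        if spacing_override is None:
            raise FormatError(f"{path}: no spacing in header and no override given")
        spacing_mm = np.asarray(spacing_override, float)
    return LabeledVolume(labels=labels.astype(np.int16),
                         spacing=np.asarray(spacing_mm) * MM,
                         origin=np.asarray(origin_mm) * MM)


def write_labeled_volume(vol: LabeledVolume, path):
    """Write a volume in the format implied by the extension (mm units)."""
    path = os.fspath(path)
    low = path.lower()
    if low.endswith((".nii", ".nii.gz")):
        _write_nifti(vol, path)
    elif low.endswith(".nrrd"):
        _write_nrrd(vol, path)
    elif low.endswith(".json"):
        _write_rawjson(vol, path)
    else:
        raise FormatError(f"unsupported volume format: {path}")


def _read_nifti(path):
    import nibabel as nib
    img = nib.load(path)
    affine = img.affine
    rot = affine[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-9):
        raise FormatError(f"{path}: only axis-aligned NIfTI affines are supported")
    spacing = np.abs(np.diag(rot))
    if np.any(spacing <= 0):
        spacing = None
    origin = affine[:3, 3]
    data = np.asanyarray(img.dataobj)
    return np.asarray(data), spacing, origin


def _write_nifti(vol, path):
    import nibabel as nib
    affine = np.eye(4)
    affine[:3, :3] = np.diag(vol.spacing / MM)
    affine[:3, 3] = vol.origin / MM
    img = nib.Nifti1Image(vol.labels.astype(np.int16), affine)
    nib.save(img, path)


def _read_nrrd(path):
    import SimpleITK as sitk
    img = sitk.ReadImage(path)
    # SimpleITK arrays come back (z, y, x); transpose to (x, y, z)
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return data, np.asarray(img.GetSpacing()), np.asarray(img.GetOrigin())


def _write_nrrd(vol, path):
    import SimpleITK as sitk
    img = sitk.GetImageFromArray(vol.labels.astype(np.int16).transpose(2, 1, 0))
    img.SetSpacing(tuple(vol.spacing / MM))
    img.SetOrigin(tuple(vol.origin / MM))
    sitk.WriteImage(img, path)


def _read_rawjson(path):
    with open(path) as fh:
        hdr = json.load(fh)
    dims = tuple(hdr["dims"])
    raw_path = os.path.join(os.path.dirname(path), hdr["raw"])
    data = np.fromfile(raw_path, dtype=np.dtype(hdr.get("dtype", "uint8")))
    if data.size != int(np.prod(dims)):
        raise FormatError(f"{raw_path}: expected {int(np.prod(dims))} voxels, got {data.size}")
    labels = data.reshape(dims, order="F")  # x fastest
    spacing = np.asarray(hdr["spacing_mm"], float) if "spacing_mm" in hdr else None
    origin = np.asarray(hdr.get("origin_mm", (0.0, 0.0, 0.0)), float)
    return labels, spacing, origin


def _write_rawjson(vol, path):
    base = os.path.splitext(path)[0]
    raw_name = os.path.basename(base) + ".raw"
    vol.labels.astype(np.uint8).ravel(order="F").tofile(base + ".raw")
    hdr = {
        "dims": list(vol.dims),
        "spacing_mm": [float(s / MM) for s in vol.spacing],
        "origin_mm": [float(o / MM) for o in vol.origin],
        "dtype": "uint8",
        "raw": raw_name,
        "label_counts": vol.label_counts(),
    }
    with open(path, "w") as fh:
        json.dump(hdr, fh, indent=1)


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------

@dataclass
class LandmarkSet:
    """Named world-space points with a registration category."""

    ids: list                   # unique strings
    positions: np.ndarray       # (n, 3) meters
    categories: list            # entries of CATEGORIES

    def __post_init__(self):
        self.ids = [str(i) for i in self.ids]
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.categories = list(self.categories)
        if len(set(self.ids)) != len(self.ids):
            dup = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValidationError(f"duplicate landmark ids: {dup}")
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError("landmark positions must be finite")
        if len(self.ids) != len(self.positions) or len(self.ids) != len(self.categories):
            raise ValidationError("ids, positions and categories must have equal length")
        for c in self.categories:
            if c not in CATEGORIES:
                raise ValidationError(f"unknown landmark category {c!r}")

    def __len__(self):
        return len(self.ids)

    def subset(self, mask):
        mask = np.asarray(mask, bool)
        return LandmarkSet(
            ids=[i for i, m in zip(self.ids, mask) if m],
            positions=self.positions[mask],
            categories=[c for c, m in zip(self.categories, mask) if m],
        )

    def category_counts(self):
        out = {}
        for c in self.categories:
            out[c] = out.get(c, 0) + 1
        return out


def read_landmarks(path) -> LandmarkSet:
    """Read a landmark CSV (header ``id,x,y,z,category``; x/y/z in mm)."""
    try:
        df = pd.read_csv(path, dtype={"id": str})
    except Exception as exc:  # noqa: BLE001 - wrap parser errors uniformly
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    required = ["id", "x", "y", "z", "category"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    for col in ("x", "y", "z"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise FormatError(f"{path}: non-numeric {col!r} at line {line}")
        df[col] = coerced
    if df[["x", "y", "z"]].isna().any().any():
        line = int(df[["x", "y", "z"]].isna().any(axis=1).idxmax()) + 2
        raise FormatError(f"{path}: missing coordinate at line {line}")
    return LandmarkSet(
        ids=df["id"].tolist(),
        positions=df[["x", "y", "z"]].to_numpy(float) * MM,
        categories=df["category"].tolist(),
    )


def write_landmarks(lms: LandmarkSet, path):
    """Write landmarks as CSV in mm, with enough digits for a lossless
    round trip (< 1e-12 m)."""
    df = pd.DataFrame({
        "id": lms.ids,
        "x": lms.positions[:, 0] / MM,
        "y": lms.positions[:, 1] / MM,
        "z": lms.positions[:, 2] / MM,
        "category": lms.categories,
    })
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Mesh export (legacy ASCII VTK unstructured grid)
# ---------------------------------------------------------------------------

def export_mesh(mesh, path, state=None, point_data=None):
    """Write a hexahedral mesh as a legacy ASCII VTK unstructured grid.

    Coordinates are written in mm.  Cells carry the integer tissue label;
    if ``state`` is given its displacements are added to the rest positions
    and also exported as a per-point vector field.
    """
    nodes = np.asarray(mesh.nodes, float)
    elements = np.asarray(mesh.elements)
    if state is not None:
        disp = np.asarray(state.u, float)
        if disp.shape != nodes.shape:
            raise ValidationError(
                f"displacement count {disp.shape[0]} != node count {nodes.shape[0]}")
        points = nodes + disp
    else:
        disp = None
        points = nodes
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nhexreg mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(points)} double\n")
        for p in points / MM:
            fh.write(f"{p[0]:.12g} {p[1]:.12g} {p[2]:.12g}\n")
        fh.write(f"CELLS {len(elements)} {len(elements) * 9}\n")
        for el in elements:
            fh.write("8 " + " ".join(str(int(i)) for i in el) + "\n")
        fh.write(f"CELL_TYPES {len(elements)}\n")
        fh.write("\n".join(["12"] * len(elements)) + "\n")
        fh.write(f"CELL_DATA {len(elements)}\n")
        fh.write("SCALARS tissue_label int 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(str(int(l)) for l in mesh.element_label) + "\n")
        if disp is not None:
            fh.write(f"POINT_DATA {len(points)}\n")
            fh.write("VECTORS displacement double\n")
            for d in disp / MM:
                fh.write(f"{d[0]:.12g} {d[1]:.12g} {d[2]:.12g}\n")


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    # label -> [Young's modulus Pa, Poisson ratio, density kg/m^3]
    "materials": {
        "1": [2.0e5, 0.49, 1000.0],
        "2": [1.0e6, 0.49, 1000.0],
        "3": [5.0e6, 0.49, 1000.0],
    },
    "coupling": {"k_tumor": 600.0, "k_vessel": 500.0},  # N/m
    "solver": {
        "dt_safety": 0.8,
        "alpha": 5.0,            # mass-proportional damping, 1/s; "auto" allowed
        "tol": 1e-4,             # max nodal speed at equilibrium, m/s
        "max_steps": 200000,
        "ramp_steps": 300,
        "quadrature": "1pt",     # "1pt" (+ hourglass control) or "8pt"
        "hourglass": 0.1,
    },
    "mls": {
        "radius_factor": 1.5,    # support radius = factor * max spacing
        "min_nodes": 4,
        "requested_nodes": 8,
        "growth": 1.3,
        "max_growth": 5,
        "kernel": "cubic_spline",
    },
    "lookup": {"w_position": 100.0, "w_angle": 1.0, "w_magnitude": 100.0},
    "resolutions": {"fine": None, "coarse": None},
    "seed": 0,
}


@dataclass
class Config:
    """Flat-ish runtime configuration; see DEFAULT_CONFIG for keys/units."""

    data: dict = field(default_factory=lambda: json.loads(json.dumps(DEFAULT_CONFIG)))

    def __post_init__(self):
        merged = json.loads(json.dumps(DEFAULT_CONFIG))
        _deep_update(merged, self.data)
        self.data = merged
        self.validate()

    def validate(self):
        for label, (E, nu, rho) in self.materials().items():
            if E <= 0:
                raise ValidationError(f"E must be > 0 for label {label}")
            if not 0 <= nu < 0.5:
                raise ValidationError(f"Poisson ratio must be in [0, 0.5) for label {label}")
            if rho <= 0:
                raise ValidationError(f"density must be > 0 for label {label}")

    def materials(self):
        return {int(k): tuple(float(x) for x in v)
                for k, v in self.data["materials"].items()}

    def __getitem__(self, key):
        return self.data[key]

    @property
    def seed(self):
        return int(self.data["seed"])

    def hash(self) -> str:
        """Stable hash of the full configuration (for provenance)."""
        blob = json.dumps(self.data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def provenance(self) -> dict:
        return {"config_hash": self.hash(), "seed": self.seed}


def _deep_update(base, extra):
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def load_config(path) -> Config:
    """Load YAML or JSON config, merged over defaults."""
    with open(path) as fh:
        text = fh.read()
    if os.fspath(path).lower().endswith(".json"):
        data = json.loads(text)
    else:
        import yaml
        data = yaml.safe_load(text) or {}
    return Config(data=data)
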