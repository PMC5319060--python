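"""Synthetic abdominal-phantom generator.

Emulates the study object every other module is exercised against: a
labeled voxel organ (parenchyma ellipsoid) with an embedded stiff tumor
sphere and a vessel tube, 25 landmarks (11 on the organ surface, 14
internal on the lesion boundaries), and families of top-surface
compression scenarios of varying position, magnitude and orientation.
Everything is reproducible bit-for-bit from the seed.

The default grid (16 x 8 x 12 cells at 5 mm) is sized so that the full
calibrate / enrich / register loop runs in minutes while keeping both
lesions thick enough (>= 3 cells across) for their split-vertex support
domains to be well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io import (BACKGROUND, PARENCHYMA, TUMOR, VESSEL, LabeledVolume,
                 LandmarkSet)
from .model import Scenario


@dataclass
class PhantomSpec:
    dims: tuple = (16, 8, 12)
    spacing: float = 5e-3                      # m, isotropic
    ellipsoid_center: np.ndarray = None        # defaults to grid center, m
    ellipsoid_semi: np.ndarray = None          # (3,) semi-axes, m
    tumor_centers: list = None                 # list of (3,) m
    tumor_radii: list = None                   # list of m
    vessel_polyline: np.ndarray = None         # (k, 3) m
    vessel_radius: float = None                # m
    n_surface_landmarks: int = 11
    n_tumor_landmarks: int = 7
    n_vessel_landmarks: int = 7
    seed: int = 0

    def __post_init__(self):
        h = self.spacing
        if self.ellipsoid_center is None:
            self.ellipsoid_center = np.array([8.0, 4.0, 6.0]) * h
        if self.ellipsoid_semi is None:
            self.ellipsoid_semi = np.array([7.3, 3.7, 5.3]) * h
        if self.tumor_centers is None:
            self.tumor_centers = [np.array([11.0, 4.0, 6.5]) * h]
            self.tumor_radii = [1.9 * h]
        if self.tumor_radii is None:
            self.tumor_radii = []
        if self.vessel_polyline is None:
            self.vessel_polyline = np.array([[4.0, 4.0, 5.0],
                                             [8.5, 4.0, 5.0]]) * h
        if self.vessel_radius is None:
            self.vessel_radius = 1.8 * h
        self.ellipsoid_center = np.asarray(self.ellipsoid_center, float)
        self.ellipsoid_semi = np.asarray(self.ellipsoid_semi, float)
        if min(self.n_surface_landmarks, self.n_tumor_landmarks,
               self.n_vessel_landmarks) < 0:
            raise ValidationError("landmark counts must be >= 0")


def _segment_distances(points, polyline):
    """Min distance of each point to a polyline, vectorized over points."""
    d = np.full(len(points), np.inf)
    for a, b in zip(polyline[:-1], polyline[1:]):
        ab = b - a
        denom = float(ab @ ab)
        t = np.clip((points - a) @ ab / denom, 0.0, 1.0) if denom > 0 else 0.0
        proj = a + np.outer(t, ab) if denom > 0 else np.tile(a, (len(points), 1))
        d = np.minimum(d, np.linalg.norm(points - proj, axis=1))
    return d


def _boundary_voxels(mask, against=None):
    """Voxels of ``mask`` 6-adjacent to ``against`` (default: ~mask, with
    out-of-grid counting as outside)."""
    other = ~mask if against is None else against
    pad = np.pad(other, 1, constant_values=against is None)
    neigh = np.zeros_like(mask)
    for ax in range(3):
        lo = [slice(1, -1)] * 3
        hi = [slice(1, -1)] * 3
        lo[ax] = slice(0, -2)
        hi[ax] = slice(2, None)
        neigh |= pad[tuple(lo)] | pad[tuple(hi)]
    return mask & neigh


def generate_phantom(spec: PhantomSpec = None):
    """(LabeledVolume, LandmarkSet) by analytic membership of voxel
    centers, precedence tumor > vessel > parenchyma; landmarks are sampled
    (seeded) on the organ surface and lesion boundary voxels."""
    spec = spec or PhantomSpec()
    dims = tuple(int(d) for d in spec.dims)
    h = spec.spacing
    vol0 = LabeledVolume(labels=np.zeros(dims, np.int16),
                         spacing=np.full(3, h))
    centers = vol0.voxel_centers().reshape(-1, 3)
    rel = (centers - spec.ellipsoid_center) / spec.ellipsoid_semi
    parenchyma = np.sum(rel ** 2, axis=1) <= 1.0
    vessel = _segment_distances(centers, np.asarray(spec.vessel_polyline)
                                ) <= spec.vessel_radius
    tumor = np.zeros(len(centers), bool)
    for c, r in zip(spec.tumor_centers, spec.tumor_radii):
        tumor |= np.linalg.norm(centers - np.asarray(c), axis=1) <= r
    labels = np.zeros(len(centers), np.int16)
    labels[parenchyma] = PARENCHYMA
    labels[vessel] = VESSEL
    labels[tumor] = TUMOR  # tumor precedence over vessel over parenchyma
    labels = labels.reshape(dims)

    # lesions must sit strictly inside the parenchyma: no lesion voxel may
    # touch background or the grid edge
    lesion = labels >= VESSEL
    touching = _boundary_voxels(lesion, against=(labels == BACKGROUND))
    interior = np.zeros_like(lesion)
    interior[1:-1, 1:-1, 1:-1] = True
    touching |= lesion & ~interior
    if touching.any():
        idx = tuple(int(v) for v in np.argwhere(touching)[0])
        raise ValidationError(f"lesion escapes the parenchyma at voxel {idx}")

    vol = LabeledVolume(labels=labels, spacing=np.full(3, h))
    rng = np.random.default_rng(spec.seed)
    lm_ids, lm_pos, lm_cat = [], [], []

    def sample(mask3d, count, category, prefix):
        cand = np.argwhere(mask3d)
        if count > len(cand):
            raise ValidationError(
                f"cannot place {count} {category} landmarks on "
                f"{len(cand)} candidate voxels")
        pick = cand[rng.choice(len(cand), size=count, replace=False)]
        for n, (i, j, k) in enumerate(pick):
            lm_ids.append(f"{prefix}{n:02d}")
            lm_pos.append((np.array([i, j, k]) + 0.5) * h)
            lm_cat.append(category)

    sample(_boundary_voxels(labels == PARENCHYMA, against=(labels == BACKGROUND)),
           spec.n_surface_landmarks, "surface", "S")
    sample(_boundary_voxels(labels == TUMOR), spec.n_tumor_landmarks,
           "internal-tumor", "T")
    sample(_boundary_voxels(labels == VESSEL), spec.n_vessel_landmarks,
           "internal-vessel", "V")
    landmarks = LandmarkSet(ids=lm_ids, positions=np.array(lm_pos).reshape(-1, 3),
                            categories=lm_cat)
    return vol, landmarks


def top_surface_height(vol: LabeledVolume):
    """Per-(i, j) column: z (m) of the top foreground voxel face, NaN where
    the column is empty."""
    fg = vol.labels > 0
    nz = vol.dims[2]
    has = fg.any(axis=2)
    top_k = nz - 1 - np.argmax(fg[:, :, ::-1], axis=2)
    z = vol.origin[2] + (top_k + 1) * vol.spacing[2]
    z = np.where(has, z, np.nan)
    return z


def generate_scenarios(vol: LabeledVolume, n_positions=5, n_magnitudes=1,
                       n_orientations=1, magnitude_range=(5e-3, 1e-2),
                       cone_angle_deg=15.0, patch_half_cells=3.0, seed=0):
    """Cross product of compression positions x magnitudes x orientations.

    Positions are patches spread along x on the top surface; magnitudes
    are evenly spaced over ``magnitude_range``; orientations are unit
    vectors inside a cone about the inward normal (-z), the first one
    being the exact normal.

    The defaults emulate compression by a rigid plate: a patch a few
    centimeters across pushed of the order of a centimeter into an organ
    ~6 cm tall, which produces landmark displacements of a few millimeters
    throughout the volume — the regime in which registration errors of the
    scale reported for compressed abdominal phantoms arise at all.
    """
    if min(n_positions, n_magnitudes, n_orientations) < 1:
        raise ValidationError("scenario counts must be >= 1")
    if not 0 <= cone_angle_deg < 90:
        raise ValidationError("cone angle must be in [0, 90) degrees")
    rng = np.random.default_rng(seed)
    fg = vol.labels > 0
    has = fg.any(axis=2)
    cols = np.argwhere(has)
    x_lo = (cols[:, 0].min() + 1) * vol.spacing[0] + vol.origin[0]
    x_hi = cols[:, 0].max() * vol.spacing[0] + vol.origin[0]
    xs = np.linspace(x_lo, x_hi, n_positions + 2)[1:-1]
    y_c = vol.origin[1] + (cols[:, 1].min() + cols[:, 1].max() + 1) / 2.0 \
        * vol.spacing[1]
    z_top = top_surface_height(vol)
    mags = np.linspace(*magnitude_range, n_magnitudes)
    cone = np.deg2rad(cone_angle_deg)
    dirs = []
    for o in range(n_orientations):
        if o == 0:
            dirs.append(np.array([0.0, 0.0, -1.0]))
        else:
            theta = cone * np.sqrt(rng.uniform())
            phi = rng.uniform(0.0, 2.0 * np.pi)
            d = np.array([np.sin(theta) * np.cos(phi),
                          np.sin(theta) * np.sin(phi), -np.cos(theta)])
            dirs.append(d / np.linalg.norm(d))
    half = np.array([patch_half_cells * vol.spacing[0],
                     patch_half_cells * vol.spacing[1], np.inf])
    out = []
    for p, xc in enumerate(xs):
        i_c = int(np.clip((xc - vol.origin[0]) / vol.spacing[0],
                          0, vol.dims[0] - 1))
        j_c = int(np.clip((y_c - vol.origin[1]) / vol.spacing[1],
                          0, vol.dims[1] - 1))
        zc = z_top[i_c, j_c]
        center = np.array([xc, y_c, zc if np.isfinite(zc) else 0.0])
        for m in mags:
            for d in dirs:
                out.append(Scenario(position_index=p, patch_center=center,
                                    patch_half=half.copy(), direction=d,
                                    magnitude=float(m)))
    return out


@dataclass
class GroundTruthCase:
    scenario: Scenario
    predicted: LandmarkSet      # noiseless model output
    observed: LandmarkSet       # predicted + isotropic Gaussian noise
    sigma: float                # m, per coordinate
    seed: int


def generate_ground_truth(model, landmarks: LandmarkSet, scenario: Scenario,
                          true_params, sigma=0.0, seed=0) -> GroundTruthCase:
    """Model-generated ground truth: run the heterogeneous forward model
    with ``true_params``; observed positions add N(0, sigma^2) noise per
    coordinate."""
    embedded = model.embed(landmarks)
    state = model.solve(scenario, params=true_params)
    predicted = model.predict_landmarks(state, embedded, landmarks)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=predicted.positions.shape) \
        if sigma > 0 else np.zeros_like(predicted.positions)
    observed = LandmarkSet(ids=list(predicted.ids),
                           positions=predicted.positions + noise,
                           categories=list(predicted.categories))
    return GroundTruthCase(scenario=scenario, predicted=predicted,
                           observed=observed, sigma=sigma, seed=seed)
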