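"""Moving-least-squares support domains and shape functions.

A query point is represented by a weighted least-squares fit over the nodes
of its support domain with a linear basis (1, x, y, z).  The resulting
shape functions satisfy partition of unity and reproduce any affine field
exactly — the two properties the tissue-coupling scheme and the detail
enrichment both rely on.

Two weight kernels are provided:

``cubic_spline``
    The standard compactly supported meshfree kernel of the normalized
    distance r/r_s (non-interpolating); used for boundary-vertex support
    domains.

``singular``
    Regularized inverse-distance-to-the-4th kernel.  Weights diverge as the
    query approaches a node, which makes the scheme interpolating there
    (delta property); used for the element-level detail-enrichment fit so
    fine vertices that coincide with coarse vertices track them exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SingularMomentMatrixError, ValidationError


@dataclass
class SupportDomain:
    query: np.ndarray        # (3,) m
    indices: np.ndarray      # node ids into the caller's node array
    positions: np.ndarray    # (n, 3) rest positions, m
    radius: float            # support radius actually used, m
    growths: int = 0         # how many times the radius was grown


@dataclass
class ShapeFunctionSet:
    indices: np.ndarray
    weights: np.ndarray      # one phi_j per node; sums to 1

    def reconstruct(self, nodal_values):
        """Sigma phi_j * value_j for per-node scalars or vectors."""
        return self.weights @ np.asarray(nodal_values)


def cubic_spline_weight(r):
    """Compact cubic-spline kernel of normalized distance r = d / r_s."""
    r = np.asarray(r, float)
    w = np.zeros_like(r)
    m1 = r <= 0.5
    w[m1] = 2.0 / 3.0 - 4.0 * r[m1] ** 2 + 4.0 * r[m1] ** 3
    m2 = (r > 0.5) & (r <= 1.0)
    w[m2] = 4.0 / 3.0 - 4.0 * r[m2] + 4.0 * r[m2] ** 2 - (4.0 / 3.0) * r[m2] ** 3
    return w


def singular_weight(r, eps=1e-12):
    r = np.asarray(r, float)
    return 1.0 / (r ** 4 + eps)


_KERNELS = {"cubic_spline": cubic_spline_weight, "singular": singular_weight}


def build_support_domain(query, candidate_positions, radius, min_nodes=4,
                         candidate_indices=None, growth=1.3, max_growth=5
                         ) -> SupportDomain:
    """Select candidate nodes within ``radius`` of ``query``; if fewer than
    ``min_nodes`` fall inside, grow the radius by ``growth`` (at most
    ``max_growth`` times)."""
    pos = np.asarray(candidate_positions, float).reshape(-1, 3)
    if len(pos) == 0:
        raise ValidationError("empty candidate set for support domain")
    query = np.asarray(query, float)
    if candidate_indices is None:
        candidate_indices = np.arange(len(pos))
    candidate_indices = np.asarray(candidate_indices)
    dist = np.linalg.norm(pos - query, axis=1)
    r = float(radius)
    growths = 0
    while True:
        inside = dist <= r
        if inside.sum() >= min_nodes:
            break
        if growths >= max_growth:
            raise ValidationError(
                f"support domain under-determined: {int(inside.sum())} nodes "
                f"within radius {r:.4g} m after {growths} growths "
                f"(need {min_nodes})")
        r *= growth
        growths += 1
    return SupportDomain(query=query, indices=candidate_indices[inside],
                         positions=pos[inside], radius=r, growths=growths)


def mls_weights(query, positions, radius, kernel="cubic_spline"):
    """Raw MLS shape-function weights at ``query`` over ``positions``.

    Linear basis, shifted and scaled by the support radius for
    conditioning.  Raises :class:`SingularMomentMatrixError` when the
    moment matrix is (numerically) singular, e.g. for coplanar nodes.
    """
    query = np.asarray(query, float)
    positions = np.asarray(positions, float).reshape(-1, 3)
    n = len(positions)
    d = (positions - query) / radius
    r = np.linalg.norm(d, axis=1)
    if kernel == "singular":
        # delta property shortcut: an (almost) coincident node wins outright
        hit = np.argmin(r)
        if r[hit] < 1e-9:
            w = np.zeros(n)
            w[hit] = 1.0
            return w
    w = _KERNELS[kernel](r)
    if np.all(w <= 0):
        raise SingularMomentMatrixError(
            "all kernel weights vanish; grow the support radius")
    p = np.hstack([np.ones((n, 1)), d])            # (n, 4) shifted basis
    a = (p * w[:, None]).T @ p                     # (4, 4) moment matrix
    # basis at the query point is (1, 0, 0, 0) in shifted coordinates
    try:
        cond = np.linalg.cond(a)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError
        c = np.linalg.solve(a, np.array([1.0, 0.0, 0.0, 0.0]))
    except np.linalg.LinAlgError:
        raise SingularMomentMatrixError(
            "singular MLS moment matrix (degenerate support domain); "
            "grow the support radius") from None
    return w * (p @ c)


def compute_shape_functions(domain: SupportDomain, kernel="cubic_spline"
                            ) -> ShapeFunctionSet:
    """MLS shape functions for a support domain (partition of unity,
    exact affine reproduction)."""
    weights = mls_weights(domain.query, domain.positions, domain.radius,
                          kernel=kernel)
    return ShapeFunctionSet(indices=np.asarray(domain.indices),
                            weights=weights)
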