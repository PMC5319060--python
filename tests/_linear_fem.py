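"""Independent small-strain linear-elastic static FEM oracle.

Isoparametric 8-node hexahedra with full 2x2x2 Gauss quadrature, assembled
from scratch (standard B-matrix formulation with the element Jacobian) and
solved as a sparse linear system — deliberately sharing no code with the
package's total-Lagrangian assembly.
"""

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

# corner order matches VTK hexahedron numbering
CORNERS = np.array([
    (-1, -1, -1), (1, -1, -1), (1, 1, -1), (-1, 1, -1),
    (-1, -1, 1), (1, -1, 1), (1, 1, 1), (-1, 1, 1),
], dtype=float)

GAUSS = [(-1 / np.sqrt(3), 1.0), (1 / np.sqrt(3), 1.0)]


def shape_gradients(xi, eta, zeta):
    """dN/d(xi,eta,zeta) for the trilinear hex, shape (8, 3)."""
    g = np.empty((8, 3))
    for a, (sx, sy, sz) in enumerate(CORNERS):
        g[a, 0] = sx * (1 + sy * eta) * (1 + sz * zeta) / 8.0
        g[a, 1] = (1 + sx * xi) * sy * (1 + sz * zeta) / 8.0
        g[a, 2] = (1 + sx * xi) * (1 + sy * eta) * sz / 8.0
    return g


def elasticity_matrix(E, nu):
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[3:, 3:] = np.eye(3) * mu
    return D


def element_stiffness(coords, E, nu):
    """8-node hex stiffness (24 x 24) by full Gauss quadrature."""
    D = elasticity_matrix(E, nu)
    K = np.zeros((24, 24))
    for xi, wx in GAUSS:
        for eta, wy in GAUSS:
            for zeta, wz in GAUSS:
                dN = shape_gradients(xi, eta, zeta)     # (8, 3) natural
                J = dN.T @ coords                       # (3, 3)
                dNdx = dN @ np.linalg.inv(J).T          # (8, 3) spatial
                B = np.zeros((6, 24))
                for a in range(8):
                    bx, by, bz = dNdx[a]
                    B[0, 3 * a] = bx
                    B[1, 3 * a + 1] = by
                    B[2, 3 * a + 2] = bz
                    B[3, 3 * a] = by
                    B[3, 3 * a + 1] = bx
                    B[4, 3 * a + 1] = bz
                    B[4, 3 * a + 2] = by
                    B[5, 3 * a] = bz
                    B[5, 3 * a + 2] = bx
                K += wx * wy * wz * np.linalg.det(J) * (B.T @ D @ B)
    return K


def solve_linear_static(nodes, elements, youngs, poissons, fixed_dofs,
                        fixed_values, forces=None):
    """Static displacements for prescribed-dof boundary conditions.

    ``youngs``/``poissons`` are per-element; ``fixed_dofs`` are global dof
    indices (3 * node + component) with values ``fixed_values``.
    """
    n_dof = 3 * len(nodes)
    rows, cols, vals = [], [], []
    for e, el in enumerate(elements):
        Ke = element_stiffness(nodes[el], youngs[e], poissons[e])
        dofs = np.repeat(el * 3, 3) + np.tile([0, 1, 2], 8)
        for i in range(24):
            rows.extend([dofs[i]] * 24)
            cols.extend(dofs)
            vals.extend(Ke[i])
    K = sp.csr_matrix((vals, (rows, cols)), shape=(n_dof, n_dof))
    f = np.zeros(n_dof) if forces is None else np.asarray(forces, float).ravel().copy()
    u = np.zeros(n_dof)
    u[fixed_dofs] = fixed_values
    free = np.setdiff1d(np.arange(n_dof), fixed_dofs)
    rhs = f[free] - K[free][:, fixed_dofs] @ u[fixed_dofs]
    u[free] = spla.spsolve(K[free][:, free].tocsc(), rhs)
    return u.reshape(-1, 3)
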