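"""Fused numba kernel for the hot total-Lagrangian force assembly.

The kernel computes, per element: gather nodal displacements, F = I + Bu,
the compressible Neo-Hookean second Piola-Kirchhoff stress, nodal internal
forces through the rest-configuration shape derivatives, the hourglass
stabilization, and scatter-adds into the global force vector.  It returns
the id of the first inverted element (det F <= 0) or -1; the caller raises.

Falls back to a pure-NumPy implementation when numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is a declared dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True, fastmath=False)
def _forces_kernel(elements, u, B, wvol, volume, mu, lam, kappa, gamma, fout):
    n_el = elements.shape[0]
    ngp = B.shape[0]
    ue = np.empty((8, 3))
    fe = np.empty((8, 3))
    F = np.empty((3, 3))
    C = np.empty((3, 3))
    Cinv = np.empty((3, 3))
    S = np.empty((3, 3))
    P = np.empty((3, 3))
    q = np.empty(3)
    for e in range(n_el):
        for a in range(8):
            n = elements[e, a]
            for i in range(3):
                ue[a, i] = u[n, i]
                fe[a, i] = 0.0
        for g in range(ngp):
            for i in range(3):
                for j in range(3):
                    s = 0.0
                    for a in range(8):
                        s += ue[a, i] * B[g, a, j]
                    F[i, j] = s
                F[i, i] += 1.0
            detF = (F[0, 0] * (F[1, 1] * F[2, 2] - F[1, 2] * F[2, 1])
                    - F[0, 1] * (F[1, 0] * F[2, 2] - F[1, 2] * F[2, 0])
                    + F[0, 2] * (F[1, 0] * F[2, 1] - F[1, 1] * F[2, 0]))
            if detF <= 0.0:
                return e
            for i in range(3):
                for j in range(3):
                    s = 0.0
                    for k in range(3):
                        s += F[k, i] * F[k, j]
                    C[i, j] = s
            a00 = C[1, 1] * C[2, 2] - C[1, 2] * C[1, 2]
            a01 = C[0, 2] * C[1, 2] - C[0, 1] * C[2, 2]
            a02 = C[0, 1] * C[1, 2] - C[0, 2] * C[1, 1]
            a11 = C[0, 0] * C[2, 2] - C[0, 2] * C[0, 2]
            a12 = C[0, 2] * C[0, 1] - C[0, 0] * C[1, 2]
            a22 = C[0, 0] * C[1, 1] - C[0, 1] * C[0, 1]
            detC = C[0, 0] * a00 + C[0, 1] * a01 + C[0, 2] * a02
            Cinv[0, 0] = a00 / detC
            Cinv[0, 1] = a01 / detC
            Cinv[0, 2] = a02 / detC
            Cinv[1, 0] = a01 / detC
            Cinv[1, 1] = a11 / detC
            Cinv[1, 2] = a12 / detC
            Cinv[2, 0] = a02 / detC
            Cinv[2, 1] = a12 / detC
            Cinv[2, 2] = a22 / detC
            lnJ = 0.5 * np.log(detC)
            for i in range(3):
                for j in range(3):
                    S[i, j] = -mu[e] * Cinv[i, j] + lam[e] * lnJ * Cinv[i, j]
                S[i, i] += mu[e]
            for i in range(3):
                for j in range(3):
                    s = 0.0
                    for k in range(3):
                        s += F[i, k] * S[k, j]
                    P[i, j] = s
            vg = volume[e] * wvol[g]
            for a in range(8):
                for i in range(3):
                    s = 0.0
                    for j in range(3):
                        s += P[i, j] * B[g, a, j]
                    fe[a, i] += vg * s
        if kappa[e] != 0.0:
            for m in range(4):
                for i in range(3):
                    q[i] = 0.0
                for a in range(8):
                    for i in range(3):
                        q[i] += gamma[a, m] * ue[a, i]
                for a in range(8):
                    for i in range(3):
                        fe[a, i] += kappa[e] * gamma[a, m] * q[i]
        for a in range(8):
            n = elements[e, a]
            for i in range(3):
                fout[n, i] += fe[a, i]
    return -1


def assemble_internal_forces(elements, u, B, wvol, volume, mu, lam, kappa,
                             gamma, n_nodes):
    """Returns (force array (N,3), first inverted element id or -1)."""
    fout = np.zeros((n_nodes, 3))
    bad = _forces_kernel(elements, u, B, wvol, volume, mu, lam, kappa, gamma,
                         fout)
    return fout, int(bad)
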