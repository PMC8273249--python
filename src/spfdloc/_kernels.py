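"""Numba kernels for the node-lattice finite-difference solver.

All arrays are indexed (i, j, k) over the node lattice; ``Sx[i, j, k]`` is
the conductance of the edge from node (i, j, k) to (i+1, j, k), likewise
Sy/Sz along the other axes.  Non-free nodes (air or the pinned reference)
are skipped by the sweeps and carry potential 0.
"""

from __future__ import annotations

import numba
import numpy as np


@numba.njit(cache=True, fastmath=True)
def sor_sweep(x, b, Sx, Sy, Sz, diag, free, omega, forward):  # pragma: no cover
    """One in-place SOR sweep in lexicographic (forward) or reverse order."""
    n0, n1, n2 = x.shape
    if forward:
        for i in range(n0):
            for j in range(n1):
                for k in range(n2):
                    if not free[i, j, k]:
                        continue
                    acc = b[i, j, k]
                    if i > 0:
                        acc += Sx[i - 1, j, k] * x[i - 1, j, k]
                    if i < n0 - 1:
                        acc += Sx[i, j, k] * x[i + 1, j, k]
                    if j > 0:
                        acc += Sy[i, j - 1, k] * x[i, j - 1, k]
                    if j < n1 - 1:
                        acc += Sy[i, j, k] * x[i, j + 1, k]
                    if k > 0:
                        acc += Sz[i, j, k - 1] * x[i, j, k - 1]
                    if k < n2 - 1:
                        acc += Sz[i, j, k] * x[i, j, k + 1]
                    x[i, j, k] += omega * (acc / diag[i, j, k] - x[i, j, k])
    else:
        for i in range(n0 - 1, -1, -1):
            for j in range(n1 - 1, -1, -1):
                for k in range(n2 - 1, -1, -1):
                    if not free[i, j, k]:
                        continue
                    acc = b[i, j, k]
                    if i > 0:
                        acc += Sx[i - 1, j, k] * x[i - 1, j, k]
                    if i < n0 - 1:
                        acc += Sx[i, j, k] * x[i + 1, j, k]
                    if j > 0:
                        acc += Sy[i, j - 1, k] * x[i, j - 1, k]
                    if j < n1 - 1:
                        acc += Sy[i, j, k] * x[i, j + 1, k]
                    if k > 0:
                        acc += Sz[i, j, k - 1] * x[i, j, k - 1]
                    if k < n2 - 1:
                        acc += Sz[i, j, k] * x[i, j, k + 1]
                    x[i, j, k] += omega * (acc / diag[i, j, k] - x[i, j, k])


@numba.njit(cache=True, fastmath=True)
def residual(x, b, Sx, Sy, Sz, diag, free):  # pragma: no cover
    """r = b - A x on free nodes (0 elsewhere), A the edge-conductance Laplacian."""
    n0, n1, n2 = x.shape
    r = np.zeros_like(x)
    for i in range(n0):
        for j in range(n1):
            for k in range(n2):
                if not free[i, j, k]:
                    continue
                acc = b[i, j, k] - diag[i, j, k] * x[i, j, k]
                if i > 0:
                    acc += Sx[i - 1, j, k] * x[i - 1, j, k]
                if i < n0 - 1:
                    acc += Sx[i, j, k] * x[i + 1, j, k]
                if j > 0:
                    acc += Sy[i, j - 1, k] * x[i, j - 1, k]
                if j < n1 - 1:
                    acc += Sy[i, j, k] * x[i, j + 1, k]
                if k > 0:
                    acc += Sz[i, j, k - 1] * x[i, j, k - 1]
                if k < n2 - 1:
                    acc += Sz[i, j, k] * x[i, j, k + 1]
                r[i, j, k] = acc
    return r
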