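"""Reference-element machinery shared by the mesh and the Biot solver.

Nine-node biquadratic Lagrange quadrilaterals (displacement, geometry) paired
with four-node bilinear quadrilaterals (pore pressure) — the inf-sup stable
Taylor-Hood pairing.  Local node order:

    corners   0:(-1,-1) 1:(+1,-1) 2:(+1,+1) 3:(-1,+1)
    midsides  4:( 0,-1) 5:(+1, 0) 6:( 0,+1) 7:(-1, 0)
    centre    8:( 0, 0)
"""

from __future__ import annotations

import numpy as np

__all__ = ["gauss_2d", "shape_q9", "shape_q4", "GAUSS_PTS", "GAUSS_WTS"]


def _lag1d(x: np.ndarray):
    """1D quadratic Lagrange basis at nodes -1, 0, +1 and its derivative."""
    vals = np.stack([0.5 * x * (x - 1.0), 1.0 - x * x, 0.5 * x * (x + 1.0)])
    ders = np.stack([x - 0.5, -2.0 * x, x + 0.5])
    return vals, ders


# (i_xi, i_eta) index into the 1D basis {-1, 0, +1} for each local Q9 node
_Q9_IDX = [(0, 0), (2, 0), (2, 2), (0, 2), (1, 0), (2, 1), (1, 2), (0, 1), (1, 1)]
_Q4_SIGNS = [(-1, -1), (1, -1), (1, 1), (-1, 1)]


def shape_q9(xi: float, eta: float):
    """Values (9,) and reference gradients (9, 2) of the Q9 basis."""
    lx, dlx = _lag1d(np.asarray([xi]))
    ly, dly = _lag1d(np.asarray([eta]))
    lx, dlx, ly, dly = lx[:, 0], dlx[:, 0], ly[:, 0], dly[:, 0]
    N = np.empty(9)
    dN = np.empty((9, 2))
    for a, (i, j) in enumerate(_Q9_IDX):
        N[a] = lx[i] * ly[j]
        dN[a, 0] = dlx[i] * ly[j]
        dN[a, 1] = lx[i] * dly[j]
    return N, dN


def shape_q4(xi: float, eta: float):
    """Values (4,) and reference gradients (4, 2) of the Q4 basis."""
    N = np.empty(4)
    dN = np.empty((4, 2))
    for a, (sx, sy) in enumerate(_Q4_SIGNS):
        N[a] = 0.25 * (1.0 + sx * xi) * (1.0 + sy * eta)
        dN[a, 0] = 0.25 * sx * (1.0 + sy * eta)
        dN[a, 1] = 0.25 * sy * (1.0 + sx * xi)
    return N, dN


def gauss_2d(n: int = 3):
    """Tensor-product Gauss points and weights on [-1, 1]^2."""
    x, w = np.polynomial.legendre.leggauss(n)
    pts = np.array([(xi, eta) for eta in x for xi in x])
    wts = np.array([wi * wj for wj in w for wi in w])
    return pts, wts


GAUSS_PTS, GAUSS_WTS = gauss_2d(3)
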