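"""Linear least-squares solvers with inequality constraints.

All DMFA variants are convex quadratic programs:

* unbounded — plain weighted least squares;
* bounded   — least squares with general inequalities ``G x >= 0``
  (irreversibility expressed through the null-space map), solved by the
  Lawson–Hanson reduction LSI -> LDP -> NNLS, an exact active-set method;
* EM modes  — least squares with non-negativity on a subset of the
  variables (the EM node rates; initial concentrations stay free),
  solved by projecting out the free block and running NNLS on the rest.

These give deterministic, high-accuracy solutions without an external QP
package and satisfy the KKT conditions to solver tolerance.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import nnls

__all__ = ["lstsq_free", "lsq_linear_inequality", "lsq_partial_nonneg"]


class SolverError(RuntimeError):
    pass


def lstsq_free(A: np.ndarray, b: np.ndarray, allow_deficient: bool = False):
    """Ordinary least squares; errors on rank deficiency unless the
    minimum-norm fallback is allowed."""
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    x, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < A.shape[1] and not allow_deficient:
        raise SolverError(
            f"design rank-deficient ({rank} < {A.shape[1]}); "
            "enable the minimum-norm fallback or refine the data/grid")
    return x


def _nnls(A, b, maxiter=None):
    try:
        x, _ = nnls(A, b, maxiter=maxiter)
    except TypeError:  # older scipy signature
        x, _ = nnls(A, b)
    return x


def lsq_linear_inequality(A: np.ndarray, b: np.ndarray, G: np.ndarray,
                          h: np.ndarray | None = None) -> np.ndarray:
    """min ||A x - b||_2 subject to G x >= h (h defaults to 0).

    Requires A of full column rank.  Reduction: with A = Q R and
    x = x_ls + R^{-1} y the objective becomes ||y||; the least-distance
    problem min ||y|| s.t. (G R^{-1}) y >= h - G x_ls is solved through
    its NNLS dual (Lawson & Hanson, ch. 23).
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    G = np.atleast_2d(np.asarray(G, dtype=float))
    n = A.shape[1]
    if h is None:
        h = np.zeros(G.shape[0])
    Q, R = np.linalg.qr(A)
    diag = np.abs(np.diag(R))
    if diag.min() <= 1e-12 * max(1.0, diag.max()):
        raise SolverError("design rank-deficient in constrained solve")
    x_ls = np.linalg.solve(R, Q.T @ b)
    if G.shape[0] == 0:
        return x_ls
    Gt = np.linalg.solve(R.T, G.T).T          # G @ R^{-1}
    ht = h - G @ x_ls
    y = _ldp(Gt, ht)
    return x_ls + np.linalg.solve(R, y)


def _ldp(G: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Least-distance program min ||y|| s.t. G y >= h, via NNLS."""
    m, n = G.shape
    scale = max(1.0, np.abs(G).max(), np.abs(h).max())
    E = np.vstack([G.T / scale, h[None, :] / scale])   # (n+1, m)
    f = np.zeros(n + 1)
    f[-1] = 1.0
    u = _nnls(E, f, maxiter=30 * max(m, n))
    r = E @ u - f
    if abs(r[-1]) < 1e-12:
        raise SolverError("inequality constraints infeasible")
    return -r[:n] / r[-1]


def lsq_partial_nonneg(A_free: np.ndarray, A_pos: np.ndarray, b: np.ndarray,
                       ridge_rows: np.ndarray | None = None):
    """min ||A_free u + A_pos x - b||^2 (+ ||ridge_rows @ x||^2) s.t. x >= 0.

    The free block is eliminated by projecting onto the orthogonal
    complement of its column space, leaving a pure NNLS problem in x;
    u is then recovered by least squares.  Handles rank-deficient
    ``A_pos`` (NNLS picks a vertex solution deterministically); the
    optimal objective is unique regardless.

    Returns (u, x).
    """
    A_free = np.asarray(A_free, dtype=float)
    A_pos = np.asarray(A_pos, dtype=float)
    b = np.asarray(b, dtype=float)
    if A_free.shape[1]:
        Q, _ = np.linalg.qr(A_free, mode="reduced")
        Ap = A_pos - Q @ (Q.T @ A_pos)
        bp = b - Q @ (Q.T @ b)
    else:
        Ap, bp = A_pos, b
    if ridge_rows is not None and ridge_rows.size:
        Ap = np.vstack([Ap, ridge_rows])
        bp = np.concatenate([bp, np.zeros(ridge_rows.shape[0])])
    x = _nnls(Ap, bp, maxiter=50 * max(Ap.shape))
    if A_free.shape[1]:
        u, _, rank, _ = np.linalg.lstsq(A_free, b - A_pos @ x, rcond=None)
        if rank < A_free.shape[1]:
            raise SolverError("free-variable block rank-deficient")
    else:
        u = np.zeros(0)
    return u, x
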