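"""Piecewise-linear flux parameterization and its exact integral map.

Volumetric fluxes are piecewise linear in time between inflection points
T_1 < ... < T_m.  Concentrations are their exact integrals (piecewise
quadratic), so each predicted concentration is a *linear* function of
the node values — the property that lets DMFA fit concentrations
directly without numerically differentiating noisy data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["InflectionGrid", "hat_integral_matrix", "hat_value_matrix",
           "design_matrix"]


class GridError(ValueError):
    pass


@dataclass(frozen=True)
class InflectionGrid:
    """Strictly increasing node times spanning the data window."""

    nodes: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        if nodes.ndim != 1 or nodes.size < 2:
            raise GridError("need at least 2 inflection points")
        if np.any(np.diff(nodes) <= 0):
            raise GridError("inflection points must be strictly increasing")
        object.__setattr__(self, "nodes", nodes)

    @classmethod
    def from_span(cls, t_min: float, t_max: float, n_nodes: int = 5
                  ) -> "InflectionGrid":
        if n_nodes < 2:
            raise GridError("need at least 2 inflection points")
        return cls(np.linspace(float(t_min), float(t_max), n_nodes))

    @property
    def n_nodes(self) -> int:
        return self.nodes.size

    def check_covers(self, times) -> None:
        t = np.asarray(times, dtype=float)
        tol = 1e-9 * max(1.0, self.nodes[-1] - self.nodes[0])
        if t.size and (t.min() < self.nodes[0] - tol
                       or t.max() > self.nodes[-1] + tol):
            raise GridError(
                f"times [{t.min()}, {t.max()}] outside grid span "
                f"[{self.nodes[0]}, {self.nodes[-1]}]")


def hat_value_matrix(grid: InflectionGrid, times) -> np.ndarray:
    """B[t, j] = phi_j(t): linear interpolation weights on the grid."""
    t = np.asarray(times, dtype=float)
    grid.check_covers(t)
    T = grid.nodes
    B = np.zeros((t.size, T.size))
    seg = np.clip(np.searchsorted(T, t, side="right") - 1, 0, T.size - 2)
    s = (t - T[seg]) / (T[seg + 1] - T[seg])
    s = np.clip(s, 0.0, 1.0)
    B[np.arange(t.size), seg] = 1.0 - s
    B[np.arange(t.size), seg + 1] += s
    return B


def hat_integral_matrix(grid: InflectionGrid, times) -> np.ndarray:
    """Phi[t, j] = integral from T_1 to t of the hat function phi_j.

    A node-value vector u then yields the exact integral of the
    piecewise-linear flux: ``Phi @ u``.
    """
    t = np.asarray(times, dtype=float)
    grid.check_covers(t)
    T = grid.nodes
    m = T.size
    h = np.diff(T)
    # cumulative full-segment contributions: segment l adds h[l]/2 to nodes l, l+1
    cum = np.zeros((m, m))  # cum[j] = coefficients of int T1..T_j
    for j in range(1, m):
        cum[j] = cum[j - 1]
        cum[j, j - 1] += h[j - 1] / 2.0
        cum[j, j] += h[j - 1] / 2.0
    seg = np.clip(np.searchsorted(T, t, side="right") - 1, 0, m - 2)
    s = np.clip((t - T[seg]) / h[seg], 0.0, 1.0)
    Phi = cum[seg].copy()
    rows = np.arange(t.size)
    Phi[rows, seg] += h[seg] * (s - s ** 2 / 2.0)
    Phi[rows, seg + 1] += h[seg] * s ** 2 / 2.0
    return Phi


def design_matrix(directions: np.ndarray, grid: InflectionGrid, times
                  ) -> np.ndarray:
    """Linear operator from flux node values to concentration increments.

    ``directions`` D is (n_species x n_dir): P@K for network fits or E
    for EM fits.  Node values are vectorized direction-major
    (``x[k*m + j] = value of direction k at node j``).  The returned A is
    (n_species*n_times x n_dir*m) with row order species-major, so that
    ``c_hat = c0 (repeated) + A @ x`` evaluated at ``times``.
    """
    D = np.atleast_2d(np.asarray(directions, dtype=float))
    Phi = hat_integral_matrix(grid, times)          # (n_t, m)
    # A[(i,t), (k,j)] = D[i,k] * Phi[t,j]
    return np.kron(D, Phi)
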