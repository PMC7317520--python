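"""DMFA estimators: unbounded, bounded, and (regularized) EM variants.

The model: volumetric fluxes are piecewise linear between inflection
points; concentrations are their exact integrals.  Fitting minimizes the
uncertainty-weighted sum of squared residuals (SSR) between measured and
predicted concentrations,

    SSR = sum_i sum_j ((c_ij^m - c_ij_hat) / sigma_ij)^2,

which is a convex quadratic program in the flux node values and the
initial concentrations.  Modes:

``unbounded``       free fluxes U_k(T_j) in null-space coordinates;
``bounded``         adds K_irr @ U(T_j) >= 0 (irreversibility) at every
                    node — sufficient for all t because fluxes are
                    piecewise linear;
``em``              fluxes as non-negative rates R_k(T_j) of elementary
                    modes, V = E @ R;
``em_regularized``  adds the penalty alpha * sum_kj (R_k(T_j)/Xv(T_j))^2
                    on squared *cell-specific* rates, stabilizing
                    ill-conditioned large EM sets.

The estimator follows the scikit-learn protocol: hyperparameters in
``__init__``, data in :meth:`fit`, fitted attributes with trailing
underscores.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .design import InflectionGrid, design_matrix, hat_value_matrix
from .elementary import ElementaryModeMatrix
from .measurements import MeasurementSet
from .network import MetabolicNetwork
from .solvers import (SolverError, lsq_linear_inequality, lsq_partial_nonneg,
                      lstsq_free)

__all__ = ["DMFA", "compute_ssr", "specific_rates", "cross_validate_alpha",
           "fit_kinetics", "solve_unbounded", "solve_bounded", "solve_em"]

MODES = ("unbounded", "bounded", "em", "em_regularized")


def compute_ssr(measured: MeasurementSet, fitted: np.ndarray) -> float:
    """Weighted SSR over observed (non-masked) points.

    ``fitted`` is aligned with ``measured.values`` (n_species x n_times).
    """
    fitted = np.asarray(fitted, dtype=float)
    if fitted.shape != measured.values.shape:
        raise ValueError("fitted array shape mismatch")
    m = measured.mask
    res = (measured.values[m] - fitted[m]) / measured.sigmas[m]
    return float(res @ res)


class DMFA(BaseEstimator):
    """Dynamic metabolic flux analysis estimator.

    Parameters
    ----------
    mode : one of {"unbounded", "bounded", "em", "em_regularized"}
    grid : InflectionGrid or None
        Flux inflection points.  If None, ``n_nodes`` equally spaced
        nodes over the data span are used.
    n_nodes : int, default 5
        Node count for the automatic grid.
    alpha : float, default 0.0
        Regularization weight on squared cell-specific EM rates
        (only used by ``em_regularized``; ``em`` with alpha=0 is the
        plain non-negative problem).
    estimate_c0 : bool, default True
        Estimate initial concentrations jointly with the fluxes; if
        False they are pinned to the first observed value per species.
    allow_deficient : bool, default False
        Permit the minimum-norm solution for rank-deficient unbounded
        designs instead of raising.
    conditioning_ridge : float, default 0.0
        Tiny uniform ridge on EM node rates, purely for numerical
        conditioning of near-degenerate EM sets (used by the bootstrap).

    Attributes (after fit)
    ----------------------
    node_values_ : (n_directions, n_nodes) flux node values U or R (mM/h)
    c0_ : (n_species,) fitted (or pinned) initial concentrations
    ssr_ : weighted SSR at the optimum (penalty excluded)
    grid_ : the grid actually used
    directions_ : the direction matrix (P@K or E) over fitted species
    species_ids_ : species entering the residuals, in row order
    """

    def __init__(self, mode: str = "unbounded", grid: InflectionGrid | None = None,
                 n_nodes: int = 5, alpha: float = 0.0, estimate_c0: bool = True,
                 allow_deficient: bool = False, conditioning_ridge: float = 0.0):
        self.mode = mode
        self.grid = grid
        self.n_nodes = n_nodes
        self.alpha = alpha
        self.estimate_c0 = estimate_c0
        self.allow_deficient = allow_deficient
        self.conditioning_ridge = conditioning_ridge

    # -- fitting -------------------------------------------------------

    def fit(self, data: MeasurementSet, network: MetabolicNetwork | None = None,
            ems: ElementaryModeMatrix | None = None, xv_interp=None):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; choose from {MODES}")
        em_mode = self.mode in ("em", "em_regularized")
        if em_mode and ems is None:
            raise ValueError("EM modes need an ElementaryModeMatrix")
        if not em_mode and network is None:
            raise ValueError("network modes need a MetabolicNetwork")

        grid = self.grid or InflectionGrid.from_span(
            data.times.min(), data.times.max(), self.n_nodes)
        grid.check_covers(data.times)

        alpha = float(self.alpha) if self.mode == "em_regularized" else 0.0
        if alpha < 0:
            raise ValueError("alpha must be >= 0")

        if em_mode:
            D_full = ems.E
            avail = list(ems.species_ids)
        else:
            basis = network.null_space_basis()
            D_full = network.P @ basis.K
            avail = network.external_ids
            self._basis_ = basis

        # species entering residuals: data species present in the
        # direction matrix; an Xv series absent from it is kept aside
        # for interpolation only.
        sel, missing = [], []
        for sid in data.species_ids:
            if sid in avail:
                sel.append(sid)
            elif sid != data.xv_id:
                missing.append(sid)
        if missing:
            raise ValueError(f"measured species not in model: {missing}")
        if not sel:
            raise ValueError("no overlap between data and model species")
        rows = [avail.index(s) for s in sel]
        D = D_full[rows]

        n_dir, m = D.shape[1], grid.n_nodes
        times = data.times
        A_flux = design_matrix(D, grid, times)        # (n_s*n_t, n_dir*m)

        # assemble observed-row weighted system
        idx = [data.species_index(s) for s in sel]
        values = data.values[idx]
        sigmas = data.sigmas[idx]
        mask = ~np.isnan(values)
        w = 1.0 / sigmas[mask]
        obs = mask.ravel()
        Aw = A_flux[obs] * w[:, None]

        n_s = len(sel)
        if self.estimate_c0:
            C0 = np.repeat(np.eye(n_s), times.size, axis=0)[obs] * w[:, None]
            bw = values[mask] * w
        else:
            C0 = np.zeros((obs.sum(), 0))
            c0_pin = np.array([values[i][mask[i]][0] for i in range(n_s)])
            bw = (values[mask] - np.repeat(c0_pin, times.size).reshape(
                n_s, times.size)[mask]) * w

        if alpha > 0 or self.mode in ("em", "em_regularized"):
            if (alpha > 0 or self.conditioning_ridge > 0) and em_mode:
                if alpha > 0 and xv_interp is None:
                    raise ValueError("alpha > 0 requires an Xv interpolant")
            ridge = self._ridge_rows(alpha, n_dir, m, grid, xv_interp)
        else:
            ridge = None

        if self.mode == "unbounded":
            x = lstsq_free(np.hstack([C0, Aw]), bw,
                           allow_deficient=self.allow_deficient)
        elif self.mode == "bounded":
            K_irr = self._basis_.K_irr
            if K_irr.shape[0] == 0:
                x = lstsq_free(np.hstack([C0, Aw]), bw,
                               allow_deficient=self.allow_deficient)
            else:
                G_flux = np.kron(K_irr, np.eye(m))
                G = np.hstack([np.zeros((G_flux.shape[0], C0.shape[1])), G_flux])
                x = lsq_linear_inequality(np.hstack([C0, Aw]), bw, G)
        else:
            u, r = lsq_partial_nonneg(C0, Aw, bw, ridge_rows=ridge)
            x = np.concatenate([u, r])

        k0 = C0.shape[1]
        if self.estimate_c0:
            self.c0_ = x[:n_s]
        else:
            self.c0_ = c0_pin
        self.node_values_ = x[k0:].reshape(n_dir, m)
        self.grid_ = grid
        self.directions_ = D
        self.species_ids_ = sel
        self.alpha_ = alpha
        self._data_shape = (len(data.species_ids), times.size)
        fitted = self._predict_on(data.times)
        full = np.full(data.values.shape, np.nan)
        for i_fit, i_dat in enumerate(idx):
            full[i_dat] = fitted[i_fit]
        # species excluded from the fit (e.g. Xv outside E) contribute 0
        self._fitted_full = np.where(np.isnan(full), data.values, full)
        self.ssr_ = compute_ssr(data, self._fitted_full)
        return self

    def _ridge_rows(self, alpha, n_dir, m, grid, xv_interp):
        rows = []
        if alpha > 0:
            xv = np.asarray(xv_interp(grid.nodes), dtype=float)
            if np.any(xv <= 0):
                bad = grid.nodes[xv <= 0]
                raise ValueError(f"Xv <= 0 at inflection points {bad}")
            rows.append(np.kron(np.eye(n_dir), np.sqrt(alpha) * np.diag(1.0 / xv)))
        if self.conditioning_ridge > 0:
            rows.append(np.sqrt(self.conditioning_ridge) * np.eye(n_dir * m))
        return np.vstack(rows) if rows else None

    # -- evaluation ----------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "node_values_"):
            raise RuntimeError("estimator not fitted")

    def _predict_on(self, times) -> np.ndarray:
        A = design_matrix(self.directions_, self.grid_, times)
        inc = (A @ self.node_values_.ravel()).reshape(
            len(self.species_ids_), np.asarray(times).size)
        return self.c0_[:, None] + inc

    def predict(self, times) -> pd.DataFrame:
        """Fitted concentrations at ``times`` (piecewise quadratic)."""
        self._check_fitted()
        t = np.atleast_1d(np.asarray(times, dtype=float))
        return pd.DataFrame(self._predict_on(t), index=self.species_ids_,
                            columns=t)

    def flux_node_rates(self, times) -> np.ndarray:
        """Node-space rates (U or R) linearly interpolated at ``times``."""
        self._check_fitted()
        B = hat_value_matrix(self.grid_, np.atleast_1d(times))
        return self.node_values_ @ B.T

    def volumetric_fluxes(self, times) -> np.ndarray:
        """Reaction-space volumetric fluxes at ``times``.

        Network modes return V = K @ U (n_reactions x n_t); EM modes
        return the EM rates R (n_EM x n_t).
        """
        self._check_fitted()
        rates = self.flux_node_rates(times)
        if self.mode in ("unbounded", "bounded"):
            return self._basis_.K @ rates
        return rates

    def score(self, data: MeasurementSet) -> float:
        """Negative weighted SSR on ``data`` (higher is better)."""
        self._check_fitted()
        fitted = self.predict(data.times)
        full = np.full(data.values.shape, np.nan)
        for i, sid in enumerate(data.species_ids):
            if sid in self.species_ids_:
                full[i] = fitted.loc[sid].to_numpy()
        full = np.where(np.isnan(full), data.values, full)
        return -compute_ssr(data, full)


def specific_rates(fit: DMFA, xv_interp, times, volume_factor: float = 1.0
                   ) -> np.ndarray:
    """Cell-specific rates r_k(t) = R_k(t) / Xv(t).

    With concentrations in mM and Xv in 10^6 cells/ml the plain ratio is
    in mmol/(l*h) per (10^6 cells/ml); multiply by ``volume_factor=1e-3``
    (the ml<->l factor) to report mmol/10^6 cells/h.
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    xv = np.asarray(xv_interp(t), dtype=float)
    if np.any(xv <= 0):
        raise ValueError(f"Xv <= 0 at times {t[xv <= 0]}")
    return volume_factor * fit.volumetric_fluxes(t) / xv


# ---------------------------------------------------------------------
# module-level wrappers (thin over the estimator)
# ---------------------------------------------------------------------

def solve_unbounded(data, network, grid=None, **kw) -> DMFA:
    return DMFA(mode="unbounded", grid=grid, **kw).fit(data, network=network)


def solve_bounded(data, network, grid=None, **kw) -> DMFA:
    return DMFA(mode="bounded", grid=grid, **kw).fit(data, network=network)


def solve_em(data, ems, grid=None, xv_interp=None, alpha: float = 0.0, **kw
             ) -> DMFA:
    mode = "em_regularized" if alpha > 0 else "em"
    return DMFA(mode=mode, grid=grid, alpha=alpha, **kw).fit(
        data, ems=ems, xv_interp=xv_interp)


# ---------------------------------------------------------------------
# cross-validation of the regularization weight
# ---------------------------------------------------------------------

def cross_validate_alpha(data: MeasurementSet, ems: ElementaryModeMatrix,
                         grid: InflectionGrid | None = None,
                         alphas=(0.0, 1e-4, 1e-3, 1e-2, 1e-1, 1.0),
                         folds: int = 3, seed: int = 0, xv_interp=None,
                         **fit_kw):
    """Pick alpha by K-fold CV over time points.

    Time points are shuffled with ``seed`` and assigned to folds
    round-robin; each fold's points are masked out, the regularized EM
    problem is fitted on the rest, and the held-out weighted SSR is
    accumulated.  Returns ``(alpha_star, table)`` where the table lists
    the mean held-out SSR per alpha; ties break toward larger alpha.
    """
    alphas = sorted(set(float(a) for a in alphas))
    if not alphas or any(a < 0 for a in alphas):
        raise ValueError("alphas must be non-empty and non-negative")
    if folds < 2:
        raise ValueError("need >= 2 folds")
    if xv_interp is None:
        xv_interp = data.xv_interpolant()
    grid = grid or InflectionGrid.from_span(data.times.min(), data.times.max())
    rng = np.random.default_rng(seed)
    order = rng.permutation(data.times.size)
    assignment = np.empty(data.times.size, dtype=int)
    assignment[order] = np.arange(data.times.size) % folds

    held_out = np.zeros((len(alphas), folds))
    for f in range(folds):
        test_cols = assignment == f
        train = data.copy()
        train.values[:, test_cols] = np.nan
        per_species = (~np.isnan(train.values)).sum(axis=1)
        if np.any(per_species < 2):
            bad = [data.species_ids[i] for i in np.flatnonzero(per_species < 2)]
            raise ValueError(
                f"fold {f} leaves species {bad} with < 2 points; use fewer folds")
        test = data.copy()
        test.values[:, ~test_cols] = np.nan
        for a_i, alpha in enumerate(alphas):
            est = DMFA(mode="em_regularized" if alpha > 0 else "em",
                       grid=grid, alpha=alpha, **fit_kw)
            est.fit(train, ems=ems, xv_interp=xv_interp)
            held_out[a_i, f] = -est.score(test)

    mean = held_out.mean(axis=1)
    # ties toward larger alpha
    best = len(alphas) - 1 - int(np.argmin(mean[::-1]))
    table = pd.DataFrame({"alpha": alphas, "mean_heldout_ssr": mean})
    for f in range(folds):
        table[f"fold{f}"] = held_out[:, f]
    return alphas[best], table


# ---------------------------------------------------------------------
# kinetic fitting to estimated rates
# ---------------------------------------------------------------------

def fit_kinetics(rate_function, theta0, times, rates, sigmas, bounds=None,
                 **least_squares_kw):
    """Weighted nonlinear fit of a kinetic law to estimated rates.

    Minimizes ``sum_i ((rate_function(t_i, theta) - r_i)/sigma_i)^2``.
    ``sigmas`` typically come from bootstrap standard deviations, so the
    poorly observed ends of a run are naturally down-weighted.  Returns a
    dict with ``theta``, ``objective``, ``success`` (non-convergence is
    flagged, not raised).
    """
    from scipy.optimize import least_squares

    times = np.asarray(times, dtype=float)
    rates = np.asarray(rates, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    theta0 = np.asarray(theta0, dtype=float)
    if times.size < theta0.size:
        raise ValueError("need at least as many time points as parameters")
    if not np.all(np.isfinite(sigmas)) or np.any(sigmas <= 0):
        raise ValueError("sigmas must be finite and positive")

    def residuals(theta):
        return (rate_function(times, theta) - rates) / sigmas

    kw = dict(xtol=1e-12, ftol=1e-12, gtol=1e-12)
    kw.update(least_squares_kw)
    if bounds is not None:
        kw["bounds"] = bounds
    res = least_squares(residuals, theta0, **kw)
    return {"theta": res.x, "objective": float(2 * res.cost),
            "success": bool(res.success), "message": res.message}
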