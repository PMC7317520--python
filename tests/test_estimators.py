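"""The four DMFA solver modes and their contracts."""

import numpy as np
import pytest

import dmfa
from dmfa.design import InflectionGrid, design_matrix
from dmfa.estimators import (DMFA, compute_ssr, cross_validate_alpha,
                             fit_kinetics, specific_rates)
from dmfa.measurements import MeasurementSet
from dmfa.solvers import SolverError, lstsq_free


def _toy_data(values, sigmas, times=None, species=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if times is None:
        times = np.arange(values.shape[1], dtype=float)
    if species is None:
        species = [f"S{i + 1}" for i in range(values.shape[0])]
    return MeasurementSet(times=times, species_ids=species, values=values,
                          sigmas=np.broadcast_to(
                              np.asarray(sigmas, dtype=float),
                              values.shape).copy(), xv_id=None)


# -- SSR -------------------------------------------------------------

def test_ssr_zero_iff_perfect_fit():
    data = _toy_data([[1.0, 2.0, 3.0]], 0.5)
    assert compute_ssr(data, data.values) == 0.0


def test_ssr_unit_standardized_residuals():
    data = _toy_data(np.ones((2, 3)), 0.25)
    fitted = data.values + 0.25
    assert compute_ssr(data, fitted) == pytest.approx(6.0)


def test_ssr_hand_computed():
    data = _toy_data([[1.0, 2.0, 4.0], [0.0, 1.0, 2.0]],
                     [[1.0, 0.5, 2.0], [1.0, 1.0, 0.5]])
    fitted = np.array([[1.5, 2.0, 3.0], [0.0, 0.0, 1.0]])
    # residual/sigma: 0.5, 0, 0.5 ; 0, 1, 2
    assert compute_ssr(data, fitted) == pytest.approx(0.25 + 0.25 + 1 + 4)


def test_ssr_masked_points_excluded():
    data = _toy_data([[1.0, np.nan, 3.0]], 1.0)
    fitted = np.array([[1.0, 99.0, 3.0]])
    assert compute_ssr(data, fitted) == 0.0


# -- recovery and oracles --------------------------------------------

def _network_truth_case(n_nodes=4, seed=0):
    """Noise-free data generated from U node values strictly inside the
    irreversibility cone of the demo network."""
    net = dmfa.demo_network()
    basis = net.null_space_basis()
    grid = InflectionGrid.from_span(0.0, 24.0, n_nodes)
    rng = np.random.default_rng(seed)
    # draw V in the strict interior of the flux cone via positive EM weights
    ems = dmfa.enumerate_ems(net)
    W = rng.uniform(0.5, 1.5, size=(ems.n_modes, n_nodes))
    V_nodes = ems.flux_patterns @ W          # (n_rxn, n_nodes), feasible
    U_true, *_ = np.linalg.lstsq(basis.K, V_nodes, rcond=None)
    assert np.abs(basis.K @ U_true - V_nodes).max() < 1e-10
    times = np.linspace(0.0, 24.0, 9)
    D = net.P @ basis.K
    A = design_matrix(D, grid, times)
    c0 = np.full(len(net.external_ids), 50.0)
    c = c0[:, None] + (A @ U_true.ravel()).reshape(len(net.external_ids),
                                                   times.size)
    data = MeasurementSet(times=times, species_ids=net.external_ids,
                          values=c, sigmas=np.full_like(c, 0.05), xv_id="Xv")
    return net, grid, U_true, c0, data


def test_unbounded_recovers_truth_in_model_class():
    net, grid, U_true, c0, data = _network_truth_case()
    fit = DMFA(mode="unbounded", grid=grid).fit(data, network=net)
    assert np.abs(fit.node_values_ - U_true).max() \
        <= 1e-8 * max(1.0, np.abs(U_true).max())
    assert np.abs(fit.c0_ - c0).max() < 1e-7
    assert fit.ssr_ < 1e-12


def test_bounded_inactive_constraints_match_unbounded():
    net, grid, U_true, c0, data = _network_truth_case(seed=3)
    fu = DMFA(mode="unbounded", grid=grid).fit(data, network=net)
    fb = DMFA(mode="bounded", grid=grid).fit(data, network=net)
    assert np.abs(fu.node_values_ - fb.node_values_).max() < 1e-8


def test_unbounded_matches_normal_equations_oracle():
    net, grid, *_ , data = _network_truth_case(seed=5)
    noisy = data.copy()
    rng = np.random.default_rng(11)
    noisy.values = noisy.values + rng.normal(scale=0.3, size=noisy.values.shape)
    fit = DMFA(mode="unbounded", grid=grid).fit(noisy, network=net)
    # oracle: explicit weighted normal equations on the same design
    basis = net.null_space_basis()
    D = net.P @ basis.K
    A_flux = design_matrix(D, grid, noisy.times)
    w = (1.0 / noisy.sigmas).ravel()
    n_s = len(noisy.species_ids)
    C0 = np.repeat(np.eye(n_s), noisy.times.size, axis=0)
    A = np.hstack([C0, A_flux]) * w[:, None]
    b = noisy.values.ravel() * w
    x = np.linalg.solve(A.T @ A, A.T @ b)
    ours = np.concatenate([fit.c0_, fit.node_values_.ravel()])
    assert np.abs(ours - x).max() <= 1e-9 * max(1.0, np.abs(x).max())


def test_bounded_active_constraint_matches_grid_search_oracle():
    # one external species consumed by one irreversible reaction; data
    # drawn so the unconstrained slope estimate would be negative
    from dmfa.network import MetabolicNetwork, Reaction, Species

    net = MetabolicNetwork(
        species=[Species("A", "external")],
        reactions=[Reaction("r1", {"A": 1.0})])   # production only
    grid = InflectionGrid(np.array([0.0, 10.0]))
    times = np.linspace(0.0, 10.0, 6)
    values = np.array([[5.0, 4.8, 4.9, 4.7, 4.75, 4.6]])  # drifting down
    data = MeasurementSet(times=times, species_ids=["A"],
                          values=values, sigmas=np.full_like(values, 0.1),
                          xv_id=None)
    fu = DMFA(mode="unbounded", grid=grid).fit(data, network=net)
    assert fu.node_values_.min() < 0          # truly active constraint
    fb = DMFA(mode="bounded", grid=grid).fit(data, network=net)
    assert fb.node_values_.min() >= -1e-9
    # oracle: dense grid search over (U1, U2) >= 0 and free c0
    best = (np.inf, None)
    A_flux = design_matrix(np.array([[1.0]]), grid, times)
    for u1 in np.linspace(0, 0.2, 81):
        for u2 in np.linspace(0, 0.2, 81):
            pred = A_flux @ np.array([u1, u2])
            c0 = np.mean(values[0] - pred)    # optimal free intercept
            ssr = np.sum(((values[0] - c0 - pred) / 0.1) ** 2)
            if ssr < best[0]:
                best = (ssr, (u1, u2))
    assert fb.ssr_ <= best[0] + 1e-4
    assert np.abs(np.array(best[1]) - fb.node_values_.ravel()).max() < 5e-3


def test_all_zero_data_gives_zero_flux_optimum(pwl):
    data = pwl.sample(np.random.default_rng(0))
    data.values[:] = 0.0
    data.sigmas[:] = 1.0
    fit = DMFA(mode="em", grid=pwl.grid, estimate_c0=False).fit(data,
                                                                ems=pwl.ems)
    assert np.abs(fit.node_values_).max() <= 1e-9
    assert fit.ssr_ == pytest.approx(0.0, abs=1e-12)


def test_em_modes_recover_truth(pwl):
    data = pwl.sample(np.random.default_rng(0))
    data.values = pwl.true_concentrations()          # noise-free
    for mode, alpha in (("em", 0.0), ("em_regularized", 1e-10)):
        fit = DMFA(mode=mode, grid=pwl.grid, alpha=alpha).fit(
            data, ems=pwl.ems, xv_interp=pwl.xv_interp)
        rel = np.abs(fit.node_values_ - pwl.node_values) / \
            max(1.0, np.abs(pwl.node_values).max())
        assert rel.max() < 1e-6


def test_nested_grid_monotonicity(simple_case):
    data, net = simple_case["data"], dmfa.demo_network(
        reversible_lactate=False)
    coarse = InflectionGrid(np.array([0.0, 20.0, 40.0, 60.0]))
    fine = InflectionGrid(np.array([0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0]))
    s_coarse = DMFA(mode="unbounded", grid=coarse).fit(data, network=net).ssr_
    s_fine = DMFA(mode="unbounded", grid=fine).fit(data, network=net).ssr_
    assert s_fine <= s_coarse + 1e-9


def test_ssr_hierarchy(simple_case):
    """unbounded <= bounded = em(full) <= em(subset) <= em(subset, alpha>0)."""
    data, grid = simple_case["data"], simple_case["grid"]
    scen = simple_case["scenario"]
    net = dmfa.demo_network(reversible_lactate=False)
    xv = data.xv_interpolant()
    s_un = DMFA(mode="unbounded", grid=grid).fit(data, network=net).ssr_
    s_bd = DMFA(mode="bounded", grid=grid).fit(data, network=net).ssr_
    s_em = DMFA(mode="em", grid=grid).fit(data, ems=scen.ems).ssr_
    sub = scen.ems.subset(np.array([0, 1, 2]))
    s_sub = DMFA(mode="em", grid=grid).fit(data, ems=sub).ssr_
    s_reg = DMFA(mode="em_regularized", grid=grid, alpha=10.0).fit(
        data, ems=sub, xv_interp=xv).ssr_
    tol = 1e-6
    assert s_un <= s_bd * (1 + tol)
    assert abs(s_bd - s_em) <= tol * s_bd
    assert s_em <= s_sub * (1 + tol)
    assert s_sub <= s_reg * (1 + tol)


def test_basis_invariance_of_fitted_curves_and_ssr(simple_case):
    """Fits are invariant under rotation of the null-space basis."""
    data, grid = simple_case["data"], simple_case["grid"]
    net = dmfa.demo_network(reversible_lactate=False)
    basis = net.null_space_basis()
    rng = np.random.default_rng(9)
    Q, _ = np.linalg.qr(rng.normal(size=(basis.K.shape[1],) * 2))
    idx = [data.species_index(s) for s in net.external_ids]
    w = 1.0 / data.sigmas[idx]
    b = (data.values[idx] * w).ravel()
    results = []
    for K in (basis.K, basis.K @ Q):
        D = net.P @ K
        A_flux = design_matrix(D, grid, data.times)
        n_s = len(net.external_ids)
        C0 = np.repeat(np.eye(n_s), data.times.size, axis=0)
        A = np.hstack([C0, A_flux]) * w.ravel()[:, None]
        x = lstsq_free(A, b)
        results.append((A @ x, float(np.sum((b - A @ x) ** 2))))
    assert np.abs(results[0][0] - results[1][0]).max() < 1e-8
    assert results[0][1] == pytest.approx(results[1][1], rel=1e-8)


def test_kkt_conditions_on_bounded_and_em_solutions(pwl):
    """Stationarity, primal feasibility and complementary slackness."""
    rng = np.random.default_rng(4)
    data = pwl.sample(rng)
    fit = DMFA(mode="em", grid=pwl.grid).fit(data, ems=pwl.ems)
    # rebuild the weighted system to evaluate the KKT residuals
    A_flux = design_matrix(pwl.ems.E, pwl.grid, data.times)
    w = (1.0 / data.sigmas).ravel()
    n_s = len(data.species_ids)
    C0 = np.repeat(np.eye(n_s), data.times.size, axis=0)
    A = np.hstack([C0, A_flux]) * w[:, None]
    b = data.values.ravel() * w
    x = np.concatenate([fit.c0_, fit.node_values_.ravel()])
    g = 2 * A.T @ (A @ x - b)                 # objective gradient
    scale = max(1.0, np.abs(g).max(), np.abs(b).max())
    R = fit.node_values_.ravel()
    assert R.min() >= -1e-9                                  # primal
    assert np.abs(g[:n_s]).max() <= 1e-8 * scale             # free block
    mu = g[n_s:]                             # multiplier of R >= 0
    assert mu.min() >= -1e-8 * scale                         # dual
    assert np.abs(mu * R).max() <= 1e-8 * scale              # slackness


def test_rank_deficient_unbounded_errors_without_fallback():
    data = _toy_data([[1.0, 2.0]], 1.0, times=np.array([0.0, 1.0]))
    from dmfa.network import MetabolicNetwork, Reaction, Species

    net = MetabolicNetwork(
        species=[Species("S1", "external")],
        reactions=[Reaction("r1", {"S1": 1.0}),
                   Reaction("r2", {"S1": 2.0})])
    grid = InflectionGrid(np.array([0.0, 1.0]))
    with pytest.raises(SolverError):
        DMFA(mode="unbounded", grid=grid).fit(data, network=net)
    fit = DMFA(mode="unbounded", grid=grid, allow_deficient=True).fit(
        data, network=net)
    assert np.isfinite(fit.ssr_)


# -- specific rates ---------------------------------------------------

def test_specific_rates_pointwise_ratio(pwl):
    data = pwl.sample(np.random.default_rng(2))
    fit = DMFA(mode="em", grid=pwl.grid).fit(data, ems=pwl.ems)
    t = np.linspace(0.0, 48.0, 11)
    r = specific_rates(fit, pwl.xv_interp, t)
    oracle = fit.volumetric_fluxes(t) / pwl.xv_interp(t)
    assert np.abs(r - oracle).max() < 1e-12
    # unit bookkeeping hook
    r_conv = specific_rates(fit, pwl.xv_interp, t, volume_factor=1e-3)
    assert np.allclose(r_conv, 1e-3 * r)


def test_specific_rates_rejects_nonpositive_xv(pwl):
    data = pwl.sample(np.random.default_rng(2))
    fit = DMFA(mode="em", grid=pwl.grid).fit(data, ems=pwl.ems)
    with pytest.raises(ValueError, match="Xv"):
        specific_rates(fit, lambda t: np.zeros_like(np.asarray(t)), [1.0])


# -- cross-validation -------------------------------------------------

def test_cv_prefers_regularization_for_collinear_ems(pwl):
    from dmfa.elementary import ElementaryModeMatrix

    E_dup = np.column_stack([pwl.ems.E, pwl.ems.E[:, [0]]])
    ems_dup = ElementaryModeMatrix(E=E_dup, species_ids=pwl.ems.species_ids,
                                   em_ids=[f"d{k}" for k in range(5)])
    data = pwl.sample(np.random.default_rng(8))
    alpha, table = cross_validate_alpha(
        data, ems_dup, grid=pwl.grid, alphas=(0.0, 1e-3, 1e-1),
        folds=3, seed=1, xv_interp=pwl.xv_interp)
    assert alpha > 0
    assert set(table.columns) >= {"alpha", "mean_heldout_ssr"}


def test_cv_near_noiseless_wellconditioned_picks_smallest_alpha(pwl):
    data = pwl.sample(np.random.default_rng(8))
    data.values = pwl.true_concentrations() + 1e-9
    alpha, _ = cross_validate_alpha(
        data, pwl.ems, grid=pwl.grid, alphas=(1e-8, 1e-2, 1.0),
        folds=3, seed=1, xv_interp=pwl.xv_interp)
    assert alpha == 1e-8


def test_cv_deterministic_given_seed(pwl):
    data = pwl.sample(np.random.default_rng(8))
    out1 = cross_validate_alpha(data, pwl.ems, grid=pwl.grid,
                                alphas=(0.0, 1e-2), folds=3, seed=42,
                                xv_interp=pwl.xv_interp)
    out2 = cross_validate_alpha(data, pwl.ems, grid=pwl.grid,
                                alphas=(0.0, 1e-2), folds=3, seed=42,
                                xv_interp=pwl.xv_interp)
    assert out1[0] == out2[0]
    assert out1[1].equals(out2[1])


# -- kinetics ---------------------------------------------------------

def test_fit_kinetics_linear_exact():
    t = np.linspace(0, 10, 8)
    r = 2.0 * t + 1.0
    res = fit_kinetics(lambda tt, th: th[0] * tt + th[1], [0.5, 0.0],
                       t, r, np.ones_like(t))
    assert res["success"]
    assert np.abs(res["theta"] - [2.0, 1.0]).max() < 1e-8


def test_fit_kinetics_monod_recovery():
    c = np.linspace(0.2, 12.0, 15)
    theta_true = (0.9, 1.7)
    r = theta_true[0] * c / (theta_true[1] + c)
    res = fit_kinetics(lambda cc, th: th[0] * cc / (th[1] + cc), [0.5, 1.0],
                       c, r, np.full_like(c, 1e-3),
                       bounds=([0.0, 0.0], [10.0, 10.0]))
    assert np.abs(res["theta"] - theta_true).max() / max(theta_true) < 1e-4


def test_fit_kinetics_weighting_shifts_fit():
    t = np.linspace(0, 10, 12)
    r = np.where(t < 5, 1.0, 2.0)       # step the model cannot match
    flat = fit_kinetics(lambda tt, th: th[0] * np.ones_like(tt), [1.0],
                        t, r, np.ones_like(t))
    late = fit_kinetics(lambda tt, th: th[0] * np.ones_like(tt), [1.0],
                        t, r, np.where(t < 5, 100.0, 1.0))
    assert late["theta"][0] > flat["theta"][0]
    assert late["theta"][0] == pytest.approx(2.0, abs=1e-3)
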