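"""Fed-batch simulator, noise sampling, pseudo-batch shift, baselines."""

import numpy as np
import pytest
from scipy.integrate import cumulative_simpson

import dmfa
from dmfa.elementary import ElementaryModeMatrix, normalize_columns
from dmfa.measurements import NoiseModel
from dmfa.synthetic import (SimulationScenario, em_rates_from_fluxes,
                            estimate_specific_fluxes, pseudo_batch_shift,
                            sample_measurements, simulate)


def _single_mode_scenario(rate=0.5, xv0=1.0, t_end=10.0):
    """One EM converting A to B at a constant specific rate; no growth."""
    E = normalize_columns(np.array([[-1.0], [1.0], [0.0]]))
    ems = ElementaryModeMatrix(E=E, species_ids=["A", "B", "Xv"],
                               em_ids=["M1"])
    return SimulationScenario(
        ems=ems, kinetics={"M1": lambda c: rate},
        initial_concentrations={"A": 20.0, "B": 0.0, "Xv": xv0},
        t_span=(0.0, t_end), sample_times=np.linspace(0.0, t_end, 6))


def test_zero_kinetics_zero_feed_constant_concentrations():
    scen = _single_mode_scenario(rate=0.0)
    res = simulate(scen)
    C = res.concentrations(np.linspace(0, 10, 7))
    assert np.abs(C - C[:, [0]]).max() < 1e-9


def test_constant_rate_batch_matches_closed_form():
    scen = _single_mode_scenario(rate=0.5, xv0=2.0)
    res = simulate(scen)
    t = np.linspace(0, 10, 11)
    C = res.concentrations(t)
    slope = 0.5 * 2.0 / np.sqrt(2.0)       # rate * Xv * |E| coefficient
    assert np.abs(C[0] - (20.0 - slope * t)).max() < 1e-6
    assert np.abs(C[1] - slope * t).max() < 1e-6


def test_conserved_moiety_drift_is_negligible():
    """Weights from the left null space of E give a conserved quantity."""
    scen = dmfa.simple_scenario(seed=0)
    res = simulate(scen)
    cols = [scen.ems.em_ids.index(e) for e in res.active_em_ids]
    E = scen.ems.E[:, cols]
    # left null vector of the active macro-reaction matrix
    _, s, Vt = np.linalg.svd(E.T)
    w = Vt[-1]
    assert np.abs(E.T @ w).max() < 1e-12
    t = np.linspace(0, 60, 31)
    q = w @ res.concentrations(t)
    assert np.abs(q - q[0]).max() <= 1e-6 * max(1.0, abs(q[0]))


def test_negative_concentration_aborts():
    scen = _single_mode_scenario(rate=0.5, xv0=2.0, t_end=40.0)
    with pytest.raises(RuntimeError, match="negative"):
        simulate(scen)       # A hits zero near t = 28


def test_sampling_noise_free_and_deterministic():
    scen = _single_mode_scenario()
    res = simulate(scen)
    clean = sample_measurements(res, noise_model=NoiseModel(default=(0, 0)),
                                rng=np.random.default_rng(0))
    t = scen.sample_times
    assert np.abs(clean.values - res.concentrations(t)).max() < 1e-12
    m = NoiseModel.from_ci95_fraction(0.05)
    assert m.default[1] == pytest.approx(0.05 / 1.96)
    a = sample_measurements(res, noise_model=m, rng=np.random.default_rng(4))
    b = sample_measurements(res, noise_model=m, rng=np.random.default_rng(4))
    assert np.array_equal(a.values, b.values)


# -- pseudo-batch correction -----------------------------------------

def test_shift_zero_feed_identity(pwl):
    data = pwl.sample(np.random.default_rng(0))
    out = pseudo_batch_shift(data, None, {}, initial_volume=500.0)
    assert np.abs(out.values - data.values).max() < 1e-12


def test_shift_pure_water_feed_rescales_amounts(pwl):
    data = pwl.sample(np.random.default_rng(0))
    out = pseudo_batch_shift(data, lambda t: 10.0, {}, initial_volume=1000.0)
    V = 1000.0 + 10.0 * data.times
    expected = data.values * V / 1000.0
    assert np.abs(out.values - expected).max() < 1e-9 * np.abs(expected).max()


def test_shift_roundtrip_against_quadrature_oracle():
    """Shifted fed-batch data equal the batch-equivalent trajectory
    (per-reference-volume amounts driven by the same volumetric rates)."""
    scen = dmfa.default_scenario(seed=0)
    res = simulate(scen, rtol=1e-10, atol=1e-12)
    t = np.linspace(0.0, 120.0, 25)
    data = sample_measurements(res, t, NoiseModel(default=(0.0, 0.0)),
                               np.random.default_rng(0))
    shifted = pseudo_batch_shift(data, scen.feed_rate,
                                 scen.feed_concentrations,
                                 initial_volume=scen.initial_volume,
                                 n_quad=4801)
    tq = np.linspace(0.0, 120.0, 4801)       # contains t exactly
    V = res.volume(tq)
    cols = [scen.ems.em_ids.index(e) for e in res.active_em_ids]
    E = scen.ems.E[:, cols]
    integ = cumulative_simpson(E @ res.volumetric_rates(tq) * V, x=tq,
                               initial=0.0)
    c0 = res.concentrations(np.array([0.0]))[:, 0]
    oracle = (c0[:, None] * scen.initial_volume + integ) / scen.initial_volume
    oracle_t = oracle[:, np.searchsorted(tq, t)]
    rel = np.abs(shifted.values - oracle_t) / np.maximum(1.0, np.abs(oracle_t))
    assert rel.max() < 1e-6


def test_shift_missing_feed_composition_errors(pwl):
    data = pwl.sample(np.random.default_rng(0))
    with pytest.raises(ValueError, match="feed"):
        pseudo_batch_shift(data, None, {"S1": 100.0}, initial_volume=1000.0)


# -- rate-based estimators -------------------------------------------

@pytest.mark.parametrize("method", ["splines", "smoothing_splines",
                                    "ma_filter", "raw"])
def test_linear_concentrations_give_constant_rate(method):
    t = np.linspace(0, 10, 11)
    values = np.vstack([20.0 - 1.5 * t, np.full_like(t, 4.0)])
    data = dmfa.MeasurementSet(times=t, species_ids=["A", "Xv"],
                               values=values,
                               sigmas=np.full_like(values, 0.1), xv_id="Xv")
    est = estimate_specific_fluxes(data, method=method)
    assert np.abs(est.q[0] - (-1.5 / 4.0)).max() < 1e-8


def test_spline_derivative_close_to_central_differences():
    t = np.linspace(0, 10, 21)
    y = np.exp(0.2 * t)
    data = dmfa.MeasurementSet(times=t, species_ids=["A", "Xv"],
                               values=np.vstack([y, np.ones_like(t)]),
                               sigmas=np.full((2, t.size), 0.1), xv_id="Xv")
    spl = estimate_specific_fluxes(data, method="splines")
    fd = np.gradient(y, t)
    interior = slice(2, -2)
    rel = np.abs(spl.q[0][interior] - fd[interior]) / np.abs(fd[interior])
    assert rel.max() < 1e-3 * 10   # central differences are themselves O(h^2)


def test_smoothing_reduces_rate_variance_on_noisy_data():
    rng = np.random.default_rng(0)
    t = np.linspace(0, 10, 21)
    truth = 20.0 - 1.0 * t
    var_raw, var_smooth = [], []
    for _ in range(10):
        y = truth + rng.normal(scale=0.4, size=t.size)
        data = dmfa.MeasurementSet(times=t, species_ids=["A", "Xv"],
                                   values=np.vstack([y, np.ones_like(t)]),
                                   sigmas=np.full((2, t.size), 0.4),
                                   xv_id="Xv")
        raw = estimate_specific_fluxes(data, method="splines").q[0]
        smooth = estimate_specific_fluxes(data,
                                          method="smoothing_splines").q[0]
        var_raw.append(np.var(raw - (-1.0)))
        var_smooth.append(np.var(smooth - (-1.0)))
    assert np.mean(var_raw) >= 2 * np.mean(var_smooth)


def test_nnls_em_rates_exact_recovery(pwl):
    rng = np.random.default_rng(3)
    r_true = rng.uniform(0.1, 1.0, size=(4, 7))
    q = pwl.ems.E @ r_true
    r = em_rates_from_fluxes(q, pwl.ems.E)
    assert np.abs(r - r_true).max() < 1e-8


def test_nnls_sign_infeasible_gives_zero():
    E = normalize_columns(np.array([[-1.0], [1.0]]))
    q = -E            # exactly opposite to the only mode
    r = em_rates_from_fluxes(q, E)
    assert np.abs(r).max() == 0.0


def test_windowed_nnls_is_smoother_than_pointwise(pwl):
    rng = np.random.default_rng(5)
    r_true = np.tile(rng.uniform(0.2, 1.0, size=(4, 1)), (1, 9))
    q = pwl.ems.E @ r_true + rng.normal(scale=0.1, size=(4, 9))
    point = em_rates_from_fluxes(q, pwl.ems.E)
    windowed = em_rates_from_fluxes(q, pwl.ems.E, window=5)
    assert np.var(windowed - r_true) < np.var(point - r_true)


def test_benchmark_reproducible_for_seed():
    scen = dmfa.simple_scenario(seed=0)
    kw = dict(noise_levels=(0.05,), n_replicates=2, seed=13,
              methods=["rate_splines", "rate_ma_filter"])
    s1, p1 = dmfa.benchmark(scen, **kw)
    s2, p2 = dmfa.benchmark(scen, **kw)
    assert p1.equals(p2)
    assert s1.equals(s2)


def test_benchmark_error_grows_with_noise():
    scen = dmfa.simple_scenario(seed=0)
    summary, _ = dmfa.benchmark(scen, noise_levels=(0.01, 0.10),
                                n_replicates=5, seed=17,
                                methods=["rate_splines"])
    assert summary.loc["rate_splines", 0.10] > summary.loc["rate_splines",
                                                           0.01]
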