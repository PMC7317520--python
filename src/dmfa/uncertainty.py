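"""Bootstrap confidence bounds for DMFA estimates.

Analytic (Fisher-information) intervals are unreliable here: many node
parameters, some barely observable, and active inequality constraints.
Instead, measurements are resampled from their assumed Gaussian error
model, the inflection-point positions are jittered to remove the bias
tied to one particular grid, and the chosen solver is re-run; empirical
percentiles of the re-estimates give the confidence bands.  The
regularization weight is kept at zero (plus an optional tiny
conditioning ridge) so the bands are not shrunk artificially.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import InflectionGrid
from .estimators import DMFA, specific_rates
from .measurements import MeasurementSet, NoiseModel, sigma_of

__all__ = ["resample_measurements", "randomize_grid", "bootstrap",
           "BootstrapEnsemble"]


def resample_measurements(data: MeasurementSet, model: NoiseModel,
                          rng: np.random.Generator) -> MeasurementSet:
    """Gaussian redraw of every observed value; sigma columns are set to
    the model values.  Negative draws are clipped at zero (count kept in
    ``out.n_clipped``)."""
    out = data.copy()
    n_clipped = 0
    for i, sid in enumerate(data.species_ids):
        obs = data.mask[i]
        if not obs.any():
            continue
        c = data.values[i, obs]
        sig = sigma_of(np.maximum(c, 0.0), model, sid)
        draw = c + rng.standard_normal(c.size) * sig
        n_clipped += int(np.sum(draw < 0))
        out.values[i, obs] = np.maximum(draw, 0.0)
        out.sigmas[i, obs] = np.maximum(sig, np.finfo(float).tiny)
    out.n_clipped = n_clipped
    return out


def randomize_grid(grid: InflectionGrid, rng: np.random.Generator,
                   jitter_fraction: float = 0.5) -> InflectionGrid:
    """Jitter interior nodes by uniform draws within +/- jitter_fraction
    of the smaller adjacent spacing; endpoints stay fixed and strict
    ordering is preserved by construction."""
    if not 0.0 <= jitter_fraction <= 0.5:
        raise ValueError("jitter_fraction must be in [0, 0.5]")
    T = grid.nodes.copy()
    if jitter_fraction == 0.0 or T.size <= 2:
        return InflectionGrid(T)
    gaps = np.diff(grid.nodes)
    for j in range(1, T.size - 1):
        half = jitter_fraction * min(gaps[j - 1], gaps[j])
        T[j] = grid.nodes[j] + rng.uniform(-half, half)
    return InflectionGrid(T)


@dataclass
class BootstrapEnsemble:
    """Per-quantity percentile bands over bootstrap re-estimates.

    ``bands[quantity]`` is a DataFrame indexed by evaluation time with
    columns median, lo68, hi68, lo95, hi95; quantities are
    ``c:<species>``, ``R:<label>`` and (when Xv is available)
    ``r:<label>``.
    """

    n_samples: int
    n_failed: int
    eval_times: np.ndarray
    bands: dict = field(default_factory=dict)
    samples: dict = field(default_factory=dict)  # quantity -> (n_ok, n_t)

    def band_table(self, quantity: str) -> pd.DataFrame:
        return self.bands[quantity]


def _percentile_bands(arr: np.ndarray, times) -> pd.DataFrame:
    q = np.percentile(arr, [50, 16, 84, 2.5, 97.5], axis=0)
    return pd.DataFrame(
        {"median": q[0], "lo68": q[1], "hi68": q[2], "lo95": q[3],
         "hi95": q[4]}, index=np.asarray(times))


def bootstrap(data: MeasurementSet, *, network=None, ems=None,
              grid: InflectionGrid | None = None,
              noise_model: NoiseModel | None = None,
              n_samples: int = 500, mode: str = "em",
              alpha_boot: float = 0.0, jitter_fraction: float = 0.5,
              seed: int = 0, eval_times=None, xv_interp=None,
              conditioning_ridge: float = 0.0,
              volume_factor: float = 1.0,
              max_failure_fraction: float = 0.2) -> BootstrapEnsemble:
    """Resample-and-refit ensemble with percentile confidence bands.

    The default sample count is 500; ``alpha_boot`` defaults to 0 so the
    ensemble spread is not biased by regularization (a small
    ``conditioning_ridge`` may be supplied for degenerate EM sets).
    Reproducible for a given ``seed`` regardless of execution order: each
    sample draws from an independent spawned substream.
    """
    if n_samples < 2:
        raise ValueError("need n_samples >= 2")
    if mode not in ("unbounded", "bounded", "em", "em_regularized"):
        raise ValueError(f"unknown mode {mode!r}")
    if noise_model is None:
        noise_model = NoiseModel()
    grid = grid or InflectionGrid.from_span(data.times.min(), data.times.max())
    if eval_times is None:
        eval_times = np.linspace(data.times.min(), data.times.max(), 25)
    eval_times = np.asarray(eval_times, dtype=float)
    if xv_interp is None and data.xv_id in data.species_ids:
        xv_interp = data.xv_interpolant()

    em_mode = mode in ("em", "em_regularized")
    labels = list(ems.em_ids) if em_mode else list(network.reaction_ids)

    streams = np.random.SeedSequence(seed).spawn(n_samples)
    conc, rates, spec = [], [], []
    n_failed = 0
    for ss in streams:
        rng = np.random.default_rng(ss)
        sample = resample_measurements(data, noise_model, rng)
        g = randomize_grid(grid, rng, jitter_fraction)
        try:
            est = DMFA(mode=mode if alpha_boot == 0 or not em_mode
                       else "em_regularized",
                       grid=g, alpha=alpha_boot if em_mode else 0.0,
                       conditioning_ridge=conditioning_ridge)
            est.fit(sample, network=network, ems=ems, xv_interp=xv_interp)
            conc.append(est._predict_on(eval_times))
            rates.append(est.volumetric_fluxes(eval_times))
            if xv_interp is not None:
                spec.append(specific_rates(est, xv_interp, eval_times,
                                           volume_factor=volume_factor))
            fitted_species = est.species_ids_
        except Exception:
            n_failed += 1
    n_ok = n_samples - n_failed
    if n_failed > max_failure_fraction * n_samples or n_ok < 2:
        raise RuntimeError(
            f"{n_failed}/{n_samples} bootstrap solves failed; "
            "model and data are inconsistent")

    ens = BootstrapEnsemble(n_samples=n_samples, n_failed=n_failed,
                            eval_times=eval_times)
    conc = np.array(conc)          # (n_ok, n_s, n_t)
    rates = np.array(rates)        # (n_ok, n_dir, n_t)
    for i, sid in enumerate(fitted_species):
        ens.bands[f"c:{sid}"] = _percentile_bands(conc[:, i], eval_times)
        ens.samples[f"c:{sid}"] = conc[:, i]
    for k, lab in enumerate(labels):
        ens.bands[f"R:{lab}"] = _percentile_bands(rates[:, k], eval_times)
        ens.samples[f"R:{lab}"] = rates[:, k]
    if spec:
        spec = np.array(spec)
        for k, lab in enumerate(labels):
            ens.bands[f"r:{lab}"] = _percentile_bands(spec[:, k], eval_times)
            ens.samples[f"r:{lab}"] = spec[:, k]
    return ens
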