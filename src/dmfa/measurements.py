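"""Concentration time-series container and the linear noise model.

Measurements are concentrations of medium species (mM) and the viable
cell density Xv (10^6 cells/ml) on a shared, non-decreasing time axis
(hours), each point carrying its standard uncertainty sigma.  Missing
points are NaN and are masked out of all residual sums.

The noise model is linear in the signal, ``sigma_i(t) = a_i + b_i*c_i(t)``,
the form typically estimated from assay replicates.  The convention
"95% confidence interval equals p% of the magnitude" maps to
``b = p/100/1.96`` with ``a = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MeasurementSet", "NoiseModel", "sigma_of",
           "read_measurements", "write_measurements"]


class MeasurementError(ValueError):
    pass


@dataclass
class MeasurementSet:
    """Wide-layout measurements: one row per species, one column per time."""

    times: np.ndarray                  # (n_t,)
    species_ids: list                  # length n_s
    values: np.ndarray                 # (n_s, n_t), NaN = missing
    sigmas: np.ndarray                 # (n_s, n_t), >0 where observed
    xv_id: str | None = "Xv"           # which species is viable-cell density

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.sigmas = np.atleast_2d(np.asarray(self.sigmas, dtype=float))
        if np.any(np.diff(self.times) < 0):
            raise MeasurementError("times must be non-decreasing")
        if self.values.shape != (len(self.species_ids), self.times.size):
            raise MeasurementError("values shape mismatch")
        if self.sigmas.shape != self.values.shape:
            raise MeasurementError("sigmas shape mismatch")
        obs = ~np.isnan(self.values)
        if np.any(self.sigmas[obs] <= 0) or np.any(np.isnan(self.sigmas[obs])):
            raise MeasurementError("sigma must be > 0 at every observed point")

    @property
    def mask(self) -> np.ndarray:
        """True where a value is observed."""
        return ~np.isnan(self.values)

    @property
    def n_observed(self) -> int:
        return int(self.mask.sum())

    def species_index(self, sid: str) -> int:
        try:
            return self.species_ids.index(sid)
        except ValueError:
            raise MeasurementError(f"species {sid!r} not in measurement set")

    def xv_interpolant(self):
        """Linear interpolant of the measured viable-cell series."""
        if self.xv_id is None or self.xv_id not in self.species_ids:
            raise MeasurementError("no viable-cell (Xv) series in this set")
        i = self.species_index(self.xv_id)
        obs = self.mask[i]
        t, x = self.times[obs], self.values[i, obs]
        if t.size < 2:
            raise MeasurementError("need >= 2 Xv points to interpolate")

        def interp(tq):
            return np.interp(np.asarray(tq, dtype=float), t, x)

        return interp

    def without_species(self, sids) -> "MeasurementSet":
        keep = [i for i, s in enumerate(self.species_ids) if s not in set(sids)]
        return MeasurementSet(
            times=self.times.copy(),
            species_ids=[self.species_ids[i] for i in keep],
            values=self.values[keep].copy(),
            sigmas=self.sigmas[keep].copy(),
            xv_id=self.xv_id if self.xv_id not in set(sids) else None,
        )

    def copy(self) -> "MeasurementSet":
        return MeasurementSet(times=self.times.copy(),
                              species_ids=list(self.species_ids),
                              values=self.values.copy(),
                              sigmas=self.sigmas.copy(),
                              xv_id=self.xv_id)


@dataclass
class NoiseModel:
    """Per-species sigma(c) = a + b*c; species not listed fall back to
    the ``default`` pair."""

    a: dict = field(default_factory=dict)
    b: dict = field(default_factory=dict)
    default: tuple = (0.0, 0.05 / 1.96)

    def params(self, species: str) -> tuple:
        a = self.a.get(species, self.default[0])
        b = self.b.get(species, self.default[1])
        if a < 0 or b < 0:
            raise MeasurementError(
                f"noise model for {species!r} needs a >= 0 and b >= 0")
        return a, b

    @classmethod
    def from_ci95_fraction(cls, fraction: float) -> "NoiseModel":
        """Model where the 95% CI spans ``fraction`` of the magnitude."""
        return cls(default=(0.0, fraction / 1.96))


def sigma_of(c, model: NoiseModel, species: str):
    """Standard uncertainty of a concentration under the linear model."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise MeasurementError("negative concentration passed to sigma_of")
    a, b = model.params(species)
    return a + b * c


# ---------------------------------------------------------------------
# long-format delimited i/o: columns time, species, value, sigma
# ---------------------------------------------------------------------

def read_measurements(path, xv_id: str | None = "Xv",
                      noise_model: NoiseModel | None = None) -> MeasurementSet:
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"time", "species", "value"}
    if not required <= set(df.columns):
        raise MeasurementError(f"measurement file needs columns {sorted(required)}")
    times = np.array(sorted(df["time"].unique()), dtype=float)
    species = list(pd.unique(df["species"]))
    values = np.full((len(species), times.size), np.nan)
    sigmas = np.full((len(species), times.size), np.nan)
    t_idx = {t: j for j, t in enumerate(times)}
    s_idx = {s: i for i, s in enumerate(species)}
    has_sigma = "sigma" in df.columns
    if not has_sigma and noise_model is None:
        raise MeasurementError("no sigma column and no noise model supplied")
    for row in df.itertuples(index=False):
        i, j = s_idx[row.species], t_idx[float(row.time)]
        if pd.isna(row.value):
            continue
        values[i, j] = float(row.value)
        if has_sigma and not pd.isna(row.sigma):
            sigmas[i, j] = float(row.sigma)
        else:
            sigmas[i, j] = sigma_of(max(row.value, 0.0), noise_model, row.species)
    return MeasurementSet(times=times, species_ids=species, values=values,
                          sigmas=sigmas,
                          xv_id=xv_id if xv_id in species else None)


def write_measurements(data: MeasurementSet, path) -> None:
    rows = []
    for i, sid in enumerate(data.species_ids):
        for j, t in enumerate(data.times):
            if data.mask[i, j]:
                rows.append((t, sid, data.values[i, j], data.sigmas[i, j]))
    pd.DataFrame(rows, columns=["time", "species", "value", "sigma"]).to_csv(
        path, index=False, float_format="%.15g")
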