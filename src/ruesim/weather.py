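"""Synthetic daily weather for a lowland tropical site, plus CSV I/O.

The generator emulates a humid-tropics station climate (~14 deg N): high
mean solar radiation with a single seasonal harmonic (dry-season maximum
around late April), day-to-day AR(1) persistence, radiation clipped to a
clear-sky envelope from solar geometry, warm temperatures weakly coupled
to the radiation anomaly, and high relative humidity.  Years are 365 days
(leap days dropped); everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .solar import extraterrestrial_radiation

__all__ = ["ClimateSpec", "WeatherSeries", "generate_weather", "read_weather", "write_weather"]

_COLUMNS = ["year", "doy", "srad", "tmax", "tmin", "rh"]


@dataclass
class ClimateSpec:
    """Distributional constants of the synthetic climate."""

    latitude: float = 14.2  # deg N
    radiation_mean: float = 17.5  # MJ m-2 d-1 annual mean shortwave
    radiation_amplitude: float = 3.5  # seasonal harmonic amplitude
    radiation_peak_doy: float = 120.0  # late-April maximum
    ar1_rho: float = 0.6  # day-to-day autocorrelation
    noise_sd: float = 3.0  # stationary s.d. of the radiation anomaly
    tmax_mean: float = 31.0  # degC
    tmin_mean: float = 23.0
    temp_amplitude: float = 1.5  # seasonal harmonic on temperatures
    temp_peak_doy: float = 135.0
    rh_mean: float = 80.0  # %
    clearsky_fraction: float = 0.75  # envelope = fraction x extraterrestrial
    n_years: int = 31
    seed: int = 0


@dataclass
class WeatherSeries:
    """A multi-year daily weather record backed by a tidy DataFrame."""

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"weather table missing columns: {missing}")
        self.frame = self.frame[_COLUMNS].reset_index(drop=True)
        for year, grp in self.frame.groupby("year", sort=True):
            doy = grp["doy"].to_numpy()
            expected = np.arange(1, len(doy) + 1)
            bad = np.nonzero(doy != expected)[0]
            if bad.size:
                line = int(grp.index[bad[0]]) + 2  # +1 header, +1 one-based
                raise ValueError(
                    f"non-contiguous doy in year {year} at line {line}: "
                    f"found {doy[bad[0]]}, expected {expected[bad[0]]}"
                )
            if len(doy) != 365:
                raise ValueError(f"year {year} has {len(doy)} days; expected 365")

    @property
    def years(self) -> np.ndarray:
        return np.unique(self.frame["year"].to_numpy())

    @property
    def n_years(self) -> int:
        return len(self.years)

    def __len__(self) -> int:
        return len(self.frame)

    def year(self, y: int) -> "WeatherSeries":
        return WeatherSeries(self.frame[self.frame["year"] == y])

    def to_arrays(self) -> dict:
        """Columns reshaped to (n_years, 365)."""
        ny = self.n_years
        return {
            c: self.frame[c].to_numpy(dtype=float).reshape(ny, 365)
            for c in ("srad", "tmax", "tmin", "rh")
        }


def generate_weather(spec: ClimateSpec) -> WeatherSeries:
    """Seeded synthetic weather series of ``spec.n_years`` x 365 days."""
    rng = np.random.default_rng(spec.seed)
    ndays = spec.n_years * 365
    doy = np.tile(np.arange(1, 366), spec.n_years)
    year = np.repeat(np.arange(1, spec.n_years + 1), 365)

    # AR(1) anomaly with stationary s.d. = noise_sd, carried across years
    eps = rng.normal(0.0, spec.noise_sd * np.sqrt(1.0 - spec.ar1_rho**2), ndays)
    z = np.empty(ndays)
    z[0] = rng.normal(0.0, spec.noise_sd)
    for t in range(1, ndays):
        z[t] = spec.ar1_rho * z[t - 1] + eps[t]

    harm = np.cos(2.0 * np.pi * (doy - spec.radiation_peak_doy) / 365.0)
    envelope = spec.clearsky_fraction * np.array(
        [extraterrestrial_radiation(spec.latitude, int(d)) for d in np.arange(1, 366)]
    )
    envelope = np.tile(envelope, spec.n_years)
    srad = np.clip(spec.radiation_mean + spec.radiation_amplitude * harm + z, 1.0, envelope)

    tharm = np.cos(2.0 * np.pi * (doy - spec.temp_peak_doy) / 365.0)
    tmax = spec.tmax_mean + spec.temp_amplitude * tharm + 0.25 * z + rng.normal(0.0, 0.8, ndays)
    tmin = spec.tmin_mean + 0.7 * spec.temp_amplitude * tharm + 0.10 * z + rng.normal(0.0, 0.8, ndays)
    tmin = np.minimum(tmin, tmax - 1.0)

    rh = np.clip(spec.rh_mean - 1.2 * z + rng.normal(0.0, 3.0, ndays), 45.0, 98.0)

    frame = pd.DataFrame(
        {"year": year, "doy": doy, "srad": srad, "tmax": tmax, "tmin": tmin, "rh": rh}
    )
    return WeatherSeries(frame)


def write_weather(series: WeatherSeries, path: str) -> None:
    series.frame.to_csv(path, index=False, float_format="%.6f")


def read_weather(path: str) -> WeatherSeries:
    """Read a weather CSV (header year,doy,srad,tmax,tmin,rh, any order)."""
    frame = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = frame[_COLUMNS].isna().any(axis=1)
    if bad.any():
        line = int(np.nonzero(bad.to_numpy())[0][0]) + 2
        raise ValueError(f"{path}: malformed row at line {line}")
    return WeatherSeries(frame)
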