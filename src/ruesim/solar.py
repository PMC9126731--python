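"""Solar geometry and the diurnal distribution of daily radiation.

Standard astronomy: declination from day of year, elevation from the
hour angle, daylength from the sunset hour angle.  Daily shortwave is
spread over the daytime with a half-sine so that the instantaneous PAR
integrates back to ``par_fraction`` x daily shortwave exactly; the
diffuse fraction follows a daily clearness-index rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SolarInstant",
    "declination",
    "daylength_hours",
    "extraterrestrial_radiation",
    "diffuse_fraction",
    "solar_geometry",
]

_SOLAR_CONSTANT = 1361.0  # W m-2


@dataclass
class SolarInstant:
    """Sun position and incident PAR at one moment."""

    elevation: float  # rad
    par_direct: float  # umol photon m-2 s-1 above the canopy
    par_diffuse: float  # umol photon m-2 s-1
    daylength: float  # h


def declination(doy: int) -> float:
    """Solar declination (rad)."""
    return math.radians(-23.45 * math.cos(2.0 * math.pi * (doy + 10) / 365.0))


def _sunset_hour_angle(latitude: float, doy: int) -> float:
    phi = math.radians(latitude)
    delta = declination(doy)
    x = -math.tan(phi) * math.tan(delta)
    if abs(x) >= 1.0:
        raise ValueError("polar day/night: latitude-day combination not supported")
    return math.acos(x)


def daylength_hours(latitude: float, doy: int) -> float:
    return 24.0 * _sunset_hour_angle(latitude, doy) / math.pi


def extraterrestrial_radiation(latitude: float, doy: int) -> float:
    """Daily extraterrestrial shortwave, MJ m-2 d-1 (clear-sky envelope base)."""
    phi = math.radians(latitude)
    delta = declination(doy)
    ws = _sunset_hour_angle(latitude, doy)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)
    s0 = (24.0 * 3600.0 / math.pi) * _SOLAR_CONSTANT * dr * (
        ws * math.sin(phi) * math.sin(delta)
        + math.cos(phi) * math.cos(delta) * math.sin(ws)
    )
    return s0 / 1e6


def diffuse_fraction(clearness_index: float) -> float:
    """Daily diffuse fraction of shortwave from the daily clearness index.

    Piecewise rule (overcast skies fully diffuse, clear skies ~23%):
      tau <= 0.07          -> 1.0
      0.07 < tau <= 0.35   -> 1 - 2.3 (tau - 0.07)^2
      0.35 < tau <= 0.75   -> 1.33 - 1.46 tau
      tau > 0.75           -> 0.23
    """
    tau = float(clearness_index)
    if tau <= 0.07:
        return 1.0
    if tau <= 0.35:
        return 1.0 - 2.3 * (tau - 0.07) ** 2
    if tau <= 0.75:
        return 1.33 - 1.46 * tau
    return 0.23


def solar_elevation(latitude: float, doy: int, hour: float) -> float:
    """Solar elevation (rad) at local solar time ``hour``."""
    phi = math.radians(latitude)
    delta = declination(doy)
    h = math.pi * (hour - 12.0) / 12.0
    sin_el = math.sin(phi) * math.sin(delta) + math.cos(phi) * math.cos(delta) * math.cos(h)
    return math.asin(max(-1.0, min(1.0, sin_el)))


def solar_geometry(
    doy: int,
    latitude: float,
    hour: float,
    daily_radiation: float,
    par_fraction: float = 0.5,
    umol_per_J: float = 4.56,
) -> SolarInstant:
    """Sun position and incident direct/diffuse PAR at a given solar hour.

    ``daily_radiation`` is daily total shortwave (MJ m-2 d-1).  The
    instantaneous PAR follows a half-sine over the daytime whose integral
    equals par_fraction x daily_radiation.
    """
    if abs(latitude) >= 66.0:
        raise ValueError("latitudes polewards of 66 deg are not supported")
    dl = daylength_hours(latitude, doy)
    sunrise = 12.0 - dl / 2.0
    elevation = solar_elevation(latitude, doy, hour)
    if hour <= sunrise or hour >= 12.0 + dl / 2.0 or elevation <= 0.0:
        return SolarInstant(elevation=elevation, par_direct=0.0, par_diffuse=0.0, daylength=dl)
    par_daily = par_fraction * daily_radiation * 1e6  # J m-2 d-1
    dl_s = dl * 3600.0
    # half-sine: integral over the day equals par_daily exactly
    par_wm2 = par_daily * (math.pi / (2.0 * dl_s)) * math.sin(math.pi * (hour - sunrise) / dl)
    s0 = extraterrestrial_radiation(latitude, doy)
    tau = min(daily_radiation / s0, 1.0)
    fd = diffuse_fraction(tau)
    par_umol = par_wm2 * umol_per_J
    return SolarInstant(
        elevation=elevation,
        par_direct=(1.0 - fd) * par_umol,
        par_diffuse=fd * par_umol,
        daylength=dl,
    )


def diurnal_temperature(tmin, tmax, hour, sunrise: float, daylength: float):
    """Air temperature interpolated between Tmin (sunrise) and Tmax.

    Half-sine over daylength + 1.5 h lag; vectorized in tmin/tmax.
    """
    frac = np.sin(math.pi * (hour - sunrise) / (daylength + 3.0))
    return np.asarray(tmin) + (np.asarray(tmax) - np.asarray(tmin)) * max(frac, 0.0)


def saturation_vapour_pressure(T):
    """kPa, Tetens formula."""
    T = np.asarray(T, dtype=float)
    return 0.6108 * np.exp(17.27 * T / (T + 237.3))
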