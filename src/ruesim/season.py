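"""Daily-stepping seasonal crop surrogate.

A fixed-length season (default 110 d) with two phases: vegetative growth
until the start of grain filling ``t_fill``, then filling with nitrogen
remobilization.  Each day the canopy model converts intercepted PAR into
gross assimilate; a fixed respired fraction and a conversion efficiency
turn it into above-ground biomass.  Nitrogen follows a sigmoid season
uptake; the canopy holds it in three pools (structural N at ``nb`` per
unit green area, photosynthetically active N, and a stem reserve that
buffers the top-leaf content at a physiological cap).  During filling,
grain nitrogen demand drains reserve and canopy; canopy N export causes
proportional loss of green area (senescence).  Slowing the canopy export
(stay-green) therefore extends photosynthetic duration.

Mass and nitrogen ledgers balance exactly at every step, and
RUE = biomass / intercepted PAR holds by construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .canopy import canopy_A_daily, make_profile
from .config import Configs, SeasonParams
from .weather import WeatherSeries

__all__ = [
    "CropState",
    "SeasonResult",
    "n_uptake_cum",
    "remobilization_step",
    "gai_update",
    "step_day",
    "run_season",
    "run_seasons",
]

_CO2_TO_CH2O = 30.0 / 44.0  # g carbohydrate per g CO2


@dataclass
class CropState:
    """Within-season pools; fields are scalars or year-batch arrays."""

    day: int
    W: np.ndarray  # above-ground biomass, g m-2
    GAI_leaf: np.ndarray
    GAI_nonleaf: np.ndarray
    N_active: np.ndarray  # photosynthetically active canopy N, g N m-2
    N_reserve: np.ndarray  # stem/sheath N reserve
    N_struct: np.ndarray  # structural N (nb per unit green area)
    N_grain: np.ndarray  # N exported to grain
    N_nonphot: np.ndarray  # stems/roots share of uptake
    N_taken: np.ndarray  # cumulative uptake + seed endowment
    PAR_int: np.ndarray  # cumulative intercepted PAR, MJ m-2
    A_gross_cum: np.ndarray  # cumulative gross assimilation, g CO2 m-2

    @property
    def GAI(self) -> np.ndarray:
        return self.GAI_leaf + self.GAI_nonleaf

    @property
    def leaf_fraction(self) -> np.ndarray:
        tot = self.GAI
        return np.where(tot > 0, self.GAI_leaf / np.maximum(tot, 1e-12), 1.0)

    @property
    def N_canopy(self) -> np.ndarray:
        """Active canopy N (the pool that drives the vertical profile)."""
        return self.N_active

    def n_ledger_residual(self) -> np.ndarray:
        pools = self.N_active + self.N_reserve + self.N_struct + self.N_grain + self.N_nonphot
        return self.N_taken - pools


@dataclass
class SeasonResult:
    """Season outputs: biomass (t ha-1), RUE (g biomass per MJ intercepted PAR)."""

    biomass: float | np.ndarray
    RUE: float | np.ndarray
    PAR_int: float | np.ndarray
    A_gross_cum: float | np.ndarray
    trace: pd.DataFrame | None = field(default=None, repr=False)

    def trace_csv(self, path: str) -> None:
        if self.trace is None:
            raise ValueError("no trace recorded")
        self.trace.to_csv(path, index=False)


def n_uptake_cum(t: float, p: SeasonParams) -> float:
    """Cumulative N uptake at day t: normalized logistic reaching Numax.

    Scaling Numax scales every daily increment equally, leaving the daily
    uptake proportions unchanged.
    """
    def logistic(x):
        return 1.0 / (1.0 + np.exp(-(x - p.t_mid) / p.t_scale))

    lo, hi = logistic(0.0), logistic(float(p.duration))
    return p.Numax * (logistic(float(t)) - lo) / (hi - lo)


def _sla_at(t: float, p: SeasonParams) -> float:
    if t <= p.sla_decline_start:
        return p.SLA_early
    if t >= p.t_fill:
        return p.SLA_late
    frac = (t - p.sla_decline_start) / (p.t_fill - p.sla_decline_start)
    return p.SLA_early + (p.SLA_late - p.SLA_early) * frac


def _f_leaf_at(t: float, p: SeasonParams) -> float:
    return p.f_leaf * max(0.0, 1.0 - t / p.t_fill)


def remobilization_step(state: CropState, t: float, p: SeasonParams, uptake_today=0.0):
    """Grain N fluxes on day t: (canopy_flux, reserve_flux), g N m-2 d-1.

    Zero before grain filling.  Grain nitrogen demand is sink-driven (a
    fixed daily requirement set by grain growth, not by the source); it is
    met first by concurrent root uptake and the stem reserve, and only the
    shortfall is remobilized from the active canopy N, scaled by the
    stay-green factor.  Canopy remobilization is what drives senescence,
    so a smaller stay-green factor and a larger N uptake both keep the
    canopy green longer.
    """
    if t < p.t_fill:
        z = np.zeros_like(np.asarray(state.N_active, dtype=float))
        return z, z
    F_res = np.minimum(p.remob_rate * state.N_reserve, state.N_reserve)
    shortfall = np.maximum(p.grain_n_demand - np.asarray(uptake_today) - F_res, 0.0)
    F_can = p.staygreen_factor * shortfall
    F_can = np.minimum(F_can, state.N_active)
    return F_can, F_res


def gai_update(state: CropState, daily_growth, t: float, p: SeasonParams, nb: float,
               nonleaf_area_ratio: float, N_available=None):
    """Potential green-area expansion on day t and its structural N cost.

    Vegetative phase only.  Expansion is co-limited by carbon and nitrogen:
    the carbon potential is SLA(t) x f_leaf(t) x growth of new leaf area
    (plus proportional non-leaf area), and nitrogen allows only as much new
    leaf area as can be filled at the minimum specific leaf N
    ``sln_expand`` after paying the structural cost ``nb`` per unit of new
    green area.  Total area is capped at max_GAI.  Returns
    (dGAI_leaf, dGAI_nonleaf, structural_N_used).
    """
    growth = np.maximum(np.asarray(daily_growth, dtype=float), 0.0)
    pot_leaf = _sla_at(t, p) * _f_leaf_at(t, p) * growth
    pot_nl = nonleaf_area_ratio * pot_leaf
    pot_tot = pot_leaf + pot_nl
    room = np.maximum(p.max_GAI - state.GAI, 0.0)
    scale = np.where(pot_tot > 0, np.minimum(1.0, room / np.maximum(pot_tot, 1e-12)), 0.0)
    if N_available is not None:
        # active N after expansion must cover sln_expand on all leaf area
        # plus the structural N of the new (leaf + non-leaf) area
        cost = p.sln_expand + nb
        dleaf_n = np.maximum(
            np.asarray(N_available, dtype=float) - p.sln_expand * state.GAI_leaf, 0.0
        ) / cost
        n_scale = np.where(pot_leaf > 0, np.minimum(1.0, dleaf_n / np.maximum(pot_leaf, 1e-12)), 0.0)
        scale = np.minimum(scale, n_scale)
    d_leaf = scale * pot_leaf
    d_nl = scale * pot_nl
    return d_leaf, d_nl, nb * d_leaf


def step_day(state: CropState, day: dict, cfg: Configs, latitude: float) -> tuple[CropState, dict]:
    """Advance the crop by one day; returns (new_state, daily diagnostics)."""
    p = cfg.season
    can = cfg.canopy
    t = state.day + 1

    # --- assimilation with the start-of-day canopy -------------------------
    early = t <= can.early_phase_days
    profile = make_profile(can, state.GAI, state.leaf_fraction, state.N_active, early=early)
    if np.all(state.GAI <= 1e-9):
        ny = np.asarray(state.W).shape[0]
        res = {"gross": np.zeros(ny), "net": np.zeros(ny), "par_int": np.zeros(ny)}
    else:
        res = canopy_A_daily(profile, day, latitude, cfg.leaf, cfg.cond, can)
    gross = res["gross"]
    dW = p.eps_conv * (1.0 - p.f_resp) * _CO2_TO_CH2O * gross

    new = dataclasses.replace(state)
    new.day = t
    new.W = state.W + dW
    new.PAR_int = state.PAR_int + res["par_int"]
    new.A_gross_cum = state.A_gross_cum + gross

    # --- nitrogen uptake ---------------------------------------------------
    du = n_uptake_cum(t, p) - n_uptake_cum(t - 1, p)
    new.N_taken = state.N_taken + du
    if t < p.t_fill:
        dN_can = (1.0 - p.f_nonphot) * du
        new.N_nonphot = state.N_nonphot + p.f_nonphot * du
        uptake_to_grain = 0.0
    else:
        # post-anthesis uptake: part keeps feeding the canopy, the rest
        # goes straight to grain
        dN_can = p.post_fill_canopy_share * du
        uptake_to_grain = (1.0 - p.post_fill_canopy_share) * du
        new.N_grain = state.N_grain + uptake_to_grain

    # --- green-area expansion (vegetative phase) ---------------------------
    avail_N = state.N_active + dN_can
    d_leaf, d_nl, n_struct_used = gai_update(
        new, dW, t, p, can.nb, can.nonleaf_area_ratio, N_available=avail_N
    )
    new.GAI_leaf = state.GAI_leaf + d_leaf
    new.GAI_nonleaf = state.GAI_nonleaf + d_nl
    new.N_struct = state.N_struct + n_struct_used
    new.N_active = avail_N - n_struct_used

    # --- top-leaf N cap: exchange with the stem reserve --------------------
    kN = profile.kN
    hold = (can.n0_max - can.nb) * (1.0 - np.exp(-kN * np.maximum(new.GAI_leaf, 1e-9))) / kN
    excess = new.N_active - hold
    to_reserve = np.maximum(excess, 0.0)
    new.N_reserve = state.N_reserve + to_reserve
    new.N_active = new.N_active - to_reserve
    if t < p.t_fill:
        back = np.minimum(np.maximum(-excess, 0.0), new.N_reserve)
        new.N_active = new.N_active + back
        new.N_reserve = new.N_reserve - back

    # --- remobilization and senescence (grain filling) ----------------------
    F_can, F_res = remobilization_step(new, t, p, uptake_today=uptake_to_grain)
    new.N_active = new.N_active - F_can
    new.N_reserve = new.N_reserve - F_res
    new.N_grain = new.N_grain + F_can + F_res
    gai_tot = new.GAI
    d_sen = np.minimum(F_can / p.sln_senesce, gai_tot)
    frac_leaf = np.where(gai_tot > 0, new.GAI_leaf / np.maximum(gai_tot, 1e-12), 1.0)
    new.GAI_leaf = np.maximum(new.GAI_leaf - d_sen * frac_leaf, 0.0)
    new.GAI_nonleaf = np.maximum(new.GAI_nonleaf - d_sen * (1.0 - frac_leaf), 0.0)
    n_struct_freed = can.nb * d_sen * frac_leaf
    new.N_struct = new.N_struct - n_struct_freed
    new.N_grain = new.N_grain + n_struct_freed

    diag = {"gross": gross, "dW": dW, "par_int": res["par_int"], "F_can": F_can, "F_res": F_res}
    return new, diag


def _initial_state(cfg: Configs, ny: int) -> CropState:
    p = cfg.season
    can = cfg.canopy
    ones = np.ones(ny)
    gai_leaf0 = p.GAI0 / (1.0 + can.nonleaf_area_ratio)
    gai_nl0 = p.GAI0 - gai_leaf0
    n_struct0 = can.nb * gai_leaf0
    return CropState(
        day=0,
        W=ones * gai_leaf0 / p.SLA_early,
        GAI_leaf=ones * gai_leaf0,
        GAI_nonleaf=ones * gai_nl0,
        N_active=ones * max(p.N_seed - n_struct0, 0.0),
        N_reserve=np.zeros(ny),
        N_struct=ones * n_struct0,
        N_grain=np.zeros(ny),
        N_nonphot=np.zeros(ny),
        N_taken=ones * p.N_seed,
        PAR_int=np.zeros(ny),
        A_gross_cum=np.zeros(ny),
    )


def run_seasons(
    cfg: Configs,
    weather: WeatherSeries,
    latitude: float | None = None,
    record_trace: bool = False,
) -> SeasonResult:
    """Run the season over every year in ``weather`` simultaneously.

    Deterministic given weather and configuration.  ``biomass`` and ``RUE``
    in the result are per-year arrays; the optional trace holds the daily
    state of all years in long format.
    """
    p = cfg.season
    lat = 14.2 if latitude is None else latitude
    arrays = weather.to_arrays()
    ny = arrays["srad"].shape[0]
    if p.emergence_doy + p.duration - 1 > arrays["srad"].shape[1]:
        raise ValueError("weather does not cover the season")
    state = _initial_state(cfg, ny)
    rows = []
    for t in range(1, p.duration + 1):
        doy = p.emergence_doy + t - 1
        day = {
            "doy": doy,
            "srad": arrays["srad"][:, doy - 1],
            "tmax": arrays["tmax"][:, doy - 1],
            "tmin": arrays["tmin"][:, doy - 1],
            "rh": arrays["rh"][:, doy - 1],
        }
        state, diag = step_day(state, day, cfg, lat)
        if record_trace:
            for iy in range(ny):
                rows.append(
                    {
                        "year": iy + 1,
                        "day": t,
                        "GAI": float(state.GAI[iy]),
                        "N_canopy": float(state.N_active[iy]),
                        "A_gross": float(diag["gross"][iy]),
                        "PAR_int": float(state.PAR_int[iy]),
                        "W": float(state.W[iy]),
                    }
                )
    biomass_g = state.W
    rue = np.where(state.PAR_int > 0, biomass_g / np.maximum(state.PAR_int, 1e-12), 0.0)
    trace = pd.DataFrame(rows) if record_trace else None
    return SeasonResult(
        biomass=biomass_g * 0.01,  # g m-2 -> t ha-1
        RUE=rue,
        PAR_int=state.PAR_int,
        A_gross_cum=state.A_gross_cum,
        trace=trace,
    )


def run_season(
    cfg: Configs,
    weather_year: WeatherSeries,
    latitude: float | None = None,
    record_trace: bool = True,
) -> SeasonResult:
    """Single-year convenience wrapper around :func:`run_seasons`."""
    if weather_year.n_years != 1:
        raise ValueError("run_season expects exactly one year of weather")
    res = run_seasons(cfg, weather_year, latitude, record_trace=record_trace)
    return SeasonResult(
        biomass=float(res.biomass[0]),
        RUE=float(res.RUE[0]),
        PAR_int=float(res.PAR_int[0]),
        A_gross_cum=float(res.A_gross_cum[0]),
        trace=res.trace,
    )
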