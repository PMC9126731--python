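"""Parameter containers and study-condition defaults.

Every tunable constant of the simulator lives in one of the dataclasses
below.  The defaults describe the baseline crop: a high-yielding lowland
tropical rice canopy under potential (non-stressed) growing conditions,
with leaf biochemical capacities expressed as linear functions of leaf
nitrogen.  Scenario runs never mutate these objects in place; they are
copied and overridden through :func:`ruesim.scenarios.apply_overrides`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = [
    "LeafBiochem",
    "AirEnv",
    "Conductances",
    "CanopyConfig",
    "SeasonParams",
    "Configs",
    "compose_kappa2ll",
    "default_configs",
    "load_configs",
    "dump_configs",
]


def compose_kappa2ll(
    beta: float, Phi2LL: float, f_cyc: float, f_pseudo: float, phi_ratio: float
) -> float:
    """Efficiency of converting *incident* photons into linear electron flux.

    kappa_2LL = beta * Phi_2LL * (1 - f_cyc - f_pseudo) / (Phi_2LL/Phi_1LL + (1 - f_cyc))

    where ``phi_ratio`` is the conserved PSII:PSI photochemical efficiency
    ratio (~0.85).  The same quotient, without the absorptance ``beta``,
    multiplies the CO2-side term in the quantum-yield expression, which is
    why ``beta * phi_co2 == phi_co2_inc`` holds identically.
    """
    return beta * Phi2LL * (1.0 - f_cyc - f_pseudo) / (phi_ratio + (1.0 - f_cyc))


@dataclass
class LeafBiochem:
    """FvCB biochemistry of one leaf (or one canopy layer) at 25 degC.

    Units: Vcmax, Tp, Rd in umol CO2 m-2 s-1; Jmax in umol e- m-2 s-1;
    Gamma_star and KmC in ubar; KmO in mbar.  ``kappa2LL`` is on the
    incident-light basis, mol e- (mol photon)-1; if left at None it is
    derived from the component efficiencies via :func:`compose_kappa2ll`.
    """

    Vcmax: float = 100.0
    Jmax: float = 150.0
    Tp: float = 8.0
    Rd: float = 1.0
    alpha_S: float = 0.0
    Gamma_star: float = 37.5
    KmC: float = 272.0
    KmO: float = 166.0
    theta_J: float = 0.85
    Phi2LL: float = 0.78
    f_cyc: float = 0.0
    f_pseudo: float = 0.05
    phi_ratio: float = 0.85
    beta: float = 0.85
    kappa2LL: float | None = None
    tpu_active: bool = True
    # Rd is tied to Vcmax when capacities are derived from leaf N.
    rd_vcmax_ratio: float = 0.01
    # Temperature response constants (J mol-1); peaked Arrhenius for the
    # capacities, plain Arrhenius for kinetic constants (Bernacchi-type).
    Ha_Vcmax: float = 65330.0
    Ha_Jmax: float = 43540.0
    Ha_Tp: float = 25000.0
    Ha_Rd: float = 46390.0
    Ha_KmC: float = 79430.0
    Ha_KmO: float = 36380.0
    Ha_Gamma: float = 37830.0
    Hd_peak: float = 152040.0
    S_peak: float = 495.0

    def __post_init__(self) -> None:
        if self.kappa2LL is None:
            self.kappa2LL = compose_kappa2ll(
                self.beta, self.Phi2LL, self.f_cyc, self.f_pseudo, self.phi_ratio
            )
        if not 0.0 <= self.alpha_S <= 0.75:
            raise ValueError("alpha_S must lie in [0, 0.75]")
        if not 0.0 < self.Gamma_star < self.KmC:
            raise ValueError("require 0 < Gamma_star < KmC")
        if not 0.0 < self.theta_J < 1.0:
            raise ValueError("theta_J must lie in (0, 1)")
        if self.f_cyc + self.f_pseudo >= 1.0:
            raise ValueError("f_cyc + f_pseudo must be < 1")
        if not 0.0 < self.beta <= 1.0:
            raise ValueError("beta must lie in (0, 1]")
        for name in ("Vcmax", "Jmax", "Tp", "Rd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def replace(self, **kw: Any) -> "LeafBiochem":
        out = dataclasses.replace(self, **kw)
        if "Phi2LL" in kw and "kappa2LL" not in kw:
            # quantum-yield components changed: re-derive the lumped slope
            out.kappa2LL = compose_kappa2ll(
                out.beta, out.Phi2LL, out.f_cyc, out.f_pseudo, out.phi_ratio
            )
        return out


@dataclass
class AirEnv:
    """Instantaneous aerial environment of a leaf."""

    I_inc: float = 1800.0  # incident PAR, umol photon m-2 s-1
    Ca: float = 380.0  # atmospheric CO2, ubar
    O: float = 210.0  # oxygen, mbar
    T_leaf: float = 25.0  # degC
    VPD: float = 1.5  # kPa

    def __post_init__(self) -> None:
        if self.I_inc < 0 or self.Ca <= 0 or self.O <= 0 or self.VPD < 0:
            raise ValueError("invalid AirEnv: need I_inc>=0, Ca>0, O>0, VPD>=0")


@dataclass
class Conductances:
    """CO2 diffusion parameters.

    ``gm`` is mesophyll conductance (mol m-2 s-1 bar-1).  Stomatal
    conductance is modelled for CO2 with a Ball-Berry-Leuning closure
    gs = g0 + a1*A/((Ca - Gamma_star)*(1 + VPD/D0)); ``gs_multiplier``
    scales the whole gs (the "improved gs" scenario uses 1.2).
    """

    gm: float = 0.25
    g0: float = 0.01
    a1: float = 12.0
    D0: float = 2.0
    gs_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.gm <= 0 or self.g0 < 0 or self.a1 <= 0 or self.D0 <= 0:
            raise ValueError("invalid Conductances")
        if self.gs_multiplier <= 0:
            raise ValueError("gs_multiplier must be > 0")


@dataclass
class CanopyConfig:
    """Canopy structure, vertical profiles and capacity-vs-nitrogen slopes."""

    leaf_angle: float = 65.0  # mean inclination from horizontal, deg
    leaf_angle_early: float = 65.0  # value used during the early phase
    early_phase_days: float = 30.0  # duration of the "early phase", d
    kN_ratio: float = 0.80  # kN : representative kL
    nb: float = 0.3  # base leaf N, g N m-2 (photosynthesis nil at/below)
    scattering: float = 0.2  # leaf scattering coefficient for PAR
    # capacity slopes vs leaf N above nb (Table-type parameter set)
    chi_Vcmax: float = 75.0  # umol (g N)-1 s-1
    chi_Jmax: float = 100.0  # umol (g N)-1 s-1
    chi_Tp: float = 5.0  # umol (g N)-1 s-1
    chi_gm: float = 0.125  # mol (g N)-1 s-1 bar-1
    nonleaf_area_ratio: float = 0.35  # green non-leaf area per unit leaf area
    nonleaf_efficiency: float = 0.5  # relative photosynthetic efficiency
    n0_max: float = 4.0  # guard cap on top-leaf N, g N m-2
    kl_reference_gai: float = 2.0  # depth at which the diffuse kL is representative
    Ca: float = 380.0  # ubar
    O: float = 210.0  # mbar
    par_fraction: float = 0.5  # PAR : shortwave
    umol_per_J: float = 4.56  # photon content of PAR
    nlayers: int = 5  # Gauss nodes over depth
    ntimes: int = 5  # Gauss nodes over the diurnal course


@dataclass
class SeasonParams:
    """Daily-stepping season surrogate parameters.

    ``f_resp`` and ``f_leaf`` are the two coefficients adjusted by the
    one-time baseline calibration; everything else is frozen.
    """

    duration: int = 110  # season length, d
    emergence_doy: int = 10  # calendar day the season starts
    GAI0: float = 0.15  # green area at emergence, m2 m-2
    SLA_early: float = 0.030  # specific leaf area, m2 g-1 (early phase)
    SLA_late: float = 0.022  # late-phase SLA, m2 g-1
    sla_decline_start: float = 30.0  # d; SLA_early applies before this day
    f_leaf: float = 0.50  # carbon allocation to leaf at emergence (calibrated)
    Numax: float = 20.0  # season-long N uptake, g N m-2
    t_mid: float = 50.0  # sigmoid uptake midpoint, d
    t_scale: float = 14.0  # sigmoid uptake time scale, d
    t_fill: float = 60.0  # start of grain filling, d
    remob_rate: float = 0.04  # fractional daily drain of the stem N reserve, d-1
    grain_n_demand: float = 0.20  # sink-driven daily grain N demand, g N m-2 d-1
    staygreen_factor: float = 1.0  # multiplier on canopy remobilization
    f_resp: float = 0.15  # respired fraction of gross assimilate (calibrated)
    eps_conv: float = 0.75  # biomass per unit carbohydrate, g g-1
    max_GAI: float = 7.5  # cap on green area index
    f_nonphot: float = 0.55  # uptake share to non-photosynthetic organs
    sln_senesce: float = 1.1  # active leaf N released per m2 senesced GAI
    sln_expand: float = 1.0  # minimum active leaf N for new leaf area, g N m-2
    post_fill_canopy_share: float = 0.0  # share of post-anthesis uptake kept by canopy
    N_seed: float = 0.2  # N endowment at emergence (consistent with GAI0 at sln_expand), g N m-2

    def __post_init__(self) -> None:
        for name in ("f_leaf", "f_resp", "eps_conv"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.Numax < 0:
            raise ValueError("Numax must be >= 0")
        if not 0 < self.t_fill < self.duration:
            raise ValueError("t_fill must lie inside the season")


@dataclass
class Configs:
    """Bundle of all configuration blocks used by a simulation run."""

    leaf: LeafBiochem = field(default_factory=LeafBiochem)
    cond: Conductances = field(default_factory=Conductances)
    canopy: CanopyConfig = field(default_factory=CanopyConfig)
    season: SeasonParams = field(default_factory=SeasonParams)

    def copy(self) -> "Configs":
        return Configs(
            leaf=dataclasses.replace(self.leaf),
            cond=dataclasses.replace(self.cond),
            canopy=dataclasses.replace(self.canopy),
            season=dataclasses.replace(self.season),
        )


def default_configs() -> Configs:
    """Baseline study conditions."""
    return Configs()


_SCHEMA_VERSION = 1


def dump_configs(cfg: Configs, path: str) -> None:
    """Write a config bundle as a versioned YAML document."""
    doc = {
        "schema_version": _SCHEMA_VERSION,
        "leaf": dataclasses.asdict(cfg.leaf),
        "cond": dataclasses.asdict(cfg.cond),
        "canopy": dataclasses.asdict(cfg.canopy),
        "season": dataclasses.asdict(cfg.season),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_configs(path: str) -> Configs:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc.get("schema_version") != _SCHEMA_VERSION:
        raise ValueError(f"unsupported config schema_version: {doc.get('schema_version')}")
    return Configs(
        leaf=LeafBiochem(**doc["leaf"]),
        cond=Conductances(**doc["cond"]),
        canopy=CanopyConfig(**doc["canopy"]),
        season=SeasonParams(**doc["season"]),
    )
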