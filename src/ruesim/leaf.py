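"""Steady-state C3 leaf photosynthesis.

Net assimilation is the minimum of three FvCB limitation rates
(Rubisco carboxylation, linear electron transport, triose-phosphate
utilization), coupled to CO2 diffusion through stomata and mesophyll:

    A  = min(Ac, Aj, Ap) evaluated at Cc,
    Cc = Ca - A * (1/gm + 1/gs(A)),
    gs = gs_multiplier * [g0 + a1 * max(A,0) / ((Ca - Gamma*) (1 + VPD/D0))].

The self-consistent solution is found by bisection on Cc; the residual
Ca - Cc - A (1/gm + 1/gs) is strictly decreasing in Cc, so the root is
unique.  All kernel functions are numpy-vectorized so a whole canopy
(layers x sunlit/shaded x time points x years) is solved in one call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import AirEnv, Conductances, LeafBiochem

__all__ = [
    "LeafFlux",
    "limitation_rates",
    "j_from_light",
    "phi_co2",
    "phi_co2_inc",
    "stomatal_conductance",
    "solve_coupled",
    "solve_coupled_arrays",
    "temperature_adjust",
    "a_max",
]

_R_GAS = 8.314  # J mol-1 K-1
_T_REF = 298.15  # K
_LIMITATION_NAMES = ("rubisco", "electron", "tpu")


@dataclass
class LeafFlux:
    """Solved leaf gas-exchange state."""

    A: float  # net assimilation, umol CO2 m-2 s-1
    Ci: float  # intercellular CO2, ubar
    Cc: float  # chloroplast CO2, ubar
    J: float  # realized electron flux, umol e- m-2 s-1
    gs: float  # stomatal conductance for CO2, mol m-2 s-1
    limitation: str  # which candidate rate is binding

    @property
    def gs_water(self) -> float:
        """Stomatal conductance for water vapour (1.6 x CO2 value)."""
        return 1.6 * self.gs


def _arrhenius(T_leaf, Ha):
    TK = np.asarray(T_leaf) + 273.15
    return np.exp(Ha * (TK - _T_REF) / (_R_GAS * _T_REF * TK))


def _peaked(T_leaf, Ha, Hd, S):
    TK = np.asarray(T_leaf) + 273.15
    arr = _arrhenius(T_leaf, Ha)
    num = 1.0 + np.exp((S * _T_REF - Hd) / (_R_GAS * _T_REF))
    den = 1.0 + np.exp((S * TK - Hd) / (_R_GAS * TK))
    return arr * num / den


def temperature_factors(p: LeafBiochem, T_leaf):
    """Multiplicative temperature scalings, all equal to 1 at 25 degC."""
    return {
        "Vcmax": _peaked(T_leaf, p.Ha_Vcmax, p.Hd_peak, p.S_peak),
        "Jmax": _peaked(T_leaf, p.Ha_Jmax, p.Hd_peak, p.S_peak),
        "Tp": _peaked(T_leaf, p.Ha_Tp, p.Hd_peak, p.S_peak),
        "Rd": _arrhenius(T_leaf, p.Ha_Rd),
        "KmC": _arrhenius(T_leaf, p.Ha_KmC),
        "KmO": _arrhenius(T_leaf, p.Ha_KmO),
        "Gamma_star": _arrhenius(T_leaf, p.Ha_Gamma),
    }


def temperature_adjust(p25: LeafBiochem, T_leaf: float) -> LeafBiochem:
    """Return the parameter set scaled from 25 degC to ``T_leaf``."""
    if not -5.0 <= T_leaf <= 50.0:
        raise ValueError(f"T_leaf {T_leaf} degC outside the supported range [-5, 50]")
    f = temperature_factors(p25, T_leaf)
    return p25.replace(
        Vcmax=p25.Vcmax * float(f["Vcmax"]),
        Jmax=p25.Jmax * float(f["Jmax"]),
        Tp=p25.Tp * float(f["Tp"]),
        Rd=p25.Rd * float(f["Rd"]),
        KmC=p25.KmC * float(f["KmC"]),
        KmO=p25.KmO * float(f["KmO"]),
        Gamma_star=p25.Gamma_star * float(f["Gamma_star"]),
        kappa2LL=p25.kappa2LL,
    )


def limitation_rates(Cc, J, p: LeafBiochem, O: float = 210.0):
    """The three candidate net rates (Ac, Aj, Ap) at chloroplast CO2 ``Cc``.

    Ap is +inf when the TPU limitation is inactive, or when Cc is at or
    below the TPU singularity (1 + 4 alpha_S) Gamma* where the expression
    is undefined (flagged as non-limiting).  With alpha_S = 0 the TPU rate
    reduces to the simplest form 3 Tp - Rd.
    """
    Cc = np.asarray(Cc, dtype=float)
    Ac = (Cc - p.Gamma_star) * p.Vcmax / (Cc + p.KmC * (1.0 + O / p.KmO)) - p.Rd
    Aj = (Cc - p.Gamma_star) * np.asarray(J) / (4.0 * (Cc + 2.0 * p.Gamma_star)) - p.Rd
    if not p.tpu_active:
        Ap = np.full_like(Ac, np.inf)
    else:
        den = Cc - (1.0 + 4.0 * p.alpha_S) * p.Gamma_star
        with np.errstate(divide="ignore", invalid="ignore"):
            Ap = np.where(den > 0, (Cc - p.Gamma_star) * 3.0 * p.Tp / np.where(den > 0, den, 1.0) - p.Rd, np.inf)
    return Ac, Aj, Ap


def j_from_light(I_inc, p: LeafBiochem):
    """Electron flux from incident PAR: non-rectangular hyperbola.

    J is the smaller root of
    theta_J J^2 - (kappa2LL I + Jmax) J + kappa2LL I Jmax = 0,
    with initial slope kappa2LL and asymptote Jmax.
    """
    I_inc = np.asarray(I_inc, dtype=float)
    return _j_nrh(I_inc, p.Jmax, p.kappa2LL, p.theta_J)


def _j_nrh(I_inc, Jmax, kappa2LL, theta_J):
    x = np.asarray(kappa2LL) * np.asarray(I_inc)
    Jmax = np.asarray(Jmax, dtype=float)
    if np.ndim(theta_J) == 0 and theta_J < 1e-9:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(x + Jmax > 0, x * Jmax / (x + Jmax), 0.0)
        return out
    b = x + Jmax
    disc = b * b - 4.0 * theta_J * x * Jmax
    return (b - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * theta_J)


def phi_co2(Cc, p: LeafBiochem):
    """Quantum yield of CO2 fixation on the absorbed-light basis.

    Phi_CO2 = Phi2LL (1 - f_cyc - f_pseudo) / (Phi2LL/Phi1LL + (1 - f_cyc))
              * (Cc - Gamma*) / (4 (Cc + 2 Gamma*)).

    For Cc <= Gamma* the (negative) extrapolation is returned as-is.
    """
    Cc = np.asarray(Cc, dtype=float)
    eff = p.Phi2LL * (1.0 - p.f_cyc - p.f_pseudo) / (p.phi_ratio + (1.0 - p.f_cyc))
    return eff * (Cc - p.Gamma_star) / (4.0 * (Cc + 2.0 * p.Gamma_star))


def phi_co2_inc(Cc, p: LeafBiochem):
    """Quantum yield on the incident-light basis: kappa2LL (Cc-G*)/(4(Cc+2G*))."""
    Cc = np.asarray(Cc, dtype=float)
    return p.kappa2LL * (Cc - p.Gamma_star) / (4.0 * (Cc + 2.0 * p.Gamma_star))


def stomatal_conductance(A, env: AirEnv, c: Conductances, Gamma_star: float = 37.5):
    """Stomatal conductance for CO2 from net assimilation and environment."""
    if env.VPD < 0:
        raise ValueError("VPD must be >= 0")
    A = np.asarray(A, dtype=float)
    var = c.a1 * np.maximum(A, 0.0) / ((env.Ca - Gamma_star) * (1.0 + env.VPD / c.D0))
    return c.gs_multiplier * (c.g0 + var)


def _gs_arrays(A, Ca, VPD, Gamma_star, g0, a1, D0, mult):
    var = a1 * np.maximum(A, 0.0) / ((Ca - Gamma_star) * (1.0 + VPD / D0))
    return mult * (g0 + var)


def solve_coupled_arrays(
    I_inc,
    Ca,
    O,
    VPD,
    Vcmax,
    Jmax,
    Tp,
    Rd,
    gm,
    Gamma_star,
    KmC,
    KmO,
    *,
    alpha_S=0.0,
    theta_J=0.85,
    kappa2LL=0.32,
    tpu_active=True,
    g0=0.01,
    a1=7.0,
    D0=1.5,
    gs_multiplier=1.0,
    n_iter=40,
):
    """Vectorized coupled FvCB-diffusion solver.

    All arguments broadcast against each other; temperature scaling must be
    applied to the biochemical inputs by the caller.  Returns a dict of
    arrays: A, Ci, Cc, J, gs and an integer limitation code
    (0 rubisco, 1 electron, 2 tpu).
    """
    (I_inc, Ca, O, VPD, Vcmax, Jmax, Tp, Rd, gm, Gamma_star, KmC, KmO) = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in
          (I_inc, Ca, O, VPD, Vcmax, Jmax, Tp, Rd, gm, Gamma_star, KmC, KmO))
    )
    gm = np.maximum(gm, 1e-9)
    J = _j_nrh(I_inc, Jmax, kappa2LL, theta_J)
    KmCO = KmC * (1.0 + O / KmO)

    def net_rate(Cc):
        Ac = (Cc - Gamma_star) * Vcmax / (Cc + KmCO) - Rd
        Aj = (Cc - Gamma_star) * J / (4.0 * (Cc + 2.0 * Gamma_star)) - Rd
        A = np.minimum(Ac, Aj)
        if tpu_active:
            den = Cc - (1.0 + 4.0 * alpha_S) * Gamma_star
            Ap = np.where(den > 0, (Cc - Gamma_star) * 3.0 * Tp / np.where(den > 0, den, 1.0) - Rd, np.inf)
            A = np.minimum(A, Ap)
        return A

    def residual(Cc):
        A = net_rate(Cc)
        gs = _gs_arrays(A, Ca, VPD, Gamma_star, g0, a1, D0, gs_multiplier)
        return Ca - Cc - A * (1.0 / gm + 1.0 / gs), A, gs

    # Dark / non-positive assimilation branch: by convention Cc = Ci = Ca.
    A_at_ca = net_rate(Ca)
    dark = A_at_ca <= 0.0

    lo = np.full_like(Ca, 1e-6)
    hi = Ca.copy()
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        f_mid, _, _ = residual(mid)
        take_hi = f_mid > 0
        lo = np.where(take_hi, mid, lo)
        hi = np.where(take_hi, hi, mid)
    Cc = 0.5 * (lo + hi)
    Cc = np.where(dark, Ca, Cc)
    A = net_rate(Cc)
    gs = _gs_arrays(A, Ca, VPD, Gamma_star, g0, a1, D0, gs_multiplier)
    Ci = np.where(dark, Ca, Ca - A / gs)

    Ac = (Cc - Gamma_star) * Vcmax / (Cc + KmCO) - Rd
    Aj = (Cc - Gamma_star) * J / (4.0 * (Cc + 2.0 * Gamma_star)) - Rd
    if tpu_active:
        den = Cc - (1.0 + 4.0 * alpha_S) * Gamma_star
        Ap = np.where(den > 0, (Cc - Gamma_star) * 3.0 * Tp / np.where(den > 0, den, 1.0) - Rd, np.inf)
    else:
        Ap = np.full_like(Ac, np.inf)
    Amin = np.minimum(np.minimum(Ac, Aj), Ap)
    # tie-break prefers the electron tag (exact ties occur at Cc = Gamma*)
    limitation = np.where(Aj <= Amin + 1e-12, 1, np.where(Ac <= Amin + 1e-12, 0, 2))
    return {"A": A, "Ci": Ci, "Cc": Cc, "J": J, "gs": gs, "limitation": limitation, "Rd": Rd}


def solve_coupled(env: AirEnv, p: LeafBiochem, c: Conductances) -> LeafFlux:
    """Self-consistent (A, Ci, Cc, gs, J) for a single leaf.

    The returned state satisfies the diffusion identity
    |Ca - Cc - A (1/gm + 1/gs)| < 1e-6 ubar (unless the dark convention
    Cc = Ci = Ca applies) and A = min(Ac, Aj, Ap) at the returned Cc.
    """
    pT = temperature_adjust(p, env.T_leaf)
    out = solve_coupled_arrays(
        env.I_inc, env.Ca, env.O, env.VPD,
        pT.Vcmax, pT.Jmax, pT.Tp, pT.Rd, c.gm, pT.Gamma_star, pT.KmC, pT.KmO,
        alpha_S=p.alpha_S, theta_J=p.theta_J, kappa2LL=p.kappa2LL,
        tpu_active=p.tpu_active, g0=c.g0, a1=c.a1, D0=c.D0,
        gs_multiplier=c.gs_multiplier, n_iter=48,
    )
    A = float(out["A"])
    Cc = float(out["Cc"])
    if not (A <= 0.0 and Cc == env.Ca):
        resid = env.Ca - Cc - A * (1.0 / c.gm + 1.0 / float(out["gs"]))
        if abs(resid) > 1e-5:
            raise RuntimeError(
                f"coupled leaf solver did not converge (residual {resid:.2e} ubar) "
                f"for Ca={env.Ca}, I={env.I_inc}, Vcmax={pT.Vcmax:.1f}"
            )
    return LeafFlux(
        A=A,
        Ci=float(out["Ci"]),
        Cc=Cc,
        J=float(out["J"]),
        gs=float(out["gs"]),
        limitation=_LIMITATION_NAMES[int(out["limitation"])],
    )


def a_max(env_sat: AirEnv, p: LeafBiochem, c: Conductances) -> LeafFlux:
    """Light-saturated net assimilation (requires saturating incident PAR)."""
    if env_sat.I_inc < 1800.0:
        raise ValueError("a_max requires saturating light (I_inc >= 1800 umol m-2 s-1)")
    return solve_coupled(env_sat, p, c)
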