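"""Solar geometry, light/nitrogen profiles and multilayer canopy integration."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.integrate import quad

import ruesim as rs
from ruesim.canopy import gm_from_sln, intercepted_par_instant
from ruesim.leaf import solve_coupled_arrays, temperature_factors
from ruesim.solar import daylength_hours, solar_elevation

LAT = 14.2


# --------------------------------------------------------------------------
# solar geometry
# --------------------------------------------------------------------------

@pytest.mark.parametrize("latitude", [0.0, 14.2, 45.0])
def test_equinox_daylength(latitude):
    assert daylength_hours(latitude, 81) == pytest.approx(12.0, abs=0.1)


def test_solstice_noon_elevation():
    """Closed-form declination check at the June solstice."""
    sun = rs.solar_geometry(172, LAT, 12.0, 20.0)
    assert math.degrees(sun.elevation) == pytest.approx(90 - abs(LAT - 23.45), abs=0.5)


def test_diurnal_par_integral_recovers_daily_par():
    """Instantaneous PAR integrates to par_fraction x daily shortwave (<1%)."""
    srad = 18.0
    hours = np.linspace(0, 24, 4801)
    par = np.array(
        [
            (rs.solar_geometry(100, LAT, h, srad).par_direct
             + rs.solar_geometry(100, LAT, h, srad).par_diffuse)
            for h in hours
        ]
    )  # umol m-2 s-1
    integral_mj = np.trapezoid(par, hours * 3600.0) / 4.56 / 1e6
    assert integral_mj == pytest.approx(0.5 * srad, rel=0.01)


def test_polar_case_rejected():
    with pytest.raises(ValueError):
        rs.solar_geometry(172, 70.0, 12.0, 20.0)


def test_night_par_is_zero():
    sun = rs.solar_geometry(100, LAT, 2.0, 18.0)
    assert sun.par_direct == 0.0 and sun.par_diffuse == 0.0


# --------------------------------------------------------------------------
# light and nitrogen profiles
# --------------------------------------------------------------------------

def test_light_at_depth_values():
    assert rs.light_at_depth(1000.0, 0.65, 0.0) == pytest.approx(1000.0)
    assert rs.light_at_depth(1000.0, 0.65, 1.0) == pytest.approx(522.05, abs=0.1)
    interception = 1.0 - rs.light_at_depth(1.0, 0.65, 6.0)
    assert interception == pytest.approx(0.980, abs=0.001)


def test_kl_spherical_limit():
    """A ~57 deg canopy with the sun overhead has kL ~ 0.5 (black leaves)."""
    kl = rs.kl_from_leaf_angle(57.3, math.radians(90.0))
    assert kl == pytest.approx(0.5, rel=0.1)


def test_kl_monotone_in_leaf_angle():
    # monotone for high sun; at low elevations erect canopies intercept
    # oblique beams efficiently and the relation genuinely reverses
    angles = np.linspace(10.0, 85.0, 40)
    for elev_deg in (60.0, 90.0):
        kls = [rs.kl_from_leaf_angle(a, math.radians(elev_deg)) for a in angles]
        assert np.all(np.diff(kls) < 0)  # more erect -> smaller kL
    assert rs.kl_from_leaf_angle(52.0, 1.0) >= rs.kl_from_leaf_angle(65.0, 1.0)
    assert rs.representative_kl(52.0) > rs.representative_kl(65.0)


def test_n_at_depth_values():
    assert rs.n_at_depth(2.0, 0.3, 0.52, 0.0) == pytest.approx(2.0)
    assert rs.n_at_depth(2.0, 0.3, 0.0, 3.0) == pytest.approx(2.0)  # uniform
    assert rs.n_at_depth(2.0, 0.3, 0.52, 3.0) == pytest.approx(0.6572, abs=2e-4)


def test_n0_from_budget_uniform_limit_and_roundtrip():
    nb, GAI = 0.3, 6.0
    assert rs.n0_from_budget(5.1, GAI, 0.0, nb) == pytest.approx(nb + 5.1 / GAI)
    # inverse property checked against numerical quadrature of the profile
    for kN, N in [(0.52, 5.1), (0.3, 2.0), (0.8, 8.0)]:
        n0 = float(rs.n0_from_budget(N, GAI, kN, nb))
        integral, _ = quad(lambda L: (n0 - nb) * np.exp(-kN * L), 0.0, GAI)
        assert integral == pytest.approx(N, rel=1e-3)
    assert rs.n0_from_budget(-1.0, GAI, 0.5, nb) == pytest.approx(nb)


def test_biochem_from_sln_slopes(cfg):
    profile = rs.make_profile(cfg.canopy, 1.0, 1.0, 1.7)
    base = cfg.leaf
    at_nb = rs.biochem_from_sln(cfg.canopy.nb, profile, base)
    assert at_nb.Vcmax == at_nb.Jmax == at_nb.Tp == at_nb.Rd == 0.0
    p = rs.biochem_from_sln(cfg.canopy.nb + 1.2, profile, base)
    assert p.Jmax == pytest.approx(cfg.canopy.chi_Jmax * 1.2)
    assert p.Vcmax == pytest.approx(cfg.canopy.chi_Vcmax * 1.2)
    assert p.Tp == pytest.approx(cfg.canopy.chi_Tp * 1.2)
    assert gm_from_sln(cfg.canopy.nb + 1.2, profile) == pytest.approx(cfg.canopy.chi_gm * 1.2)
    # baseline capacity slopes of the study conditions
    assert (cfg.canopy.chi_Vcmax, cfg.canopy.chi_Jmax, cfg.canopy.chi_Tp, cfg.canopy.chi_gm) == (
        75.0, 100.0, 5.0, 0.125,
    )


# --------------------------------------------------------------------------
# instantaneous canopy assimilation
# --------------------------------------------------------------------------

def _midday_sun(srad=20.0, doy=100):
    return rs.solar_geometry(doy, LAT, 12.0, srad)


def test_canopy_instant_zero_gai(cfg):
    profile = rs.make_profile(cfg.canopy, 0.0, 1.0, 0.0)
    gross, net = rs.canopy_A_instant(profile, _midday_sun(), rs.AirEnv(), cfg.leaf, cfg.cond, cfg.canopy)
    assert gross == 0.0 and net == 0.0


def test_canopy_instant_night_respiration(cfg):
    """With PAR = 0, net canopy A equals minus the integrated layer Rd."""
    profile = rs.make_profile(cfg.canopy, 4.0, 0.8, 4.0)
    night = rs.SolarInstant(elevation=-0.1, par_direct=0.0, par_diffuse=0.0, daylength=12.0)
    env = rs.AirEnv(I_inc=0.0, T_leaf=24.0, VPD=0.5)
    gross, net = rs.canopy_A_instant(profile, night, env, cfg.leaf, cfg.cond, cfg.canopy)
    assert gross == pytest.approx(0.0, abs=1e-9)
    # independent dense integral of the Rd profile
    fT = float(temperature_factors(cfg.leaf, 24.0)["Rd"])
    eff = 0.8 + 0.2 * cfg.canopy.nonleaf_efficiency
    kN = profile.kN

    def rd_at(L):
        n = (profile.n0 - profile.nb) * np.exp(-kN * 0.8 * L) + profile.nb
        return cfg.leaf.rd_vcmax_ratio * cfg.canopy.chi_Vcmax * (n - profile.nb) * fT

    expected, _ = quad(rd_at, 0.0, 4.0)
    assert net == pytest.approx(-expected * eff, rel=0.01)


def _dense_reference(profile, sun, env, base, cond, cfg, nlayer=500):
    """Trapezoid-rule canopy integral over many layers (quadrature oracle)."""
    sigma = profile.scattering
    sq = math.sqrt(1.0 - sigma)
    kb_black = rs.kl_from_leaf_angle(profile.leaf_angle, max(sun.elevation, math.radians(0.5)))
    kb = kb_black * sq
    kd = profile.kL_rep
    GAI = float(profile.GAI)
    L = np.linspace(0.0, GAI, nlayer)
    n_i = rs.n_at_depth(profile.n0, profile.nb, profile.kN, L * float(profile.leaf_fraction))
    dn = np.maximum(n_i - profile.nb, 0.0)
    fT = temperature_factors(base, env.T_leaf)
    fsun = np.exp(-kb_black * L)
    Ib, Id = sun.par_direct, sun.par_diffuse
    q_sh = Id * kd * np.exp(-kd * L) + Ib * (kb * np.exp(-kb * L) - kb_black * (1 - sigma) * np.exp(-kb_black * L))
    q_sh = np.maximum(q_sh, 0.0)
    q_sun = q_sh + kb_black * (1 - sigma) * Ib
    out = []
    for q in (q_sun, q_sh):
        sol = solve_coupled_arrays(
            q / base.beta, env.Ca, env.O, env.VPD,
            profile.chi_Vcmax * dn * fT["Vcmax"], profile.chi_Jmax * dn * fT["Jmax"],
            profile.chi_Tp * dn * fT["Tp"], base.rd_vcmax_ratio * profile.chi_Vcmax * dn * fT["Rd"],
            np.maximum(profile.chi_gm * dn, 1e-9),
            base.Gamma_star * fT["Gamma_star"], base.KmC * fT["KmC"], base.KmO * fT["KmO"],
            alpha_S=base.alpha_S, theta_J=base.theta_J, kappa2LL=base.kappa2LL,
            tpu_active=base.tpu_active, g0=cond.g0, a1=cond.a1, D0=cond.D0,
            gs_multiplier=cond.gs_multiplier,
        )
        out.append(sol["A"])
    A_sun, A_sh = out
    eff = float(profile.leaf_fraction) + (1 - float(profile.leaf_fraction)) * profile.nonleaf_efficiency
    integrand = (fsun * A_sun + (1 - fsun) * A_sh) * eff
    return float(np.trapezoid(integrand, L))


def test_gauss_vs_dense_trapezoid(cfg):
    """5-point Gaussian depth quadrature agrees with a 500-layer trapezoid."""
    rng = np.random.default_rng(7)
    for _ in range(8):
        GAI = rng.uniform(1.0, 7.0)
        N = rng.uniform(0.5, 5.5)
        lf = rng.uniform(0.6, 1.0)
        profile = rs.make_profile(cfg.canopy, GAI, lf, N)
        sun = rs.solar_geometry(int(rng.integers(20, 140)), LAT, rng.uniform(8, 16), rng.uniform(8, 26))
        if sun.par_direct + sun.par_diffuse <= 0:
            continue
        env = rs.AirEnv(T_leaf=rng.uniform(22, 33), VPD=rng.uniform(0.4, 2.5))
        gross, net = rs.canopy_A_instant(profile, sun, env, cfg.leaf, cfg.cond, cfg.canopy)
        dense_net = _dense_reference(profile, sun, env, cfg.leaf, cfg.cond, cfg.canopy)
        assert net == pytest.approx(dense_net, rel=0.01, abs=0.05)


def test_energy_bookkeeping(cfg):
    """Layer-absorbed PAR sums to the closed-form component interception."""
    profile = rs.make_profile(cfg.canopy, 5.0, 0.8, 4.0)
    sun = _midday_sun()
    nodes, w = np.polynomial.legendre.leggauss(5)
    L = 0.5 * (nodes + 1.0) * 5.0
    wL = 0.5 * w * 5.0
    sq = math.sqrt(1.0 - profile.scattering)
    kb_black = rs.kl_from_leaf_angle(profile.leaf_angle, sun.elevation)
    kb, kd = kb_black * sq, profile.kL_rep
    q_sh = sun.par_diffuse * kd * np.exp(-kd * L) + sun.par_direct * (
        kb * np.exp(-kb * L) - kb_black * (1 - profile.scattering) * np.exp(-kb_black * L)
    )
    fsun = np.exp(-kb_black * L)
    q_tot = q_sh + fsun * kb_black * (1 - profile.scattering) * sun.par_direct
    absorbed = float((q_tot * wL).sum())
    expected = intercepted_par_instant(profile, sun)
    assert absorbed == pytest.approx(expected, rel=0.01)


# --------------------------------------------------------------------------
# daily integration
# --------------------------------------------------------------------------

def _day(srad=22.0, doy=100, tmax=32.0, tmin=23.0, rh=75.0):
    return {"doy": doy, "srad": srad, "tmax": tmax, "tmin": tmin, "rh": rh}


def test_daily_zero_gai_intercepts_nothing(cfg):
    profile = rs.make_profile(cfg.canopy, 0.0, 1.0, 0.0)
    res = rs.canopy_A_daily(profile, _day(), LAT, cfg.leaf, cfg.cond, cfg.canopy)
    assert float(res["par_int"][0]) == 0.0
    assert float(res["gross"][0]) == 0.0


def test_daily_thin_canopy_interception_scales_linearly(cfg):
    p1 = rs.make_profile(cfg.canopy, 0.1, 1.0, 0.2)
    p2 = rs.make_profile(cfg.canopy, 0.2, 1.0, 0.4)
    r1 = rs.canopy_A_daily(p1, _day(), LAT, cfg.leaf, cfg.cond, cfg.canopy)
    r2 = rs.canopy_A_daily(p2, _day(), LAT, cfg.leaf, cfg.cond, cfg.canopy)
    assert float(r2["par_int"][0]) / float(r1["par_int"][0]) == pytest.approx(2.0, rel=0.05)


def test_daily_gross_plausible_closed_canopy(cfg):
    """Clear-day gross assimilation of a closed baseline canopy: 30-80 g CO2."""
    profile = rs.make_profile(cfg.canopy, 5.5, 0.75, 4.5)
    res = rs.canopy_A_daily(profile, _day(srad=24.0), LAT, cfg.leaf, cfg.cond, cfg.canopy)
    assert 30.0 < float(res["gross"][0]) < 80.0


def test_daily_interception_consistent_with_beer_lambert(cfg):
    """Daily intercepted PAR matches the closed-form fraction within 2%."""
    profile = rs.make_profile(cfg.canopy, 4.0, 1.0, 3.5)
    day = _day(srad=16.0)
    res = rs.canopy_A_daily(profile, day, LAT, cfg.leaf, cfg.cond, cfg.canopy)
    par_available = 0.5 * day["srad"]
    frac = float(res["par_int"][0]) / par_available
    # bracketing closed forms with the diffuse and a midday beam coefficient
    kd = profile.kL_rep
    f_kd = 1.0 - math.exp(-kd * 4.0)
    assert abs(frac - f_kd) / f_kd < 0.10  # beam/diffuse mix stays near kd


def test_daily_batched_equals_loop(cfg):
    """Vectorized year axis gives the same answers as one-by-one calls."""
    profile = rs.make_profile(
        cfg.canopy, np.array([2.0, 5.0]), np.array([0.8, 0.9]), np.array([1.5, 4.0])
    )
    day = {"doy": 80, "srad": np.array([14.0, 22.0]), "tmax": np.array([30.0, 33.0]),
           "tmin": np.array([22.0, 24.0]), "rh": np.array([85.0, 70.0])}
    res = rs.canopy_A_daily(profile, day, LAT, cfg.leaf, cfg.cond, cfg.canopy)
    for iy in range(2):
        p1 = rs.make_profile(cfg.canopy, 2.0 if iy == 0 else 5.0, 0.8 if iy == 0 else 0.9,
                             1.5 if iy == 0 else 4.0)
        d1 = {k: (v if k == "doy" else float(v[iy])) for k, v in day.items()}
        r1 = rs.canopy_A_daily(p1, d1, LAT, cfg.leaf, cfg.cond, cfg.canopy)
        assert float(res["gross"][iy]) == pytest.approx(float(r1["gross"][0]), rel=1e-12)


# --------------------------------------------------------------------------
# nitrogen-profile optimality
# --------------------------------------------------------------------------

def test_optimal_kn_near_kl_diffuse_linear_case(cfg):
    """With nb = 0 and diffuse-only light the optimal kN sits near kL."""
    can = dataclasses.replace(cfg.canopy, nb=0.0)
    profile = rs.make_profile(can, 5.0, 1.0, 5.0)
    grid = np.arange(0.30, 0.85, 0.05)
    kn_opt, gains = rs.optimal_kN_scan(
        profile, _day(srad=15.0), LAT, cfg.leaf, cfg.cond, grid, can, force_diffuse=True
    )
    assert abs(kn_opt - profile.kL_rep) <= 0.05 + 1e-9
    # uniform N never beats the optimum
    uniform = rs.optimal_kN_scan(
        profile, _day(srad=15.0), LAT, cfg.leaf, cfg.cond, [1e-9], can, force_diffuse=True
    )[1][0]
    assert uniform <= gains.max() + 1e-9


def test_daily_gross_non_decreasing_toward_optimal_ratio(cfg):
    """Raising kN:kL from 0.8 toward 1.0 never hurts in the diffuse case."""
    can = dataclasses.replace(cfg.canopy, nb=0.0)
    gains = []
    for ratio in (0.8, 0.9, 1.0):
        can_r = dataclasses.replace(can, kN_ratio=ratio)
        profile = rs.make_profile(can_r, 5.0, 1.0, 5.0)
        res = rs.canopy_A_daily(profile, _day(srad=15.0), LAT, cfg.leaf, cfg.cond, can_r,
                                force_diffuse=True)
        gains.append(float(res["gross"][0]))
    assert gains[0] <= gains[1] + 1e-9 <= gains[2] + 2e-9
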