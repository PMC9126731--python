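"""Trait-perturbation experiment: scenario catalogue, baseline calibration,
multi-year batch runs and percent-advantage accounting.

The catalogue contains the baseline, twelve single-trait improvements
(each parameter moved 20% in its favourable direction, except the PSII
efficiency which is raised to its ~0.85 physiological ceiling and the
TPU limitation which is simply removed) and six stacked combinations.
All scenarios are run on the same weather years (common random numbers),
and advantages are computed on multi-year means:

    advantage% = 100 x (mean_scenario - mean_baseline) / mean_baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .config import Configs
from .season import run_seasons
from .weather import WeatherSeries

__all__ = [
    "ScenarioSpec",
    "AdvantageTable",
    "build_scenarios",
    "apply_overrides",
    "calibrate_baseline",
    "run_experiment",
    "synergy_metrics",
]

# an override is (attribute path, mode, value); mode "set" or "scale"
Override = tuple[str, str, float | bool]


@dataclass
class ScenarioSpec:
    id: str
    label: str
    overrides: list[Override] = field(default_factory=list)
    members: list[str] = field(default_factory=list)


_SINGLE_TRAITS: dict[str, tuple[str, list[Override]]] = {
    "T1": ("chi_Vcmax 75->90", [("canopy.chi_Vcmax", "set", 90.0)]),
    "T2": ("chi_Jmax 100->120", [("canopy.chi_Jmax", "set", 120.0)]),
    "T3": ("Phi2LL 0.78->0.85", [("leaf.Phi2LL", "set", 0.85)]),
    "T4": ("gs x1.2", [("cond.gs_multiplier", "scale", 1.2)]),
    "T5": ("chi_gm 0.125->0.150", [("canopy.chi_gm", "set", 0.150)]),
    "T6": ("TPU limitation removed", [("leaf.tpu_active", "set", False)]),
    "T7": ("leaf angle 65->52 (early)", [("canopy.leaf_angle_early", "set", 52.0)]),
    "T8": ("kN:kL 0.80->0.96", [("canopy.kN_ratio", "set", 0.96)]),
    "T9": ("stay-green (remobilization x0.8)", [("season.staygreen_factor", "set", 0.8)]),
    "T10": ("SLA 0.030->0.036 (early)", [("season.SLA_early", "set", 0.036)]),
    "T11": (
        "non-leaf photosynthesis +20%",
        [
            ("canopy.nonleaf_area_ratio", "scale", 1.2),
            ("canopy.nonleaf_efficiency", "scale", 1.2),
        ],
    ),
    "T12": ("Numax 20->24", [("season.Numax", "set", 24.0)]),
}

_COMBINATIONS: dict[str, tuple[str, list[str]]] = {
    "C2-6": ("photosynthetic traits 2-6", ["T2", "T3", "T4", "T5", "T6"]),
    "C8-9-11": ("morpho-physiological traits 8, 9, 11", ["T8", "T9", "T11"]),
    "C2-6+8-9-11": (
        "traits 2-6 plus 8, 9, 11",
        ["T2", "T3", "T4", "T5", "T6", "T8", "T9", "T11"],
    ),
    "C2-6+12": ("traits 2-6 plus Numax", ["T2", "T3", "T4", "T5", "T6", "T12"]),
    "C8-9-11+12": ("traits 8, 9, 11 plus Numax", ["T8", "T9", "T11", "T12"]),
    "Call": (
        "traits 2-6, 8, 9, 11 plus Numax",
        ["T2", "T3", "T4", "T5", "T6", "T8", "T9", "T11", "T12"],
    ),
}


def build_scenarios() -> list[ScenarioSpec]:
    """Baseline + 12 single-trait + 6 combination scenarios (19 in total)."""
    out = [ScenarioSpec(id="baseline", label="baseline", overrides=[], members=[])]
    for sid, (label, ov) in _SINGLE_TRAITS.items():
        out.append(ScenarioSpec(id=sid, label=label, overrides=list(ov), members=[sid]))
    for cid, (label, members) in _COMBINATIONS.items():
        ov: list[Override] = []
        for m in members:
            ov.extend(_SINGLE_TRAITS[m][1])
        out.append(ScenarioSpec(id=cid, label=label, overrides=ov, members=list(members)))
    return out


def apply_overrides(cfg: Configs, overrides: list[Override]) -> Configs:
    """Return a copy of ``cfg`` with the scenario overrides applied."""
    out = cfg.copy()
    for path, mode, value in overrides:
        block_name, attr = path.split(".")
        block = getattr(out, block_name)
        if not hasattr(block, attr):
            raise KeyError(f"unknown parameter path: {path}")
        if mode == "set":
            new_val = value
        elif mode == "scale":
            new_val = getattr(block, attr) * value
        else:
            raise ValueError(f"unknown override mode: {mode}")
        if block_name == "leaf":
            setattr(out, block_name, block.replace(**{attr: new_val}))
        else:
            setattr(block, attr, new_val)
    return out


def calibrate_baseline(
    cfg: Configs,
    weather: WeatherSeries,
    latitude: float | None = None,
    target_rue: float = 2.57,
    target_biomass: float = 19.6,
    free_coeffs: tuple[str, str] = ("f_resp", "f_leaf"),
    bounds: dict | None = None,
    tol: float = 0.02,
) -> Configs:
    """One-time calibration of the declared free season coefficients.

    Minimizes the sum of squared relative errors of the multi-year mean
    (RUE, biomass) against the anchors with Nelder-Mead on logit-transformed
    coefficients.  Raises if the converged baseline misses either anchor by
    more than ``tol`` (relative).  The returned config is frozen: scenario
    runs must not re-calibrate.
    """
    bounds = bounds or {"f_resp": (0.05, 0.60), "f_leaf": (0.15, 0.95)}

    def to_unit(name: str, v: float) -> float:
        lo, hi = bounds[name]
        u = (v - lo) / (hi - lo)
        u = min(max(u, 1e-6), 1 - 1e-6)
        return math.log(u / (1 - u))

    def from_unit(name: str, x: float) -> float:
        lo, hi = bounds[name]
        return lo + (hi - lo) / (1.0 + math.exp(-x))

    def make_cfg(x) -> Configs:
        trial = cfg.copy()
        for name, xi in zip(free_coeffs, x):
            setattr(trial.season, name, from_unit(name, float(xi)))
        return trial

    def objective(x) -> float:
        res = run_seasons(make_cfg(x), weather, latitude)
        rue = float(np.mean(res.RUE))
        biomass = float(np.mean(res.biomass))
        return ((rue - target_rue) / target_rue) ** 2 + (
            (biomass - target_biomass) / target_biomass
        ) ** 2

    x0 = [to_unit(n, getattr(cfg.season, n)) for n in free_coeffs]
    opt = optimize.minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-8, "maxiter": 200},
    )
    calibrated = make_cfg(opt.x)
    res = run_seasons(calibrated, weather, latitude)
    rue = float(np.mean(res.RUE))
    biomass = float(np.mean(res.biomass))
    if abs(rue - target_rue) / target_rue > tol or abs(biomass - target_biomass) / target_biomass > tol:
        raise RuntimeError(
            f"calibration did not converge within {tol:.0%}: "
            f"RUE {rue:.3f} vs {target_rue}, biomass {biomass:.2f} vs {target_biomass} "
            f"(residual {opt.fun:.3e})"
        )
    return calibrated


@dataclass
class AdvantageTable:
    """Per-scenario multi-year means and percent advantages vs baseline."""

    table: pd.DataFrame
    baseline_rue: float
    baseline_biomass: float

    def advantage(self, scenario_id: str, quantity: str = "biomass") -> float:
        row = self.table.loc[self.table["id"] == scenario_id]
        if row.empty:
            raise KeyError(f"unknown scenario id: {scenario_id}")
        return float(row[f"{quantity}_advantage_pct"].iloc[0])

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index=False, float_format="%.4f")

    def to_text(self) -> str:
        cols = ["id", "label", "rue_advantage_pct", "biomass_advantage_pct"]
        return self.table[cols].to_string(index=False, float_format=lambda v: f"{v:7.2f}")


def run_experiment(
    scenarios: list[ScenarioSpec],
    cfg: Configs,
    weather: WeatherSeries,
    latitude: float | None = None,
) -> AdvantageTable:
    """Run every scenario over the same weather years; advantages on means."""
    base_res = run_seasons(cfg, weather, latitude)
    base_rue = float(np.mean(base_res.RUE))
    base_biomass = float(np.mean(base_res.biomass))
    rows = []
    for sc in scenarios:
        if sc.id == "baseline":
            rue, biomass = base_rue, base_biomass
        else:
            res = run_seasons(apply_overrides(cfg, sc.overrides), weather, latitude)
            rue = float(np.mean(res.RUE))
            biomass = float(np.mean(res.biomass))
        rows.append(
            {
                "id": sc.id,
                "label": sc.label,
                "members": "+".join(sc.members),
                "rue": rue,
                "biomass": biomass,
                "rue_advantage_pct": 100.0 * (rue - base_rue) / base_rue,
                "biomass_advantage_pct": 100.0 * (biomass - base_biomass) / base_biomass,
            }
        )
    return AdvantageTable(
        table=pd.DataFrame(rows), baseline_rue=base_rue, baseline_biomass=base_biomass
    )


def synergy_metrics(table: AdvantageTable) -> pd.DataFrame:
    """Combined vs sum-of-members advantage for every combination scenario."""
    df = table.table
    rows = []
    for _, row in df.iterrows():
        members = [m for m in row["members"].split("+") if m and m != row["id"]]
        if len(members) < 1 or row["id"] in _SINGLE_TRAITS or row["id"] == "baseline":
            continue
        rec = {"id": row["id"], "label": row["label"]}
        for q in ("rue", "biomass"):
            combined = row[f"{q}_advantage_pct"]
            member_sum = float(
                df.loc[df["id"].isin(members), f"{q}_advantage_pct"].sum()
            )
            rec[f"{q}_combined_pct"] = combined
            rec[f"{q}_member_sum_pct"] = member_sum
            rec[f"{q}_synergy_pct"] = combined - member_sum
        rows.append(rec)
    return pd.DataFrame(rows)
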