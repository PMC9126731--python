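# ruesim

Leaf-to-canopy-to-season photosynthesis simulation for trait-ideotype
analysis of crop radiation-use efficiency (RUE).

A recurring question in crop physiology is which photosynthesis-related
traits are actually worth breeding for: the light-saturated capacity that
is easiest to measure, the electron-transport parameters that govern most
leaves most of the day, the CO2-diffusion conductances, or the
canopy-level traits — nitrogen profiles, stay-green, non-leaf
photosynthesis, early vigour — that set how a whole stand uses light over
a season. `ruesim` answers this the way crop modellers do: with a
mechanistic simulator that scales the Farquhar–von Caemmerer–Berry (FvCB)
leaf model to a multilayer canopy and a daily-stepping season, and a
perturbation experiment that improves each trait by 20% (alone and in
stacks) and reports the percent advantage in season biomass and RUE over
a calibrated high-yielding lowland-rice baseline.

The core pieces:

- **Leaf** (`ruesim.leaf`): net assimilation
  `A = min(Ac, Aj, Ap)` of the Rubisco-, electron-transport- and
  TPU-limited rates, with quantum-yield decomposition
  (Φ_CO2, Φ_2LL, κ_2LL), coupled to
  `Cc = Ca − A (1/gm + 1/gs)` via a Ball–Berry–Leuning stomatal model
  and solved self-consistently by bisection on Cc.
- **Canopy** (`ruesim.canopy`, `ruesim.solar`): Beer–Lambert light
  profiles `I_i = I_0 e^(−kL·L)` with ellipsoidal leaf-angle extinction
  and sunlit/shaded layers, exponential nitrogen profiles
  `n_i = (n_0 − n_b) e^(−kN·L) + n_b` with capacities linear in leaf N,
  5-point Gaussian integration over depth and the diurnal course.
- **Season** (`ruesim.season`): sigmoid N uptake, carbon–nitrogen
  co-limited green-area expansion, sink-driven grain-N remobilization
  and senescence (stay-green), exact mass/N ledgers, biomass in t/ha and
  RUE in g biomass per MJ intercepted PAR.
- **Weather** (`ruesim.weather`): a seeded synthetic generator for a
  lowland tropical climate (14.2°N), plus a plain CSV reader/writer.
- **Experiment** (`ruesim.scenarios`): the 19-scenario catalogue
  (baseline, 12 single traits, 6 combinations), one-time baseline
  calibration to the anchors (RUE 2.57 g MJ⁻¹, biomass 19.6 t ha⁻¹),
  31-year batch runs and synergy diagnostics.

See `docs/methods.md` for the model description and assumptions.

## Worked example

```python
import dataclasses
import ruesim as rs

# a single top leaf at 2.0 g N m-2 under bright midday conditions
cfg = rs.default_configs()
profile = rs.make_profile(cfg.canopy, GAI=1.0, leaf_fraction=1.0, N_canopy=1.7)
leaf = rs.biochem_from_sln(2.0, profile, cfg.leaf)
cond = dataclasses.replace(cfg.cond, gm=cfg.canopy.chi_gm * 1.7)
flux = rs.solve_coupled(rs.AirEnv(I_inc=1500, T_leaf=28, VPD=1.5), leaf, cond)
print(f"A = {flux.A:.1f} umol m-2 s-1 ({flux.limitation}-limited), "
      f"Ci = {flux.Ci:.0f}, Cc = {flux.Cc:.0f} ubar, gs(H2O) = {flux.gs_water:.2f}")

# the full trait experiment on 31 synthetic years
weather = rs.generate_weather(rs.ClimateSpec(seed=1))
cal = rs.calibrate_baseline(rs.default_configs(), weather)
table = rs.run_experiment(rs.build_scenarios(), cal, weather)
print(f"baseline: {table.baseline_biomass:.1f} t/ha, RUE {table.baseline_rue:.2f} g/MJ")
print(table.to_text())
```

prints (a few minutes; the calibration alone runs ~60 season batches):

```
A = 22.9 umol m-2 s-1 (electron-limited), Ci = 332, Cc = 224 ubar, gs(H2O) = 0.76
baseline: 19.6 t/ha, RUE 2.57 g/MJ
         id                                label  rue_advantage_pct  biomass_advantage_pct
   baseline                             baseline               0.00                   0.00
         T1                     chi_Vcmax 75->90               0.25                   0.28
         T2                    chi_Jmax 100->120               4.56                   5.08
         T3                    Phi2LL 0.78->0.85               3.58                   3.96
         T4                              gs x1.2               1.03                   1.14
         T5                  chi_gm 0.125->0.150               1.71                   1.91
         T6               TPU limitation removed               0.00                   0.00
         T7            leaf angle 65->52 (early)              -0.83                   0.17
         T8                     kN:kL 0.80->0.96               0.99                   1.14
         T9     stay-green (remobilization x0.8)               1.20                   3.06
        T10             SLA 0.030->0.036 (early)              -0.97                  -0.20
        T11         non-leaf photosynthesis +20%               1.32                   3.87
        T12                         Numax 20->24               7.26                  14.86
       C2-6            photosynthetic traits 2-6              12.90                  14.26
    C8-9-11 morpho-physiological traits 8, 9, 11               3.99                   8.34
C2-6+8-9-11             traits 2-6 plus 8, 9, 11              17.81                  23.74
    C2-6+12                traits 2-6 plus Numax              21.27                  30.91
 C8-9-11+12           traits 8, 9, 11 plus Numax              11.28                  22.13
       Call      traits 2-6, 8, 9, 11 plus Numax              25.92                  38.98
```

Reading it: the leaf operates electron-transport-limited at 1500
µmol m⁻² s⁻¹ — which is why raising the Jmax-per-nitrogen slope (T2,
+5.1% biomass) beats raising the Rubisco slope (T1, +0.3%); season-long
nitrogen uptake (T12, +14.9%) dwarfs every single photosynthetic trait;
thinner early leaves (T10) cost a little biomass through nitrogen
dilution; and stacking all nine improvements yields +39% biomass —
more than the +35% sum of its parts, i.e. the traits are synergistic.

## Command line

```bash
ruesim weather --seed 1 --years 31 --out weather.csv   # synthetic climate
ruesim leaf --par 1500 --sln 2.0                       # single-leaf CSV
ruesim calibrate --weather-csv weather.csv --out cal.yaml
ruesim simulate  --weather-csv weather.csv --config cal.yaml --trace-out trace.csv
ruesim table1    --weather-csv weather.csv --config cal.yaml   # full experiment
```

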