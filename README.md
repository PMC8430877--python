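# ppas — passive air sampler exposure toolkit

`ppas` estimates personal exposure to chlorine gas from a wearable passive
air sampler: a PDMS patch doped with the redox dye o-dianisidine. Chlorine
diffusing into the patch oxidizes the dye irreversibly, so the dye consumed
over a deployment is a pump-free record of cumulative uptake. The package
is aimed at exposure scientists who want to turn sampler extraction
chemistry into time-weighted-average (TWA) concentrations and CT dose
metrics, and at anyone studying the sampler's kinetics.

It provides:

- **Uptake model** (`ppas.sampler_model`) — a two-resistance
  diffusion–reaction model with finite dye capacity:
  `F_diffusion = k_O·A_s·(C_A − c_free/K_SA)`,
  `F_reaction = k_reac·A_s·c_free/δ·g(r)`, integrated as a stiff two-state
  ODE. It reproduces the sampler's early linear uptake (slope
  `k_O·A_s·C_A/V_s`) and its plateau at the dye capacity
  `C_cap = 1.8 mol m⁻³`.
- **Exposure estimation** (`ppas.exposure`) — extraction chemistry to TWA:
  `C_s = (C_i − C_f)·V_E/(M_w·V_s·stoich)` and
  `C_v,TWA = C_s·V_s/(R_s·t)` with `R_s = 2.53e-3 m³ h⁻¹`, plus CT values
  (ppbv·min), guideline flags (PEL / AEGL-1, 500 ppbv) and saturation
  warnings.
- **Reference instrument series** (`ppas.ptrms`) — Cl₂ isotopologue
  channels at m/z 70/72/74 → instantaneous concentration → trapezoidal
  TWA.
- **Synthetic chamber experiments** (`ppas.synthetic`) — seeded,
  bit-reproducible generator for liquid/spray/gel/stock-solution emission
  scenarios, sampler responses and measurement noise.
- **Inference** (`ppas.inference`) — kinetic parameter fitting,
  plateau-capacity estimation, linear-phase slopes, two-phase
  (gel) changepoint detection, and parameter-recovery studies.
- **CLI** (`ppas`) — `simulate`, `estimate`, `twa`, `recover`
  subcommands over the same functions.

## Worked example

```python
import numpy as np
from ppas import SamplerParams, AirConcentrationSeries, simulate_uptake, twa
from ppas.exposure import ExtractionMeasurement, cs_from_extraction, cv_twa_from_cs

params = SamplerParams()          # calibrated defaults: R_s = 2.53e-3 m³/h, C_cap = 1.8

# A sampler worn 2 h comes back with the dye extract at 0.09395 g/L
# against a 0.100 g/L blank:
m = ExtractionMeasurement(C_i=0.100, C_f=0.09395, deployment_h=2.0)
cs = cs_from_extraction(m, params)
summary = cv_twa_from_cs(cs, params, deployment_h=2.0)
print(f"C_s = {cs:.4f} mol/m3")
print(f"TWA = {summary.C_v_TWA_ppbv:.1f} ppbv over 2 h")
print(f"CT  = {summary.ct.value:.0f} ppbv·min, flags = {sorted(summary.flags)}")

# Forward model: what the sampler does in a chamber held at 500 ppbv
air = AirConcentrationSeries(np.array([0.0, 600.0]), np.array([500.0, 500.0]))
traj = simulate_uptake(params, air, duration_h=10.0)
print(f"plateau C_s = {traj.C_s[-1]:.2f} mol/m3")
```

prints

```
C_s = 1.0006 mol/m3
TWA = 598.7 ppbv over 2 h
CT  = 71843 ppbv·min, flags = ['AEGL-1', 'OSHA_PEL']
plateau C_s = 1.80 mol/m3
```

i.e. this sampler saw an average of ≈599 ppbv — above both 500-ppbv
reference levels for its 2-h window — and a sampler left in a constant
500-ppbv atmosphere eventually saturates at the dye capacity.

From the shell, the same estimation runs as:

```sh
ppas simulate --seed 1 --deployment-times 0.5,1,2 --out-dir run/
ppas estimate --measurements run/measurements.csv --out run/report.csv
ppas twa --series run/emission.csv --start 0 --end 120
```

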