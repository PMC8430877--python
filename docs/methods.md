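# Methods

## The measurement problem

Chlorine-based disinfectants release Cl₂ gas during use. A personal passive
air sampler (PPAS) for this gas is a thin PDMS sheet doped with the redox
dye o-dianisidine: dissolved chlorine oxidizes the dye irreversibly, so the
dye consumed over a deployment records the cumulative uptake without a pump
or instrument. This package implements the quantitative chain around that
sampler: the forward uptake kinetics, the extraction-based exposure
estimators, reference PTR/SRI-MS series processing, a synthetic
chamber-experiment generator, and inverse-problem tooling.

## Uptake model

Uptake is two processes in series. Fickian transfer across the air/sampler
interface,

    F_diffusion = k_O · A_s · (C_A − c_free / K_SA)          [mol h⁻¹]

and first-order oxidation of the dye by the dissolved pool,

    F_reaction = k_reac · A_s · c_free / δ · g(r)            [mol h⁻¹]

with `r = 1 − C_s/C_cap` the remaining-dye fraction. The harmonic
("resistances in series") combination of these two fluxes is degenerate at
start-up — the reaction flux vanishes with `c_free`, which would force the
total flux to zero at t = 0, contradicting the observed early linear
uptake. The default integrator therefore evolves two states,

    dc_free/dt = (F_diffusion − F_reaction) / V_s
    dC_s/dt    =  F_reaction / V_s

where `c_free` is the dissolved, unreacted chlorine and `C_s` the
cumulative reacted chlorine per sampler volume (the quantity recovered by
extraction). Eliminating `c_free` at quasi-steady state gives the
closed form

    F = A_s · C_A / (1/k_O + δ/(k_reac · K_SA · g(r)))

exposed as `quasi_steady_flux` and as a single-state integration mode. Both
reproduce the two limiting behaviours the sampler exhibits: an early linear
phase with slope `k_O·A_s·C_A/V_s` when reaction is fast, and a plateau at
`C_cap` once the dye is exhausted. The literal harmonic-of-fluxes
expression is retained only as the diagnostic `total_flux_literal`.

The capacity factor `g` defaults to `g(r) = r` (reaction proportional to
remaining dye; smooth approach to the plateau). `g(r) = 1{r>0}` ("hard"
mode) gives the piecewise-linear idealization of the uptake curve.

### Parameters and defaults

| Parameter | Default | Unit | Basis |
|---|---|---|---|
| A_s | 2.25e-4 | m² | sampler face area (1.5 cm × 1.5 cm) |
| δ | 5.5e-4 | m | PDMS sheet thickness |
| V_s | A_s·δ = 1.2375e-7 | m³ | lumped sampler volume |
| R_s | 2.53e-3 | m³ h⁻¹ | calibrated sampling rate |
| k_O | R_s/A_s = 11.244 | m h⁻¹ | ties the kinetic model to R_s |
| k_reac | 100 | h⁻¹ | fast-reaction regime (weakly identified; see below) |
| K_SA | 10 | — | never measured; affects only back-diffusion |
| C_cap | 1.8 | mol m⁻³ | dye capacity per sampler volume |
| stoich | 2 | mol dye / mol Cl₂ | redox stoichiometry |

Two published values for the sheet thickness circulate (0.55 mm physical
sheet vs 5 mm in one symbol list); the package uses the physical 0.55 mm
and treats the other as a typographical error, overridable in config.
`k_O = R_s/A_s` makes the linear-regime effective sampling rate
(`sampling_rate_identity`) equal the calibrated R_s exactly, which is what
makes the generate → estimate closure exact in the linear regime.

In the default (reaction-fast) regime the fast eigenvalue of the two-state
system is ≈ `k_O/(K_SA·δ) + k_reac/δ²` ≈ 3e8 h⁻¹: the system is very stiff
and is integrated with LSODA (rtol 1e-8, atol 1e-12; BDF fallback at
extreme parameter corners). `k_reac` and `K_SA` are structurally almost
unidentifiable there — any sufficiently fast reaction gives the same
diffusion-limited uptake — so both are held fixed in fits by default.

### Exposure estimators

From one extraction record (initial/final dye concentration in 10 mL
isopropyl alcohol),

    C_s     = (C_i − C_f) · V_E / (M_w · V_s · stoich),  M_w = 244.30 g mol⁻¹
    C_v,TWA = C_s · V_s / (R_s · t)

then ideal-gas conversion to ppbv at configurable conditions (default
298.15 K, 101325 Pa — the chamber conditions were not published, so these
are package defaults, not measured values) and a CT dose metric
(TWA × duration, ppbv·min) with threshold flags for the occupational PEL
and AEGL-1 reference levels (both 500 ppbv; AEGL-1 applies to 10 min – 8 h
windows). Samplers with `C_s ≥ 0.9·C_cap` carry a SATURATION flag: near
capacity, uptake stalls and the TWA estimate is a lower bound only.

A known internal tension is documented rather than hidden: a fully
saturated sampler (C_s = 1.8 mol m⁻³) read at a 3-h deployment with the
geometry and R_s above corresponds to ≈129,000 ppbv·min, whereas the
capacity is elsewhere quoted as 104,000 ppbv·min; no combination of
room-temperature conditions and the stated geometry reconciles the two
(the published T/P and the V_s convention used there are unknown). The
package reports what its own equations give.

## Synthetic chamber experiments

The generator emulates a 125 L closed-chamber protocol. Emission shapes
are phenomenological, not hypochlorite speciation chemistry (pH is carried
as metadata only):

- liquid / stock solution / spray: saturating rise
  `C(t) = plateau·(1 − exp(−rise_rate·t))`, default plateau 1160 ppbv and
  rise rate 1 h⁻¹ so the series is still visibly rising at 2 h;
  the dilution factor deliberately does not change the emission (diluting
  bleach lowers pH, which compensates the chlorine loss).
- spray: per-spray plateau (default 300 ppbv) scaled by
  `amount^0.7` — plateaus for 1/5/10 sprays are ordered and sublinear.
  The exponent is a configuration default, not a claim.
- gel: piecewise-linear two-phase rise with a 1.5 h lag; the late/early
  slope ratio defaults to 20, representing the observed pattern of a
  barely-detectable early signal (thickener suppresses out-diffusion)
  followed by a steep rise. Profiles are emitted on a 1-min grid, the
  natural PTR-MS cadence.

Sampler responses are produced by the forward model, inverted through the
extraction equation to noise-free dye drops, then perturbed by
multiplicative Gaussian noise with a configurable coefficient of variation
(default 0.05, the scale of reported triplicate spread). Every draw comes
from a counter-split stream of one experiment seed, so adding replicates
or deployment times never perturbs earlier draws and regeneration is
bit-for-bit reproducible. PTR-MS channel rendering splits the calibrated
net response across m/z 70/72/74 by the binomial isotopologue fractions
(³⁵Cl abundance 0.7577) and inverts exactly when noise is off.

What the generator does **not** emulate: chamber wall losses, aerosol
physics of sprays, humidity/temperature dependence of uptake, instrument
baseline drift, or the possibility that a real chamber never plateaus.
Passing tests therefore demonstrate internal consistency of the estimation
chain under the stated noise model, not field accuracy of the sampler.

## Inference

- `fit_uptake`: least squares on C_s(t) with free parameters on a log
  scale, deterministic 5-point multi-start, bounds, and a
  finite-difference step (1e-3 in log space) chosen to sit well above the
  ODE-solver noise floor — with the default square-root-of-eps step the
  Jacobian is dominated by adaptive-integrator jitter and fits stall.
  Ties break by lowest SSE then smallest log-distance from the initial
  guess; boundary convergence and multi-start disagreement are flagged,
  never silently returned.
- `estimate_capacity`: mean of the terminal run of points whose local
  relative slope is below 0.02 h⁻¹ — loose enough to accept the smooth
  proportional-g tail, tight enough to reject the linear phase at
  hour-scale sampling; returns a not-plateaued marker otherwise.
- `linear_phase_slope`: OLS over a window; in the linear regime the slope
  maps to an implied air concentration through `slope = R_s·C_A/V_s`.
- `changepoint_check`: exhaustive two-segment scan (it *is* the brute
  force at these sizes), declaring a changepoint when the two-segment fit
  improves the one-segment SSE by ≥10%. Residuals are normalized by the
  local signal level before squaring because the measurement noise is
  multiplicative with constant CV: on raw residuals the strong
  heteroscedasticity of a rising series produces spurious detections on
  perfectly linear profiles at any realistic series length, while
  CV-normalized residuals give ≤1% false positives at 181 points with
  ≥96% localization of the gel lag to within one sample. `relative=False`
  restores plain SSE.
- `recovery_study`: seeded generate → fit repetitions reporting
  per-parameter bias and RMSE; individual fit failures are recorded and
  more than 20% of failures aborts with diagnostics.

## Numerical validation choices

The adaptive integrator is cross-checked against an independent fixed-step
explicit-Euler integration at 1e-4 h. Explicit Euler is only stable when
the fast eigenvalue is ≲2e4 h⁻¹, so the cross-check draws parameters from
a diffusion-dominated regime (k_O 2–15 m h⁻¹, k_reac 1e-3–1e-2 h⁻¹, K_SA
20–100, δ 2–6 mm, C_cap 0.8–2.5 mol m⁻³) where both methods are valid;
agreement there is ~1e-5 relative. The statistical studies use problem
sizes chosen as representative defaults: 100 repetitions for recovery
under 5% noise, 100/200 replicates for changepoint hit/false-positive
rates, nine deployment times spanning the linear and plateau phases.

## Known limitations

- The model is lumped (no spatial diffusion profile through the PDMS
  sheet) and single-gas (no competition from other oxidants).
- K_SA is a placeholder default; only strongly reversible regimes would be
  sensitive to it, and fits do not attempt to identify it.
- TWA estimates from saturated samplers are lower bounds, not estimates.
- The whole-face interpretation of A_s (one effective face) is a
  convention; results scale accordingly if both faces collect gas.
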