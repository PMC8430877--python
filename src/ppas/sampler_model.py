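"""Forward model of chlorine uptake into the dye-doped PDMS sampler.

The sampler accumulates gas through two processes in series: Fickian
diffusion across the air/sampler boundary,

    F_diffusion = k_O · A_s · (C_A − c_free / K_SA)        [mol h⁻¹]

and irreversible first-order oxidation of the dye by dissolved chlorine,

    F_reaction = k_reac · A_s · c_free / δ · g(r)          [mol h⁻¹]

where ``c_free`` is the dissolved (not yet reacted) chlorine concentration in
the sampler, ``r = 1 − C_s/C_cap`` the remaining-dye fraction and ``g`` a
capacity-limiting factor.  The default integrator evolves the two states

    dc_free/dt = (F_diffusion − F_reaction) / V_s
    dC_s/dt    =  F_reaction / V_s

which reproduces both limiting behaviours of the uptake curve: an early
linear phase with slope k_O·A_s·C_A/V_s when reaction is much faster than
diffusion, and a plateau at the dye capacity C_cap once the dye is
exhausted.  A single-state quasi-steady reduction (series-resistance closed
form) and the literal harmonic combination of the two fluxes are provided as
diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

from ppas.ptrms import AirConcentrationSeries
from ppas.units import GasConditions, STANDARD_CONDITIONS

#: Calibrated sampling rate of the default sampler geometry, m³ h⁻¹.
DEFAULT_SAMPLING_RATE = 2.53e-3

#: Default sampler face area, m².
DEFAULT_AREA = 2.25e-4

#: Default sampler sheet thickness, m (0.55 mm PDMS sheet).
DEFAULT_THICKNESS = 5.5e-4

#: Default maximum reacted-chlorine capacity, mol m⁻³.
DEFAULT_CAPACITY = 1.8


@dataclass(frozen=True)
class SamplerParams:
    """Geometry and kinetic constants of one passive sampler.

    Parameters
    ----------
    A_s : float
        Sampler surface area, m².
    delta : float
        Sheet thickness δ, m.
    K_SA : float
        Dimensionless sampler–air partition constant.  Never measured for
        this sampler; the default of 10 only affects the reversible
        back-diffusion term and is irrelevant in the reaction-fast regime.
    k_O : float
        Overall (air-side + sampler-side) mass-transfer coefficient, m h⁻¹.
        Defaults to R_s / A_s so that the linear-regime sampling rate equals
        the calibrated R_s.
    k_reac : float
        First-order rate constant of the chlorine/dye redox reaction, h⁻¹.
    C_cap : float
        Maximum reacted-chlorine load per sampler volume, mol m⁻³.
    R_s : float
        Calibrated sampling rate, m³ h⁻¹.
    stoich : float
        Moles of dye consumed per mole of Cl₂ reacted (2 by default).
    V_s : float
        Sampler volume, m³; A_s·δ unless overridden.
    """

    A_s: float = DEFAULT_AREA
    delta: float = DEFAULT_THICKNESS
    K_SA: float = 10.0
    k_O: float = DEFAULT_SAMPLING_RATE / DEFAULT_AREA
    k_reac: float = 100.0
    C_cap: float = DEFAULT_CAPACITY
    R_s: float = DEFAULT_SAMPLING_RATE
    stoich: float = 2.0
    V_s: float | None = None

    def __post_init__(self) -> None:
        for name in ("A_s", "delta", "K_SA", "k_O", "k_reac", "C_cap", "R_s", "stoich"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v!r}")
        if self.V_s is None:
            object.__setattr__(self, "V_s", self.A_s * self.delta)
        elif not (math.isfinite(self.V_s) and self.V_s > 0):
            raise ValueError(f"V_s must be positive and finite, got {self.V_s!r}")

    def with_(self, **overrides) -> "SamplerParams":
        """Copy with fields replaced (V_s recomputed unless given)."""
        if "V_s" not in overrides:
            overrides["V_s"] = None
        return replace(self, **overrides)


def capacity_factor(dye_remaining: float, mode: str = "proportional") -> float:
    """Capacity-limiting factor g(r) applied to the reaction flux.

    ``proportional`` (default): g(r) = r — the reaction slows in proportion
    to the remaining dye, giving a smooth approach to the plateau.
    ``hard``: g(r) = 1 while any dye remains — the piecewise-linear
    idealization of the uptake curve.
    """
    r = min(max(dye_remaining, 0.0), 1.0)
    if mode == "proportional":
        return r
    if mode == "hard":
        return 1.0 if r > 0 else 0.0
    raise ValueError(f"unknown capacity mode {mode!r}")


def diffusion_flux(params: SamplerParams, C_A: float, c_free: float) -> float:
    """Fickian flux into the sampler, mol h⁻¹ (negative means outgassing)."""
    return params.k_O * params.A_s * (C_A - c_free / params.K_SA)


def reaction_flux(
    params: SamplerParams,
    c_free: float,
    dye_remaining: float = 1.0,
    capacity_mode: str = "proportional",
) -> float:
    """First-order dye-oxidation flux, mol h⁻¹."""
    g = capacity_factor(dye_remaining, capacity_mode)
    return params.k_reac * params.A_s * c_free / params.delta * g


def total_flux_literal(F_diff: float, F_reac: float) -> float:
    """Harmonic (series-resistance) combination of the two fluxes.

    Diagnostic only: this expression is degenerate at start-up, where the
    reaction flux vanishes with the dissolved concentration and forces the
    total to zero.  Use :func:`simulate_uptake` for time evolution.
    """
    if F_diff < 0 or F_reac < 0:
        raise ValueError("total_flux_literal requires non-negative fluxes")
    if F_diff == 0 or F_reac == 0:
        return 0.0
    return 1.0 / (1.0 / F_diff + 1.0 / F_reac)


def quasi_steady_flux(
    params: SamplerParams,
    C_A: float,
    dye_remaining: float = 1.0,
    capacity_mode: str = "proportional",
) -> float:
    """Uptake flux with the dissolved chlorine pool at quasi-steady state.

    Eliminating c_free from the two-state model (dc_free/dt ≈ 0) gives the
    series-resistance form

        F = A_s · C_A / (1/k_O + δ/(k_reac · K_SA · g(r)))

    which reduces to the pure-diffusion flux k_O·A_s·C_A when reaction is
    fast and to 0 when the dye is exhausted.
    """
    if C_A < 0:
        raise ValueError(f"C_A must be non-negative, got {C_A!r}")
    g = capacity_factor(dye_remaining, capacity_mode)
    if g <= 0.0:
        return 0.0
    resistance = 1.0 / params.k_O + params.delta / (params.k_reac * params.K_SA * g)
    return params.A_s * C_A / resistance


def sampling_rate_identity(params: SamplerParams) -> float:
    """Effective sampling rate k_O·A_s (m³ h⁻¹) in the reaction-fast linear regime.

    With the default k_O = R_s/A_s this returns the calibrated R_s exactly,
    tying the kinetic model to the sampling-rate formulation of the TWA
    estimator.
    """
    return params.k_O * params.A_s


@dataclass(frozen=True)
class UptakeTrajectory:
    """Simulated sampler state versus time.

    ``C_s`` is the cumulative reacted chlorine per sampler volume (the
    quantity recovered by solvent extraction); ``c_free`` the dissolved
    unreacted pool; ``flux`` the instantaneous uptake flux from air; and
    ``uptake_mol`` the running time-integral of that flux (for mass-balance
    checks).
    """

    time_h: np.ndarray
    c_free: np.ndarray
    C_s: np.ndarray
    flux: np.ndarray
    uptake_mol: np.ndarray
    params: SamplerParams

    def cs_at(self, t_h) -> np.ndarray:
        return np.interp(t_h, self.time_h, self.C_s)

    @property
    def saturation_fraction(self) -> float:
        return float(self.C_s[-1] / self.params.C_cap)


def _forcing(air: AirConcentrationSeries, cond: GasConditions, duration_h: float,
             extrapolation: str):
    """Air concentration C_A(t_h) in mol m⁻³, zero-order hold outside the grid."""
    t_h = air.time_min / 60.0
    if t_h[0] > 1e-12:
        raise ValueError("air series must start at or before t = 0")
    if extrapolation == "strict" and duration_h > t_h[-1] + 1e-12:
        raise ValueError(
            f"air series ends at {t_h[-1]:g} h but simulation runs to {duration_h:g} h"
        )
    c_molar = air.ppbv * 1e-9 * cond.molar_density

    def C_A(t: float) -> float:
        return float(np.interp(t, t_h, c_molar))

    return C_A


def simulate_uptake(
    params: SamplerParams,
    air: AirConcentrationSeries,
    duration_h: float,
    step_h: float = 0.01,
    mode: str = "two_state",
    cond: GasConditions = STANDARD_CONDITIONS,
    capacity_mode: str = "proportional",
    extrapolation: str = "hold",
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> UptakeTrajectory:
    """Integrate the uptake model against an air concentration series.

    Parameters
    ----------
    duration_h : float
        Deployment length, hours.
    step_h : float
        Output grid spacing, hours (the integrator itself is adaptive).
    mode : {"two_state", "quasi_steady"}
        ``two_state`` evolves (c_free, C_s); ``quasi_steady`` integrates the
        closed-form flux with c_free slaved to C_A.
    extrapolation : {"hold", "strict"}
        Policy when the air series ends before ``duration_h``: hold the last
        value constant, or reject.

    Returns an :class:`UptakeTrajectory`; the cumulative uptake integral is
    carried as an extra ODE state so mass balance holds to solver tolerance.
    """
    if duration_h <= 0:
        raise ValueError(f"duration_h must be positive, got {duration_h!r}")
    if step_h <= 0:
        raise ValueError(f"step_h must be positive, got {step_h!r}")
    if mode not in ("two_state", "quasi_steady"):
        raise ValueError(f"unknown mode {mode!r}")

    C_A = _forcing(air, cond, duration_h, extrapolation)
    p = params
    if t_eval is None:
        t_eval = np.arange(0.0, duration_h + step_h / 2, step_h)
        t_eval[-1] = min(t_eval[-1], duration_h)
        if t_eval[-1] < duration_h:
            t_eval = np.append(t_eval, duration_h)

    if mode == "two_state":
        def rhs(t, y):
            c_free, C_s = y[0], y[1]
            r = 1.0 - C_s / p.C_cap
            Fd = diffusion_flux(p, C_A(t), c_free)
            Fr = reaction_flux(p, max(c_free, 0.0), r, capacity_mode)
            return ((Fd - Fr) / p.V_s, Fr / p.V_s, Fd)

        y0 = [0.0, 0.0, 0.0]
    else:
        def rhs(t, y):
            C_s = y[0]
            r = 1.0 - C_s / p.C_cap
            F = quasi_steady_flux(p, C_A(t), r, capacity_mode)
            return (F / p.V_s, F)

        y0 = [0.0, 0.0]

    sol = solve_ivp(
        rhs, (0.0, duration_h), y0, method="LSODA",
        t_eval=t_eval, rtol=rtol, atol=atol,
    )
    if not sol.success:
        # very stiff corners (e.g. extreme k_O during optimization) can defeat
        # LSODA's switching; retry with a pure implicit method
        sol = solve_ivp(
            rhs, (0.0, duration_h), y0, method="BDF",
            t_eval=t_eval, rtol=rtol, atol=atol,
        )
    if not sol.success:
        raise RuntimeError(f"uptake integration failed: {sol.message}")

    if mode == "two_state":
        c_free = np.maximum(sol.y[0], 0.0)
        C_s = np.clip(sol.y[1], 0.0, p.C_cap)
        uptake = sol.y[2]
        flux = np.array([
            diffusion_flux(p, C_A(t), cf) for t, cf in zip(sol.t, c_free)
        ])
    else:
        C_s = np.clip(sol.y[0], 0.0, p.C_cap)
        uptake = sol.y[1]
        flux = np.array([
            quasi_steady_flux(p, C_A(t), 1.0 - cs / p.C_cap, capacity_mode)
            for t, cs in zip(sol.t, C_s)
        ])
        # quasi-steady dissolved pool implied by the flux balance
        c_free = np.maximum(p.K_SA * (np.array([C_A(t) for t in sol.t]) - flux / (p.k_O * p.A_s)), 0.0)

    C_s = np.maximum.accumulate(C_s)  # remove sub-tolerance ripples
    return UptakeTrajectory(sol.t, c_free, C_s, flux, uptake, p)


def trajectory_frame(traj: UptakeTrajectory):
    """Trajectory as a pandas DataFrame (time_h, c_free_mol_m3, C_s_mol_m3, flux_mol_h)."""
    import pandas as pd

    return pd.DataFrame({
        "time_h": traj.time_h,
        "c_free_mol_m3": traj.c_free,
        "C_s_mol_m3": traj.C_s,
        "flux_mol_h": traj.flux,
    })
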