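"""Synthetic closed-chamber experiment generator.

Emulates the structure of a 125 L chamber study: a disinfectant product
placed in the chamber emits chlorine with a product-dependent concentration
profile, passive samplers deployed in the chamber take up chlorine per the
forward model, and each retrieved sampler yields a noisy solvent-extraction
measurement.  Optionally the chamber series is also rendered as raw PTR-MS
isotopologue channels.

Emission shapes are phenomenological, not hypochlorite speciation chemistry:

* liquid / stock_solution / spray — saturating rise
  C(t) = plateau · (1 − exp(−rise_rate·t)); the spray plateau scales
  sublinearly with the number of sprays (power law, exponent 0.7 by
  default), reflecting that ten sprays do not emit ten times one spray.
* gel — two-phase piecewise-linear rise: a shallow slope during an initial
  lag (the thickener suppresses out-diffusion), then a steeper slope.

Every generator is a pure function of (configuration, seed): replicate
noise streams are split from the seed by counter so adding replicates or
deployment times never perturbs earlier draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from ppas.exposure import (
    DEFAULT_EXTRACTION_VOLUME,
    ExtractionMeasurement,
    delta_extraction_from_cs,
)
from ppas.ptrms import (
    AirConcentrationSeries,
    ChannelSeries,
    NATURAL_CL35_ABUNDANCE,
    PtrmsCalibration,
    isotopologue_fractions,
)
from ppas.sampler_model import SamplerParams, UptakeTrajectory, simulate_uptake
from ppas.units import GasConditions, STANDARD_CONDITIONS

PRODUCT_TYPES = ("liquid", "spray", "gel", "stock_solution")

#: Dye concentration yielded by an unexposed sampler's extract, g L⁻¹.
DEFAULT_BLANK_EXTRACT_G_PER_L = 0.1


@dataclass(frozen=True)
class ScenarioConfig:
    """One chamber-experiment scenario.

    ``amount`` is product-specific: mL for liquid/stock_solution, number of
    sprays for spray, grams for gel.  ``plateau_ppbv`` anchors the emission
    profile: the asymptote for saturating products (per spray for sprays),
    the end-of-profile concentration for gels.  ``lag_time_h`` and
    ``gel_slope_ratio`` shape the gel two-phase profile; ``dilution_factor``
    is carried as metadata for liquids (chamber emission is insensitive to
    dilution because the solution pH drop compensates the chlorine loss).
    """

    product_type: str = "liquid"
    amount: float = 200.0
    dilution_factor: float = 1.0
    chamber_volume: float = 0.125       # m³ (125 L chamber)
    plateau_ppbv: float = 1160.0
    rise_rate: float = 1.0              # h⁻¹
    lag_time_h: float = 1.5             # gel only
    gel_slope_ratio: float = 20.0       # late/early emission slope, gel only
    spray_exponent: float = 0.7         # sublinearity of plateau vs spray count
    seed: int = 0

    def __post_init__(self) -> None:
        if self.product_type not in PRODUCT_TYPES:
            raise ValueError(
                f"unknown product_type {self.product_type!r}; expected one of {PRODUCT_TYPES}"
            )
        if not self.chamber_volume > 0:
            raise ValueError(f"chamber_volume must be positive, got {self.chamber_volume!r}")
        if self.plateau_ppbv < 0:
            raise ValueError(f"plateau_ppbv must be non-negative, got {self.plateau_ppbv!r}")
        if self.lag_time_h < 0:
            raise ValueError(f"lag_time_h must be non-negative, got {self.lag_time_h!r}")
        if self.dilution_factor < 1:
            raise ValueError(f"dilution_factor must be >= 1, got {self.dilution_factor!r}")
        if self.gel_slope_ratio <= 1:
            raise ValueError(f"gel_slope_ratio must exceed 1, got {self.gel_slope_ratio!r}")


@dataclass(frozen=True)
class SyntheticExperiment:
    """A generated dataset together with its ground truth."""

    scenario: ScenarioConfig
    params: SamplerParams
    air: AirConcentrationSeries
    trajectory: UptakeTrajectory
    deployment_times_h: tuple[float, ...]
    true_cs: np.ndarray                      # C_s at each deployment time
    measurements: list[ExtractionMeasurement]
    channels: ChannelSeries | None = None
    cond: GasConditions = STANDARD_CONDITIONS
    blank_extract_g_per_L: float = DEFAULT_BLANK_EXTRACT_G_PER_L


def emission_profile(
    scenario: ScenarioConfig,
    duration_h: float = 3.0,
    dt_min: float = 1.0,
) -> AirConcentrationSeries:
    """Deterministic chamber concentration profile for a scenario."""
    if duration_h <= 0 or dt_min <= 0:
        raise ValueError("duration_h and dt_min must be positive")
    t_min = np.arange(0.0, duration_h * 60.0 + dt_min / 2, dt_min)
    t_h = t_min / 60.0
    p = scenario
    if p.product_type in ("liquid", "stock_solution"):
        c = p.plateau_ppbv * (1.0 - np.exp(-p.rise_rate * t_h))
    elif p.product_type == "spray":
        plateau = p.plateau_ppbv * p.amount ** p.spray_exponent
        c = plateau * (1.0 - np.exp(-p.rise_rate * t_h))
    else:  # gel
        lag = min(p.lag_time_h, duration_h)
        ratio = p.gel_slope_ratio
        s1 = p.plateau_ppbv / (lag + ratio * (duration_h - lag))
        c = np.where(t_h <= lag, s1 * t_h, s1 * lag + ratio * s1 * (t_h - lag))
    return AirConcentrationSeries(t_min, np.maximum(c, 0.0))


def _replicate_rng(seed: int, dep_index: int, rep_index: int) -> np.random.Generator:
    # Counter-based stream split: each (deployment, replicate) slot owns an
    # independent stream derived from the one experiment seed.
    return np.random.default_rng([seed, dep_index, rep_index])


def generate_experiment(
    scenario: ScenarioConfig,
    params: SamplerParams,
    deployment_times_h: list[float],
    n_replicates: int = 3,
    noise_cv: float = 0.05,
    cond: GasConditions = STANDARD_CONDITIONS,
    with_channels: bool = False,
    calibration: PtrmsCalibration | None = None,
    blank_extract_g_per_L: float = DEFAULT_BLANK_EXTRACT_G_PER_L,
    V_E: float = DEFAULT_EXTRACTION_VOLUME,
    mode: str = "two_state",
) -> SyntheticExperiment:
    """Simulate a chamber deployment and emit noisy extraction measurements.

    For each deployment time the forward model provides the true C_s; the
    extraction inverse map gives the noise-free dye drop (C_i − C_f), and
    multiplicative Gaussian noise with coefficient of variation ``noise_cv``
    is applied independently per replicate.  Draws that would imply
    C_f > C_i are floored at zero dye drop; if more than 1% of draws are
    floored a warning is emitted.
    """
    times = list(deployment_times_h)
    if not times or any(t <= 0 for t in times) or sorted(times) != times:
        raise ValueError("deployment_times_h must be positive and sorted ascending")
    if n_replicates < 1:
        raise ValueError(f"n_replicates must be >= 1, got {n_replicates!r}")
    if not 0.0 <= noise_cv < 1.0:
        raise ValueError(f"noise_cv must lie in [0, 1), got {noise_cv!r}")

    duration = times[-1]
    air = emission_profile(scenario, duration_h=duration)
    traj = simulate_uptake(params, air, duration_h=duration, step_h=min(0.01, duration / 50),
                           mode=mode, cond=cond)
    true_cs = traj.cs_at(times)

    measurements: list[ExtractionMeasurement] = []
    n_floored = 0
    n_draws = 0
    for i_dep, (t_dep, cs) in enumerate(zip(times, true_cs)):
        delta_true = delta_extraction_from_cs(cs, params, V_E)
        for i_rep in range(n_replicates):
            if noise_cv > 0:
                z = _replicate_rng(scenario.seed, i_dep, i_rep).standard_normal()
                delta = delta_true * (1.0 + noise_cv * z)
            else:
                delta = delta_true
            n_draws += 1
            if delta < 0:
                n_floored += 1
                delta = 0.0
            delta = min(delta, blank_extract_g_per_L)  # extract cannot go below zero dye
            measurements.append(ExtractionMeasurement(
                C_i=blank_extract_g_per_L,
                C_f=blank_extract_g_per_L - delta,
                deployment_h=t_dep,
                V_E=V_E,
                replicate_id=f"t{t_dep:g}h_r{i_rep + 1}",
            ))
    if n_draws and n_floored / n_draws > 0.01:
        warnings.warn(
            f"{n_floored}/{n_draws} noisy extraction draws implied C_f > C_i "
            "and were floored at zero dye consumption",
            stacklevel=2,
        )

    channels = None
    if with_channels:
        cal = calibration or PtrmsCalibration(slope=10.0)
        channels = generate_ptrms_channels(
            air, cal, noise_cv=noise_cv, seed=scenario.seed,
        )

    return SyntheticExperiment(
        scenario=scenario,
        params=params,
        air=air,
        trajectory=traj,
        deployment_times_h=tuple(times),
        true_cs=np.asarray(true_cs),
        measurements=measurements,
        channels=channels,
        cond=cond,
        blank_extract_g_per_L=blank_extract_g_per_L,
    )


def generate_ptrms_channels(
    series: AirConcentrationSeries,
    cal: PtrmsCalibration,
    noise_cv: float = 0.0,
    seed: int = 0,
    cl35_abundance: float = NATURAL_CL35_ABUNDANCE,
) -> ChannelSeries:
    """Render a concentration series as raw isotopologue channel responses.

    The total net response slope·C + intercept is split across m/z 70/72/74
    by the binomial isotopologue fractions; outside-chamber channels sit at
    the intercept-level baseline.  With ``noise_cv = 0`` the construction is
    the exact inverse of :func:`ppas.ptrms.instantaneous_concentration`.
    """
    if not 0.0 <= noise_cv < 1.0:
        raise ValueError(f"noise_cv must lie in [0, 1), got {noise_cv!r}")
    fracs = np.array(isotopologue_fractions(cl35_abundance))
    total_in = cal.slope * series.ppbv + cal.intercept   # net signal to encode
    baseline = fracs * cal.intercept                      # outside-chamber level
    inside = {}
    outside = {}
    rng = np.random.default_rng([seed, 70_72_74]) if noise_cv > 0 else None
    for i, mz in enumerate((70, 72, 74)):
        in_ch = fracs[i] * total_in + baseline[i]
        out_ch = np.full_like(in_ch, baseline[i])
        if rng is not None:
            in_ch = in_ch * (1.0 + noise_cv * rng.standard_normal(in_ch.shape))
            out_ch = out_ch * (1.0 + noise_cv * rng.standard_normal(out_ch.shape))
        inside[f"in_{mz}"] = np.maximum(in_ch, 0.0)
        outside[f"out_{mz}"] = np.maximum(out_ch, 0.0)
    return ChannelSeries(time_min=series.time_min, **inside, **outside)


def scenario_from_dict(d: dict) -> ScenarioConfig:
    """Build a scenario from a plain mapping (e.g. parsed YAML)."""
    known = {f.name for f in ScenarioConfig.__dataclass_fields__.values()}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown scenario key(s): {sorted(unknown)}")
    return ScenarioConfig(**d)


def scenario_with_seed(scenario: ScenarioConfig, seed: int) -> ScenarioConfig:
    return replace(scenario, seed=int(seed) % 2**31)
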