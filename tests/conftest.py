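import numpy as np
import pytest

from ppas import AirConcentrationSeries, SamplerParams
from ppas.units import GasConditions


@pytest.fixture
def params() -> SamplerParams:
    return SamplerParams()


@pytest.fixture
def cond() -> GasConditions:
    return GasConditions()


@pytest.fixture
def constant_air():
    """Factory for a constant-concentration series (ppbv) over a span in minutes."""

    def make(ppbv: float, end_min: float = 600.0) -> AirConcentrationSeries:
        return AirConcentrationSeries(
            np.array([0.0, end_min]), np.array([ppbv, ppbv])
        )

    return make


def euler_uptake(p: SamplerParams, c_air_molar: float, duration_h: float,
                 step_h: float) -> float:
    """Independent fixed-step explicit-Euler integration of the two-state model.

    Scalar, loop-based, shares no code with the adaptive integrator; valid
    only where explicit Euler is stable for the fast dissolved-chlorine mode.
    Returns C_s at the end of the run.
    """
    c_free = 0.0
    C_s = 0.0
    n = int(round(duration_h / step_h))
    for _ in range(n):
        r = max(0.0, 1.0 - C_s / p.C_cap)
        F_diff = p.k_O * p.A_s * (c_air_molar - c_free / p.K_SA)
        F_reac = p.k_reac * p.A_s * c_free / p.delta * r
        c_free += step_h * (F_diff - F_reac) / p.V_s
        C_s += step_h * F_reac / p.V_s
    return C_s


def euler_stable_params(rng: np.random.Generator) -> SamplerParams:
    """Random parameter draw inside the explicit-Euler stability domain.

    The fast eigenvalue of the two-state system is about
    k_O/(K_SA·δ) + k_reac/δ²; the ranges below keep it small enough that a
    1e-4 h fixed step is both stable and accurate.
    """
    return SamplerParams(
        k_O=rng.uniform(2.0, 15.0),
        k_reac=rng.uniform(1e-3, 1e-2),
        K_SA=rng.uniform(20.0, 100.0),
        C_cap=rng.uniform(0.8, 2.5),
        delta=rng.uniform(2e-3, 6e-3),
    )
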