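"""Unit conversions, CT dose metrics and exposure-guideline comparisons.

Gas-phase concentrations are reported in ppbv (parts per billion by volume)
but the sampler kinetics are written in mol m⁻³; the two are linked by the
ideal-gas law at user-supplied temperature and pressure.  Dose is expressed
as a CT value (TWA concentration × exposure time, ppbv·min), the metric used
to compare short high exposures with long low ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

R_GAS = 8.314462
"""Molar gas constant, J mol⁻¹ K⁻¹."""


def _require_finite_nonneg(value: float, name: str) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    if value < 0:
        raise ValueError(f"{name} must be non-negative, got {value!r}")


@dataclass(frozen=True)
class GasConditions:
    """Temperature and pressure at which ppbv ↔ molar conversions are done.

    Defaults to 298.15 K and 101325 Pa.
    """

    temperature: float = 298.15  # K
    pressure: float = 101325.0   # Pa

    def __post_init__(self) -> None:
        if not (math.isfinite(self.temperature) and self.temperature > 0):
            raise ValueError(f"temperature must be positive, got {self.temperature!r}")
        if not (math.isfinite(self.pressure) and self.pressure > 0):
            raise ValueError(f"pressure must be positive, got {self.pressure!r}")

    @property
    def molar_density(self) -> float:
        """Total gas molar density P/(RT), mol m⁻³."""
        return self.pressure / (R_GAS * self.temperature)


STANDARD_CONDITIONS = GasConditions()


def ppbv_to_molar(c_ppbv: float, cond: GasConditions = STANDARD_CONDITIONS) -> float:
    """Convert a mole fraction in ppbv to a molar concentration (mol m⁻³)."""
    _require_finite_nonneg(c_ppbv, "concentration (ppbv)")
    return c_ppbv * 1e-9 * cond.molar_density


def molar_to_ppbv(c_molar: float, cond: GasConditions = STANDARD_CONDITIONS) -> float:
    """Convert a molar concentration (mol m⁻³) to ppbv; inverse of :func:`ppbv_to_molar`."""
    _require_finite_nonneg(c_molar, "concentration (mol m-3)")
    return c_molar / (1e-9 * cond.molar_density)


@dataclass(frozen=True)
class CtValue:
    """Concentration × time dose metric.

    Attributes
    ----------
    twa : float
        Time-weighted average concentration over the interval, ppbv.
    duration : float
        Exposure duration, minutes.
    value : float
        CT product, ppbv·min.
    """

    twa: float
    duration: float
    value: float = field(init=False)

    def __post_init__(self) -> None:
        _require_finite_nonneg(self.twa, "twa (ppbv)")
        _require_finite_nonneg(self.duration, "duration (min)")
        object.__setattr__(self, "value", self.twa * self.duration)


def ct_value(twa: float, duration: float) -> CtValue:
    """Build the CT dose metric from a TWA (ppbv) and a duration (minutes)."""
    return CtValue(twa=twa, duration=duration)


def equivalent_exposure_time(ct: CtValue, reference: float = 500.0) -> float:
    """Duration (min) of constant exposure at ``reference`` ppbv with the same CT.

    The default reference of 500 ppbv is the chlorine occupational
    permissible-exposure level; the equivalent time lets a single sampler
    reading be expressed as "x minutes at the limit".
    """
    _require_finite_nonneg(reference, "reference (ppbv)")
    if reference == 0:
        raise ValueError("reference (ppbv) must be positive, got 0")
    return ct.value / reference


@dataclass(frozen=True)
class GuidelineLimit:
    """One threshold-style exposure guideline.

    ``min_duration``/``max_duration`` (minutes) bound the averaging windows
    the guideline applies to; ``None`` means unbounded on that side.
    """

    label: str
    threshold_ppbv: float
    min_duration: float | None = None
    max_duration: float | None = None

    def applies(self, duration: float) -> bool:
        if self.min_duration is not None and duration < self.min_duration:
            return False
        if self.max_duration is not None and duration > self.max_duration:
            return False
        return True


#: Chlorine exposure guidelines: the occupational permissible exposure limit
#: and the acute exposure guideline level 1, both 500 ppbv; AEGL-1 is defined
#: for 10 min – 8 h averaging windows.
DEFAULT_GUIDELINES: tuple[GuidelineLimit, ...] = (
    GuidelineLimit("OSHA_PEL", 500.0),
    GuidelineLimit("AEGL-1", 500.0, min_duration=10.0, max_duration=480.0),
)


def guideline_flags(
    twa: float,
    duration: float,
    guidelines: tuple[GuidelineLimit, ...] = DEFAULT_GUIDELINES,
) -> set[str]:
    """Labels of every guideline whose threshold ``twa`` meets or exceeds.

    A guideline with a duration window is only evaluated when ``duration``
    falls inside it.
    """
    _require_finite_nonneg(twa, "twa (ppbv)")
    _require_finite_nonneg(duration, "duration (min)")
    return {
        g.label
        for g in guidelines
        if g.applies(duration) and twa >= g.threshold_ppbv
    }
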