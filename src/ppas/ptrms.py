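"""PTR/SRI-MS reference-series processing.

Molecular chlorine is detected as three isotopologues at m/z 70 (³⁵Cl³⁵Cl),
72 (³⁵Cl³⁷Cl + ³⁷Cl³⁵Cl) and 74 (³⁷Cl³⁷Cl).  The instantaneous chamber
concentration is obtained by summing the inside-minus-outside raw response
differences across the three channels and inverting a linear calibration.
The time-weighted average over a deployment window is the time integral of
the instantaneous series divided by the window length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Natural abundance of the ³⁵Cl isotope.
NATURAL_CL35_ABUNDANCE = 0.7577

CHANNEL_COLUMNS = ["time_min", "in_70", "in_72", "in_74", "out_70", "out_72", "out_74"]
CONCENTRATION_COLUMNS = ["time_min", "ppbv"]


def _as_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def _check_times(t: np.ndarray, name: str = "timestamps") -> None:
    if t.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError(f"{name} must be strictly increasing")


@dataclass(frozen=True)
class PtrmsCalibration:
    """Linear instrument calibration: total response = slope·C + intercept."""

    slope: float  # counts per ppbv
    intercept: float = 0.0  # counts

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError(f"calibration slope must be positive, got {self.slope!r}")


@dataclass(frozen=True)
class ChannelSeries:
    """Raw per-channel responses recorded inside and outside the chamber."""

    time_min: np.ndarray
    in_70: np.ndarray
    in_72: np.ndarray
    in_74: np.ndarray
    out_70: np.ndarray
    out_72: np.ndarray
    out_74: np.ndarray

    def __post_init__(self) -> None:
        for name in CHANNEL_COLUMNS:
            object.__setattr__(self, name, _as_array(getattr(self, name), name))
        _check_times(self.time_min)
        n = self.time_min.size
        for name in CHANNEL_COLUMNS[1:]:
            arr = getattr(self, name)
            if arr.size != n:
                raise ValueError(
                    f"channel {name} has length {arr.size}, expected {n}"
                )
            if np.any(arr < 0):
                raise ValueError(f"channel {name} contains negative responses")

    def net_response(self) -> np.ndarray:
        """Σ over m/z 70/72/74 of (inside − outside), per timestamp."""
        return (
            (self.in_70 - self.out_70)
            + (self.in_72 - self.out_72)
            + (self.in_74 - self.out_74)
        )


@dataclass(frozen=True)
class AirConcentrationSeries:
    """Timestamped instantaneous gas concentration, minutes / ppbv."""

    time_min: np.ndarray
    ppbv: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "time_min", _as_array(self.time_min, "time_min"))
        object.__setattr__(self, "ppbv", _as_array(self.ppbv, "ppbv"))
        _check_times(self.time_min)
        if self.ppbv.size != self.time_min.size:
            raise ValueError("time_min and ppbv must have equal lengths")
        if np.any(self.ppbv < 0):
            raise ValueError("concentrations must be non-negative")

    def at(self, t_min) -> np.ndarray:
        """Linearly interpolate the series; edge values held constant."""
        return np.interp(t_min, self.time_min, self.ppbv)


def isotopologue_fractions(cl35_abundance: float = NATURAL_CL35_ABUNDANCE) -> tuple[float, float, float]:
    """Binomial Cl₂ isotopologue fractions at m/z 70, 72, 74.

    For ³⁵Cl abundance p the dichlorine fractions are (p², 2p(1−p), (1−p)²),
    which sum to 1.
    """
    p = cl35_abundance
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"cl35_abundance must lie in [0, 1], got {p!r}")
    return (p * p, 2.0 * p * (1.0 - p), (1.0 - p) * (1.0 - p))


def instantaneous_concentration(
    channels: ChannelSeries,
    cal: PtrmsCalibration,
    negative_tolerance: float = 0.10,
) -> AirConcentrationSeries:
    """Instantaneous concentration from summed channel differences.

    Per timestamp: net = Σ_{m/z} (inside − outside); C = (net − intercept)/slope,
    floored at zero.  If more than ``negative_tolerance`` of the points are
    floored a warning is emitted (persistent negative responses suggest
    baseline drift, which this module does not correct).
    """
    net = channels.net_response()
    raw = (net - cal.intercept) / cal.slope
    floored = raw < 0
    if floored.mean() > negative_tolerance:
        warnings.warn(
            f"{floored.sum()} of {raw.size} points gave negative concentrations "
            "and were floored at zero; check instrument baseline",
            stacklevel=2,
        )
    return AirConcentrationSeries(channels.time_min, np.maximum(raw, 0.0))


def twa(series: AirConcentrationSeries, start: float, end: float) -> float:
    """Time-weighted average concentration (ppbv) over [start, end] minutes.

    Trapezoidal quadrature on the irregular timestamps, with linear
    interpolation at the window endpoints.  The window must lie inside the
    span of the series.
    """
    if not start < end:
        raise ValueError(f"window start {start} must precede end {end}")
    t, c = series.time_min, series.ppbv
    if start < t[0] or end > t[-1]:
        raise ValueError(
            f"window [{start}, {end}] min lies outside the series span "
            f"[{t[0]}, {t[-1]}] min"
        )
    inside = (t > start) & (t < end)
    t_w = np.concatenate(([start], t[inside], [end]))
    c_w = np.concatenate(([series.at(start)], c[inside], [series.at(end)]))
    return float(np.trapezoid(c_w, t_w) / (end - start))


# ---------------------------------------------------------------------------
# CSV interfaces.  Headers are mandatory; '#'-prefixed lines are comments.

def _read_csv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def read_channel_csv(path) -> ChannelSeries:
    df = _read_csv(path, CHANNEL_COLUMNS)
    return ChannelSeries(**{c: df[c].to_numpy() for c in CHANNEL_COLUMNS})


def write_channel_csv(channels: ChannelSeries, path, header_comment: str | None = None) -> None:
    df = pd.DataFrame({c: getattr(channels, c) for c in CHANNEL_COLUMNS})
    _write_csv(df, path, header_comment)


def read_concentration_csv(path) -> AirConcentrationSeries:
    df = _read_csv(path, CONCENTRATION_COLUMNS)
    return AirConcentrationSeries(df["time_min"].to_numpy(), df["ppbv"].to_numpy())


def write_concentration_csv(series: AirConcentrationSeries, path, header_comment: str | None = None) -> None:
    df = pd.DataFrame({"time_min": series.time_min, "ppbv": series.ppbv})
    _write_csv(df, path, header_comment)


def _write_csv(df: pd.DataFrame, path, header_comment: str | None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
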