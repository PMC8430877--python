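"""Extraction chemistry → TWA exposure estimation.

A deployed sampler is extracted overnight in isopropyl alcohol and the
remaining (unoxidized) o-dianisidine concentration is read by UV/Vis.  The
dye consumed gives the reacted-chlorine load per sampler volume

    C_s = (C_i − C_f) · V_E / (M_w · V_s · stoich)          [mol m⁻³]

with M_w = 244.30 g mol⁻¹ for o-dianisidine and stoich = 2 mol dye per mol
Cl₂.  Dividing the sampled mass C_s·V_s by the calibrated sampling rate and
deployment time yields the time-weighted average air concentration

    C_v,TWA = C_s · V_s / (R_s · t)                          [mol m⁻³]

which is converted to ppbv and a CT dose metric for guideline comparison.
Samplers near their dye capacity underestimate the TWA (uptake stalls at the
plateau); such results carry a saturation flag and should be read as lower
bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ppas.sampler_model import SamplerParams
from ppas.units import (
    CtValue,
    GasConditions,
    STANDARD_CONDITIONS,
    ct_value,
    guideline_flags,
    molar_to_ppbv,
)

#: Molecular weight of o-dianisidine, g mol⁻¹.
M_W_ODIANISIDINE = 244.30

#: Default extraction solvent volume, L (10 mL isopropyl alcohol).
DEFAULT_EXTRACTION_VOLUME = 0.01

#: C_s/C_cap ratio above which a sampler is flagged as saturating.
SATURATION_WARNING_FRACTION = 0.9

MEASUREMENT_COLUMNS = ["replicate_id", "deployment_h", "Ci_g_per_L", "Cf_g_per_L", "VE_L"]


@dataclass(frozen=True)
class ExtractionMeasurement:
    """One sampler's solvent-extraction record.

    ``C_i`` is the dye concentration an unexposed (blank) sampler yields and
    ``C_f`` the concentration after exposure, both in g L⁻¹ of extract.
    """

    C_i: float
    C_f: float
    deployment_h: float
    V_E: float = DEFAULT_EXTRACTION_VOLUME
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.C_i) and self.C_i >= 0):
            raise ValueError(f"C_i must be non-negative, got {self.C_i!r}")
        if not (math.isfinite(self.C_f) and self.C_f >= 0):
            raise ValueError(f"C_f must be non-negative, got {self.C_f!r}")
        if self.C_f > self.C_i:
            raise ValueError(
                f"C_f ({self.C_f!r}) exceeds C_i ({self.C_i!r}); "
                "exposure cannot create dye"
            )
        if not (math.isfinite(self.V_E) and self.V_E > 0):
            raise ValueError(f"V_E must be positive, got {self.V_E!r}")
        if not (math.isfinite(self.deployment_h) and self.deployment_h > 0):
            raise ValueError(f"deployment_h must be positive, got {self.deployment_h!r}")


@dataclass(frozen=True)
class ExposureSummary:
    """End product of the estimation chain for one sampler."""

    C_s: float                 # mol m⁻³ reacted chlorine per sampler volume
    M_sampled: float           # mol chlorine captured
    C_v_TWA_molar: float       # mol m⁻³ TWA air concentration
    C_v_TWA_ppbv: float
    ct: CtValue
    saturation_fraction: float
    flags: frozenset[str] = field(default_factory=frozenset)

    @property
    def saturated(self) -> bool:
        return "SATURATION" in self.flags


def cs_from_extraction(m: ExtractionMeasurement, params: SamplerParams) -> float:
    """Reacted-chlorine load C_s (mol m⁻³) from one extraction record."""
    return (m.C_i - m.C_f) * m.V_E / M_W_ODIANISIDINE / params.V_s / params.stoich


def delta_extraction_from_cs(C_s: float, params: SamplerParams,
                             V_E: float = DEFAULT_EXTRACTION_VOLUME) -> float:
    """Inverse map: dye concentration drop (C_i − C_f, g L⁻¹) producing C_s."""
    if C_s < 0:
        raise ValueError(f"C_s must be non-negative, got {C_s!r}")
    return C_s * M_W_ODIANISIDINE * params.V_s * params.stoich / V_E


def cv_twa_from_cs(
    C_s: float,
    params: SamplerParams,
    deployment_h: float,
    cond: GasConditions = STANDARD_CONDITIONS,
) -> ExposureSummary:
    """TWA air concentration and CT dose from a reacted-chlorine load."""
    if deployment_h <= 0:
        raise ValueError(f"deployment_h must be positive, got {deployment_h!r}")
    if C_s < 0:
        raise ValueError(f"C_s must be non-negative, got {C_s!r}")
    M_sampled = C_s * params.V_s
    C_v_molar = M_sampled / (params.R_s * deployment_h)
    C_v_ppbv = molar_to_ppbv(C_v_molar, cond)
    duration_min = deployment_h * 60.0
    ct = ct_value(C_v_ppbv, duration_min)
    flags = set(guideline_flags(C_v_ppbv, duration_min))
    saturation = C_s / params.C_cap
    if saturation >= SATURATION_WARNING_FRACTION:
        flags.add("SATURATION")
    return ExposureSummary(
        C_s=C_s,
        M_sampled=M_sampled,
        C_v_TWA_molar=C_v_molar,
        C_v_TWA_ppbv=C_v_ppbv,
        ct=ct,
        saturation_fraction=saturation,
        flags=frozenset(flags),
    )


def estimate_exposure(
    m: ExtractionMeasurement,
    params: SamplerParams,
    cond: GasConditions = STANDARD_CONDITIONS,
) -> ExposureSummary:
    """Full chain for one measurement: extraction → C_s → TWA/CT summary."""
    return cv_twa_from_cs(cs_from_extraction(m, params), params, m.deployment_h, cond)


def absorbance_to_concentration(absorbance: float, slope: float, intercept: float = 0.0) -> float:
    """Invert a linear Beer–Lambert calibration (AU per g L⁻¹), floored at 0."""
    if slope <= 0:
        raise ValueError(f"calibration slope must be positive, got {slope!r}")
    if absorbance < 0:
        raise ValueError(f"absorbance must be non-negative, got {absorbance!r}")
    return max((absorbance - intercept) / slope, 0.0)


def batch_report(
    measurements: list[ExtractionMeasurement],
    params: SamplerParams,
    cond: GasConditions = STANDARD_CONDITIONS,
) -> pd.DataFrame:
    """Per-replicate exposure summaries plus per-deployment-time aggregates.

    Returns one ``replicate`` row per measurement and, for each deployment
    time, a ``summary`` row carrying the mean and the sample (n−1) standard
    deviation of C_s and of the TWA in ppbv (NaN when only one replicate).
    """
    if not measurements:
        raise ValueError("batch_report requires at least one measurement")
    rows = []
    for m in measurements:
        s = estimate_exposure(m, params, cond)
        rows.append({
            "row_type": "replicate",
            "replicate_id": m.replicate_id,
            "deployment_h": m.deployment_h,
            "C_s_mol_m3": s.C_s,
            "M_sampled_mol": s.M_sampled,
            "C_v_TWA_mol_m3": s.C_v_TWA_molar,
            "C_v_TWA_ppbv": s.C_v_TWA_ppbv,
            "ct_ppbv_min": s.ct.value,
            "saturation_fraction": s.saturation_fraction,
            "flags": ";".join(sorted(s.flags)),
        })
    reps = pd.DataFrame(rows)
    summaries = []
    for dep, grp in reps.groupby("deployment_h", sort=True):
        n = len(grp)
        summaries.append({
            "row_type": "summary",
            "replicate_id": f"mean_of_{n}",
            "deployment_h": dep,
            "C_s_mol_m3": grp["C_s_mol_m3"].mean(),
            "C_s_sd": grp["C_s_mol_m3"].std(ddof=1) if n > 1 else np.nan,
            "C_v_TWA_ppbv": grp["C_v_TWA_ppbv"].mean(),
            "C_v_TWA_ppbv_sd": grp["C_v_TWA_ppbv"].std(ddof=1) if n > 1 else np.nan,
            "flags": ";".join(sorted(set().union(*[set(f.split(";")) - {""} for f in grp["flags"]]))),
        })
    return pd.concat([reps, pd.DataFrame(summaries)], ignore_index=True)


def read_measurements_csv(path) -> list[ExtractionMeasurement]:
    """Read extraction records; columns replicate_id, deployment_h, Ci_g_per_L, Cf_g_per_L, VE_L."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        raise ValueError(f"{path}: no measurement rows")
    out = []
    for idx, row in df.iterrows():
        try:
            out.append(ExtractionMeasurement(
                replicate_id=str(row["replicate_id"]),
                deployment_h=float(row["deployment_h"]),
                C_i=float(row["Ci_g_per_L"]),
                C_f=float(row["Cf_g_per_L"]),
                V_E=float(row["VE_L"]),
            ))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: invalid measurement in row {idx}: {exc}") from exc
    return out


def write_measurements_csv(measurements: list[ExtractionMeasurement], path,
                           header_comment: str | None = None) -> None:
    df = pd.DataFrame({
        "replicate_id": [m.replicate_id for m in measurements],
        "deployment_h": [m.deployment_h for m in measurements],
        "Ci_g_per_L": [m.C_i for m in measurements],
        "Cf_g_per_L": [m.C_f for m in measurements],
        "VE_L": [m.V_E for m in measurements],
    })
    from ppas.ptrms import _write_csv

    _write_csv(df, path, header_comment)
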