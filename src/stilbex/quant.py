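"""UV calibration, dry-weight quantification, and [M-H]- mass annotation.

Calibration is ordinary least squares of detector response on
concentration.  Detection and quantification limits follow the ICH-style
residual formulas LOD = 3.3 s_res / slope and LOQ = 10 s_res / slope,
where ``s_res`` is the standard deviation of the fit residuals.

Extraction contents are back-calculated to milligrams of analyte per gram
of dry plant weight (mg/g DW): concentration (mg/L) times extract volume
(L) times dilution, over sample mass (g).

Annotation assigns negative-mode pseudo-molecular ions: a peak of measured
m/z matches a candidate when ``|mz - (M_mono - 1.00728)| <= tolerance``
(deprotonation removes one proton); ties go to the nearest mass and
unmatched ions are reported as "unknown".  The default 0.5 Da tolerance
suits nominal-resolution ion-trap data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PROTON_MASS",
    "CalibrationCurve",
    "ExtractionContent",
    "fit_calibration",
    "quantify",
    "annotate",
    "selectivity_diff",
]

PROTON_MASS = 1.00728  # Da


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear response curve with ICH-style limits."""

    analyte: str
    levels: Tuple[float, ...]  # mg/L
    responses: Tuple[float, ...]
    slope: float
    intercept: float
    r_squared: float
    lod: float  # mg/L
    loq: float  # mg/L
    working_range: Tuple[float, float]

    def __post_init__(self):
        if len(self.levels) < 5:
            raise ValueError("calibration needs >= 5 levels")
        if self.r_squared > 1 + 1e-12:
            raise ValueError("r_squared cannot exceed 1")
        if self.lod >= self.loq and self.lod > 0:
            raise ValueError("LOD must be below LOQ")

    def concentration(self, response: float) -> float:
        return (response - self.intercept) / self.slope


@dataclass(frozen=True)
class ExtractionContent:
    """Analyte content on a dry-weight basis."""

    analyte: str
    content: float  # mg/g DW
    sd: float = 0.0
    n: int = 1

    def __post_init__(self):
        if self.content < 0:
            raise ValueError("content cannot be negative")
        if self.n < 1:
            raise ValueError("need at least one replicate")


def fit_calibration(
    levels: Sequence[float],
    responses: Sequence[float],
    analyte: str = "",
) -> CalibrationCurve:
    """Ordinary least squares of response on concentration level."""
    x = np.asarray(levels, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size != y.size:
        raise ValueError("levels and responses must pair up")
    if np.unique(x).size < 5:
        raise ValueError("calibration needs >= 5 distinct levels")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in levels")
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    dof = x.size - 2
    s_res = float(np.sqrt(np.sum(resid**2) / dof)) if dof > 0 else 0.0
    lod = 3.3 * s_res / abs(fit.slope)
    loq = 10.0 * s_res / abs(fit.slope)
    return CalibrationCurve(
        analyte=analyte,
        levels=tuple(x),
        responses=tuple(y),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=round(float(fit.rvalue) ** 2, 4),
        lod=lod,
        loq=loq,
        working_range=(float(x.min()), float(x.max())),
    )


def quantify(
    response: float,
    curve: CalibrationCurve,
    extract_volume_l: float,
    sample_mass_g: float,
    dilution: float = 1.0,
    analyte: Optional[str] = None,
) -> ExtractionContent:
    """Back-calculate mg analyte per g dry weight from one response.

    content = c (mg/L) * V (L) * dilution / m (g).  Responses outside the
    calibrated working range trigger a warning, negative back-calculated
    concentrations an error.
    """
    if extract_volume_l <= 0 or sample_mass_g <= 0 or dilution <= 0:
        raise ValueError("volume, mass and dilution must be positive")
    conc = curve.concentration(response)
    if conc < 0:
        raise ValueError(f"negative back-calculated concentration {conc:.3g} mg/L")
    lo, hi = curve.working_range
    if not lo <= conc <= hi:
        warnings.warn(
            f"concentration {conc:.3g} mg/L outside working range [{lo}, {hi}]",
            stacklevel=2,
        )
    content = conc * extract_volume_l * dilution / sample_mass_g
    return ExtractionContent(
        analyte=analyte if analyte is not None else curve.analyte,
        content=content,
    )


def annotate(
    mz_list: Sequence[float],
    mass_table: pd.DataFrame,
    tolerance: float = 0.5,
) -> Tuple[pd.DataFrame, int]:
    """Assign [M-H]- ions against a candidate mass table.

    `mass_table` needs columns ``name`` and ``monoisotopic_mass`` (neutral,
    Da).  Returns the annotation table and the number of assigned ions.
    Deterministic, and monotone in tolerance: widening it never
    un-assigns an ion.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    if mass_table.empty:
        raise ValueError("empty candidate mass table")
    names = mass_table["name"].to_numpy()
    target_mz = mass_table["monoisotopic_mass"].to_numpy(dtype=float) - PROTON_MASS
    rows = []
    n_assigned = 0
    for mz in mz_list:
        if mz <= 0:
            raise ValueError("m/z must be positive")
        diff = np.abs(target_mz - mz)
        j = int(np.argmin(diff))
        if diff[j] <= tolerance:
            assignment = str(names[j])
            n_assigned += 1
            delta = float(mz - target_mz[j])
        else:
            assignment, delta = "unknown", np.nan
        rows.append({"mz": float(mz), "assignment": assignment, "delta_mz": delta})
    return pd.DataFrame(rows), n_assigned


def selectivity_diff(
    table_a: pd.DataFrame, table_b: pd.DataFrame
) -> Dict[str, Set[Tuple[str, int]]]:
    """Shared/unique assignments between two annotated extracts.

    Keys on (assignment, nominal m/z) so two distinct ions with the same
    assignment (e.g. isomeric dimers) are kept apart.
    """
    def keys(t: pd.DataFrame) -> Set[Tuple[str, int]]:
        return {
            (str(row["assignment"]), int(round(row["mz"])))
            for _, row in t.iterrows()
        }

    a, b = keys(table_a), keys(table_b)
    return {
        "shared": a & b,
        "unique_to_a": a - b,
        "unique_to_b": b - a,
    }
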