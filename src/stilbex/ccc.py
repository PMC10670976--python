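"""Countercurrent-chromatography retention bookkeeping.

With a liquid stationary phase retained in the coil, retention reduces to
exact volume arithmetic.  For a coil of volume ``V_C`` holding a stationary
fraction ``S_F`` (%), the stationary and mobile volumes are
``V_S = (S_F/100) V_C`` and ``V_M = V_C - V_S + V_ext`` (``V_ext`` being
peripheral tubing), and a solute of partition ratio ``K_D`` elutes at

    V_R = V_M + K_D * V_S

The module provides this relation and its inverse, fraction planning
(1-based indices, half-open volume intervals), heart-cut pooling of a
co-eluting window for re-chromatography, recovery/purity mass balance, and
peak resolution ``R_S = 2 |V_Rb - V_Ra| / (w_a + w_b)`` for simulated
chromatograms with known baseline widths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

__all__ = [
    "CoilSystem",
    "CCCPeak",
    "MassBalance",
    "HeartCut",
    "stationary_fraction",
    "kd_from_retention",
    "retention_volume",
    "plan_fractions",
    "heart_cut",
    "recovery_report",
    "resolution",
]


@dataclass(frozen=True)
class CoilSystem:
    """Coil geometry and run parameters of a CCC instrument."""

    V_C: float  # total coil volume, mL
    flow: float  # mL/min
    V_ext: float = 0.0  # periphery tubing volume, mL
    rotation: Optional[float] = None  # rpm
    mode: str = "head-to-tail"
    mobile_phase: str = "lower"

    def __post_init__(self):
        if self.V_C <= 0:
            raise ValueError("coil volume must be positive")
        if self.flow <= 0:
            raise ValueError("flow must be positive")
        if self.V_ext < 0:
            raise ValueError("periphery volume cannot be negative")
        if self.mode not in ("head-to-tail", "tail-to-head"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mobile_phase not in ("lower", "upper"):
            raise ValueError("mobile_phase must be 'lower' or 'upper'")


@dataclass(frozen=True)
class CCCPeak:
    """An eluted peak; width is known only for simulated chromatograms."""

    solute: str
    V_R: float  # retention volume, mL
    K_D: Optional[float] = None
    R_t: Optional[float] = None  # retention time, min
    fraction_span: Optional[Tuple[int, int]] = None
    width: Optional[float] = None  # baseline width, mL

    def __post_init__(self):
        if self.V_R < 0:
            raise ValueError("retention volume cannot be negative")
        if self.width is not None and self.width <= 0:
            raise ValueError("peak width must be positive")


@dataclass(frozen=True)
class MassBalance:
    """Injected mass versus recovered per-compound masses (mg)."""

    injected_mass: float
    recovered: Dict[str, float]
    purity: Optional[Dict[str, float]] = None  # % at stated wavelength
    wavelength_nm: Optional[float] = None

    def __post_init__(self):
        if self.injected_mass <= 0:
            raise ValueError("injected mass must be positive")
        for name, mass in self.recovered.items():
            if mass < 0:
                raise ValueError(f"{name}: negative recovered mass")
            if mass > self.injected_mass:
                raise ValueError(f"{name}: recovered exceeds injected")
        if self.purity:
            for name, pur in self.purity.items():
                if not 0 <= pur <= 100:
                    raise ValueError(f"{name}: purity outside 0-100%")


@dataclass(frozen=True)
class HeartCut:
    """A pooled co-eluting window destined for a second separation."""

    t_start: float  # min
    t_end: float  # min
    pooled_volume: float  # mL
    solutes: Tuple[str, ...]


def stationary_fraction(V_S: float, V_C: float) -> float:
    """Stationary-phase retention S_F [%] = V_S / V_C * 100."""
    if V_C <= 0:
        raise ValueError("coil volume must be positive")
    if not 0 <= V_S <= V_C:
        raise ValueError("V_S must lie within [0, V_C]")
    return V_S / V_C * 100.0


def _volumes(S_F_pct: float, V_C: float, V_ext: float) -> Tuple[float, float]:
    if not 0 <= S_F_pct <= 100:
        raise ValueError("S_F must be a percentage in [0, 100]")
    if V_C <= 0:
        raise ValueError("coil volume must be positive")
    V_S = S_F_pct / 100.0 * V_C
    V_M = V_C - V_S + V_ext
    return V_S, V_M


def kd_from_retention(
    V_R: float, S_F_pct: float, V_C: float, V_ext: float = 0.0
) -> float:
    """K_D = (V_R - V_M) / V_S from a measured retention volume."""
    V_S, V_M = _volumes(S_F_pct, V_C, V_ext)
    if V_S == 0:
        raise ValueError("no stationary phase retained: K_D undefined")
    if V_R < V_M - 1e-12:
        raise ValueError(
            f"V_R={V_R} mL elutes before the solvent front (V_M={V_M} mL)"
        )
    return (V_R - V_M) / V_S


def retention_volume(
    K_D: float, S_F_pct: float, V_C: float, V_ext: float = 0.0
) -> float:
    """V_R = V_M + K_D * V_S — exact inverse of :func:`kd_from_retention`."""
    if K_D < 0:
        raise ValueError("K_D cannot be negative")
    V_S, V_M = _volumes(S_F_pct, V_C, V_ext)
    return V_M + K_D * V_S


def plan_fractions(
    flow: float, fraction_minutes: float, total_minutes: float
) -> List[Tuple[int, float, float]]:
    """Fraction index -> half-open volume interval [start, end), mL.

    Indices are 1-based; intervals partition the run volume without gaps
    or overlaps.  A ragged final fraction covers the remainder.
    """
    if flow <= 0 or fraction_minutes <= 0 or total_minutes <= 0:
        raise ValueError("flow, fraction length and run length must be positive")
    per_fraction = flow * fraction_minutes
    total_volume = flow * total_minutes
    plan = []
    idx, start = 1, 0.0
    while start < total_volume - 1e-12:
        end = min(start + per_fraction, total_volume)
        plan.append((idx, start, end))
        idx += 1
        start = end
    return plan


def fraction_of_volume(
    plan: Sequence[Tuple[int, float, float]], volume: float
) -> int:
    """Index of the fraction whose half-open interval contains `volume`."""
    for idx, start, end in plan:
        if start <= volume < end:
            return idx
    raise ValueError(f"volume {volume} mL outside the planned run")


def heart_cut(
    peaks: Sequence[CCCPeak],
    window_minutes: Tuple[float, float],
    flow: float,
) -> HeartCut:
    """Pool the time window [t0, t1] and list the solutes eluting in it."""
    t0, t1 = window_minutes
    if t1 <= t0:
        raise ValueError("heart-cut window must have positive length")
    if flow <= 0:
        raise ValueError("flow must be positive")
    v0, v1 = t0 * flow, t1 * flow
    inside = tuple(p.solute for p in peaks if v0 <= p.V_R <= v1)
    return HeartCut(
        t_start=t0, t_end=t1, pooled_volume=flow * (t1 - t0), solutes=inside
    )


def recovery_report(balance: MassBalance) -> Dict[str, float]:
    """Per-compound yield % = recovered / injected * 100, to 1 decimal."""
    return {
        name: round(mass / balance.injected_mass * 100.0, 1)
        for name, mass in balance.recovered.items()
    }


def resolution(peak_a: CCCPeak, peak_b: CCCPeak) -> float:
    """R_S = 2 |V_Rb - V_Ra| / (w_a + w_b) from baseline widths."""
    if peak_a.width is None or peak_b.width is None:
        raise ValueError("both peaks need widths (simulated chromatograms only)")
    return 2.0 * abs(peak_b.V_R - peak_a.V_R) / (peak_a.width + peak_b.width)
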