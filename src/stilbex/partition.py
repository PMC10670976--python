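"""Partition-ratio prediction and biphasic solvent-system selection for CCC.

The partition ratio of a solute between the stationary upper and mobile
lower phase of a biphasic system is obtained from infinite-dilution
activity coefficients in the two phases and the phase molar volumes:

    K_D = c_u / c_l = (gamma_inf_lower / gamma_inf_upper) * (v_l / v_u)

The convention is fixed to head-to-tail operation: concentration in the
stationary *upper* phase over the mobile *lower* phase.  Swapping phases is
an explicit operation and inverts K_D exactly.

Selection applies the classical CCC "sweet spot" 0.4 <= K_D <= 2.5 to every
target, discards systems whose target pair separates too poorly
(separation factor alpha below a threshold), and ranks the survivors by the
larger minimum target K_D — a solute that is retained more strongly leaves
less room for co-elution of polar matrix components at the solvent front —
with alpha as tie-break.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Tuple

import pandas as pd

from .engine import EngineParams, MixtureState, ln_gamma_infinite_dilution
from .lle import PhaseSplit
from .sigma import ComponentRecord

__all__ = [
    "SelectionCriteria",
    "PartitionTable",
    "SelectionReport",
    "compute_kd",
    "separation_factor",
    "select_system",
    "kd_comparison_report",
]


def compute_kd(
    solute: ComponentRecord,
    split: PhaseSplit,
    T: float,
    params: EngineParams = EngineParams(),
) -> float:
    """Partition ratio of `solute` in a converged phase split at `T` (K).

    The separation temperature may differ from the temperature at which
    the split itself was solved (CCC practice equilibrates the solvent
    system at bench temperature but runs the coil thermostatted); the phase
    compositions are used as-is.
    """
    upper = MixtureState(split.components, split.x_upper, T)
    lower = MixtureState(split.components, split.x_lower, T)
    lg_u = ln_gamma_infinite_dilution(solute, upper, params)
    lg_l = ln_gamma_infinite_dilution(solute, lower, params)
    return math.exp(lg_l - lg_u) * (split.v_lower / split.v_upper)


def separation_factor(k_a: float, k_b: float) -> float:
    """alpha = K_larger / K_smaller (>= 1). Unrounded; round at reporting."""
    if k_a <= 0 or k_b <= 0:
        raise ValueError("partition ratios must be positive")
    return max(k_a, k_b) / min(k_a, k_b)


def kd_comparison_report(calculated: float, experimental: float) -> float:
    """Absolute deviation |K_calc - K_exp|, reported to 2 decimals."""
    if calculated <= 0 or experimental <= 0:
        raise ValueError("partition ratios must be positive")
    return round(abs(calculated - experimental), 2)


@dataclass(frozen=True)
class SelectionCriteria:
    """Sweet-spot window and separation-factor threshold."""

    k_min: float = 0.4
    k_max: float = 2.5
    min_alpha: float = 1.3
    anti_coelution_margin: float = 0.0  # minimum K_D of the earliest target

    def __post_init__(self):
        if not 0 < self.k_min < self.k_max:
            raise ValueError("require 0 < k_min < k_max")
        if self.min_alpha < 1:
            raise ValueError("min_alpha must be >= 1")


@dataclass
class PartitionTable:
    """K_D per (system, solute) with per-system separation factors."""

    rows: List[Tuple[str, str, float]]  # (system_id, solute, K_D)

    def __post_init__(self):
        for sys_id, solute, kd in self.rows:
            if kd <= 0:
                raise ValueError(f"{sys_id}/{solute}: K_D must be positive")

    @property
    def systems(self) -> List[str]:
        seen = []
        for sys_id, _, _ in self.rows:
            if sys_id not in seen:
                seen.append(sys_id)
        return seen

    def kd_by_system(self) -> Dict[str, Dict[str, float]]:
        out: Dict[str, Dict[str, float]] = {}
        for sys_id, solute, kd in self.rows:
            out.setdefault(sys_id, {})[solute] = kd
        return out

    def alpha(self, system_id: str) -> float:
        """Minimum pairwise separation factor among the system's solutes."""
        kds = list(self.kd_by_system()[system_id].values())
        if len(kds) < 2:
            raise ValueError(f"{system_id}: need >= 2 solutes for alpha")
        return min(separation_factor(a, b) for a, b in combinations(kds, 2))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows, columns=["system_id", "solute", "K_D"])
        df["alpha"] = df["system_id"].map(lambda s: self.alpha(s))
        return df


@dataclass
class SelectionReport:
    """Ranked surviving systems plus per-system exclusion reasons."""

    ranking: List[str]
    excluded: Dict[str, str]
    table: pd.DataFrame = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rank, sys_id in enumerate(self.ranking, start=1):
            rows.append({"system_id": sys_id, "rank": rank, "reason": "selected"})
        for sys_id, reason in self.excluded.items():
            rows.append({"system_id": sys_id, "rank": None, "reason": reason})
        return pd.DataFrame(rows)


def select_system(
    table: PartitionTable,
    criteria: SelectionCriteria = SelectionCriteria(),
) -> SelectionReport:
    """Apply sweet-spot and separation-factor rules; rank the survivors.

    Deterministic and invariant to the order systems appear in the table:
    survivors are sorted by (min target K_D, alpha, system_id) descending on
    the numeric keys.  An empty survivor set yields an empty ranking, not
    an error.
    """
    by_system = table.kd_by_system()
    if not by_system:
        return SelectionReport(ranking=[], excluded={}, table=pd.DataFrame())
    if any(len(v) < 2 for v in by_system.values()):
        raise ValueError("selection needs >= 2 solutes per system")

    excluded: Dict[str, str] = {}
    survivors: List[Tuple[float, float, str]] = []
    for sys_id in sorted(by_system):
        kds = by_system[sys_id]
        out_of_window = {
            sol: kd
            for sol, kd in kds.items()
            if not (criteria.k_min <= kd <= criteria.k_max)
        }
        if out_of_window:
            worst = ", ".join(
                f"{sol} K_D={kd:.2f}" for sol, kd in sorted(out_of_window.items())
            )
            excluded[sys_id] = (
                f"outside sweet spot [{criteria.k_min}, {criteria.k_max}]: {worst}"
            )
            continue
        alpha = table.alpha(sys_id)
        if alpha < criteria.min_alpha:
            excluded[sys_id] = (
                f"separation factor {alpha:.2f} below {criteria.min_alpha:.2f}"
            )
            continue
        min_kd = min(kds.values())
        if min_kd < criteria.anti_coelution_margin:
            excluded[sys_id] = (
                f"earliest target K_D={min_kd:.2f} below anti-co-elution margin"
            )
            continue
        survivors.append((min_kd, alpha, sys_id))

    survivors.sort(key=lambda t: (-t[0], -t[1], t[2]))
    ranking = [sys_id for _, _, sys_id in survivors]
    return SelectionReport(ranking=ranking, excluded=excluded, table=table.to_frame())
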