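"""Screening of deep-eutectic-solvent formulations by ln gamma at infinite dilution.

A natural deep eutectic solvent (NADES) is specified by a hydrogen-bond
acceptor (HBA), a hydrogen-bond donor (HBD), their molar ratio, and an
optional water content in mass percent.  Mixtures are treated as
pseudo-liquids of the two (or three) neutral species; a salt HBA such as
choline chloride enters as one undissociated ion-pair species with a single
sigma profile, and organic acids as their protonated forms.

The figure of merit is ln gamma of the target solute at infinite dilution
at 25 degC: the lower it is, the better the formulation is expected to
solubilise — and hence extract — the solute.  The screen is deterministic
and cell-cached, rankings sort ascending ln gamma, and predicted
ln gamma can be correlated (Pearson) against measured extraction contents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .engine import EngineParams, MixtureState, ln_gamma_infinite_dilution
from .sigma import ComponentRecord

__all__ = [
    "CANONICAL_RATIOS",
    "WATER_GRID_DEFAULT",
    "NADESSpec",
    "ScreeningGrid",
    "CorrelationReport",
    "nades_composition",
    "screen",
    "rank_specs",
    "correlate",
    "heatmap_export",
]

#: HBA:HBD stoichiometries of the standard screen
CANONICAL_RATIOS = ((3, 1), (2, 1), (1, 1), (1, 2), (1, 3))
#: default water lattice, wt% (the screen spans 0-70 wt%)
WATER_GRID_DEFAULT = (0, 10, 20, 30, 40, 50, 60, 70)

WATER_MOLAR_MASS = 18.015


@dataclass(frozen=True)
class NADESSpec:
    """One formulation: HBA, HBD, molar ratio and water mass fraction.

    Ratios outside the canonical screening set (e.g. 1/5) are legal but
    must be flagged with ``nonstandard_ratio=True`` so accidental typos in
    bulk screens fail loudly.  ``preparable`` is an experimental
    annotation (some combinations recrystallise); it is never predicted.
    """

    hba: ComponentRecord
    hbd: ComponentRecord
    ratio: Tuple[int, int]  # hba : hbd
    water_wt_pct: float = 0.0
    nonstandard_ratio: bool = False
    preparable: Optional[bool] = None

    def __post_init__(self):
        num, den = self.ratio
        if num <= 0 or den <= 0:
            raise ValueError("molar ratio parts must be positive")
        if not 0 <= self.water_wt_pct <= 70:
            raise ValueError("water content must be within 0-70 wt%")
        if tuple(self.ratio) not in CANONICAL_RATIOS and not self.nonstandard_ratio:
            raise ValueError(
                f"ratio {num}/{den} outside the canonical set "
                f"{CANONICAL_RATIOS}; pass nonstandard_ratio=True to allow"
            )

    @property
    def key(self) -> str:
        return (
            f"{self.hba.name}/{self.hbd.name} {self.ratio[0]}/{self.ratio[1]} "
            f"{self.water_wt_pct:g}wt%"
        )


def nades_composition(
    spec: NADESSpec, water: Optional[ComponentRecord] = None
) -> np.ndarray:
    """Mole fractions (hba, hbd, water) of a formulation.

    The water content is interpreted as mass of water over total mixture
    mass (HBA + HBD + water).
    """
    n_a, n_d = float(spec.ratio[0]), float(spec.ratio[1])
    dry_mass = n_a * spec.hba.molar_mass + n_d * spec.hbd.molar_mass
    w = spec.water_wt_pct / 100.0
    m_w = WATER_MOLAR_MASS if water is None else water.molar_mass
    n_w = 0.0 if w == 0 else (w / (1.0 - w)) * dry_mass / m_w
    x = np.array([n_a, n_d, n_w])
    return x / x.sum()


@dataclass
class ScreeningGrid:
    """Long-form result table: one ln gamma per (spec, solute)."""

    entries: pd.DataFrame  # columns: spec, hba, hbd, ratio, water_wt_pct, solute, ln_gamma, T_C, error
    T_C: float = 25.0

    def for_solute(self, solute: str) -> pd.DataFrame:
        return self.entries[self.entries["solute"] == solute]


@dataclass(frozen=True)
class CorrelationReport:
    """Pearson correlation of predicted ln gamma with measured content."""

    solute: str
    r: float
    p_value: float
    n: int
    pairs: Tuple[str, ...]
    dropped: Tuple[str, ...] = ()

    def __post_init__(self):
        if not -1 <= self.r <= 1 + 1e-12:
            raise ValueError("Pearson r outside [-1, 1]")
        if self.n < 3:
            raise ValueError("need at least 3 paired observations")


def screen(
    solutes: Sequence[ComponentRecord],
    specs: Sequence[NADESSpec],
    T_C: float = 25.0,
    params: EngineParams = EngineParams(),
    water: Optional[ComponentRecord] = None,
    _cache: Optional[dict] = None,
) -> ScreeningGrid:
    """ln gamma at infinite dilution of each solute in each formulation.

    Per-cell engine failures are recorded in the grid (``ln_gamma`` NaN,
    ``error`` message) rather than aborting the screen.  Cells are cached
    by (spec key, solute name) so interrupted screens can resume by
    passing the same cache dict.
    """
    if water is None and any(s.water_wt_pct > 0 for s in specs):
        raise ValueError("a water ComponentRecord is required for hydrated specs")
    T = T_C + 273.15
    cache = {} if _cache is None else _cache
    rows = []
    for spec in specs:
        x3 = nades_composition(spec, water)
        comps = [spec.hba, spec.hbd] + ([water] if x3[2] > 0 else [])
        x = x3 if x3[2] > 0 else x3[:2] / x3[:2].sum()
        for solute in solutes:
            ck = (spec.key, solute.name, T_C)
            if ck in cache:
                lng, err = cache[ck]
            else:
                try:
                    state = MixtureState(comps, x, T)
                    lng = ln_gamma_infinite_dilution(solute, state, params)
                    err = ""
                except Exception as exc:  # recorded in-grid, not fatal
                    lng, err = math.nan, str(exc)
                cache[ck] = (lng, err)
            rows.append(
                {
                    "spec": spec.key,
                    "hba": spec.hba.name,
                    "hbd": spec.hbd.name,
                    "ratio": f"{spec.ratio[0]}/{spec.ratio[1]}",
                    "water_wt_pct": spec.water_wt_pct,
                    "solute": solute.name,
                    "ln_gamma": lng,
                    "T_C": T_C,
                    "error": err,
                }
            )
    return ScreeningGrid(entries=pd.DataFrame(rows), T_C=T_C)


def rank_specs(grid: ScreeningGrid, solute: str) -> pd.DataFrame:
    """Formulations ordered by ascending ln gamma (best solubiliser first).

    Stable sort; exact ties break lexicographically on
    (hba, hbd, ratio, water).  Failed cells are dropped.
    """
    df = grid.for_solute(solute).dropna(subset=["ln_gamma"]).copy()
    if df.empty:
        return df
    df = df.sort_values(
        by=["ln_gamma", "hba", "hbd", "ratio", "water_wt_pct"],
        kind="mergesort",
    ).reset_index(drop=True)
    df.index += 1
    df.index.name = "rank"
    return df


def correlate(
    lngamma_by_spec: Mapping[str, float],
    content_by_spec: Mapping[str, float],
    solute: str = "",
    alpha: float = 0.05,
) -> CorrelationReport:
    """Pearson r between predicted ln gamma and measured content (mg/g DW).

    Pairs match on spec identity; specs present in only one table are
    dropped and reported.  Raises on zero variance in either vector.
    """
    shared = sorted(set(lngamma_by_spec) & set(content_by_spec))
    dropped = tuple(
        sorted((set(lngamma_by_spec) | set(content_by_spec)) - set(shared))
    )
    if len(shared) < 3:
        raise ValueError(f"need >= 3 paired specs, got {len(shared)}")
    x = np.array([lngamma_by_spec[k] for k in shared], dtype=float)
    y = np.array([content_by_spec[k] for k in shared], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y)
    return CorrelationReport(
        solute=solute,
        r=float(res.statistic),
        p_value=float(res.pvalue),
        n=len(shared),
        pairs=tuple(shared),
        dropped=dropped,
    )


def heatmap_export(
    grid: ScreeningGrid,
    solute: str,
    csv_path=None,
    figure_path=None,
):
    """HBD x HBA matrix of ln gamma for one solute.

    Column labels carry the molar ratio (``HBA r_n/r_d``).  The selection
    must be rectangular: every (HBD, HBA-with-ratio) cell at a single water
    level per column set, otherwise the missing cells are listed in the
    error.  Returns the matrix DataFrame; optionally writes CSV and renders
    a figure.
    """
    df = grid.for_solute(solute)
    if df.empty:
        raise ValueError(f"no screening entries for solute {solute!r}")
    df = df.copy()
    df["col"] = df["hba"] + " " + df["ratio"] + " " + df["water_wt_pct"].map(
        "{:g}wt%".format
    )
    matrix = df.pivot_table(
        index="hbd", columns="col", values="ln_gamma", aggfunc="first"
    )
    if matrix.isna().any().any():
        missing = [
            f"({i}, {c})"
            for i in matrix.index
            for c in matrix.columns
            if pd.isna(matrix.loc[i, c])
        ]
        raise ValueError(f"ragged selection; missing cells: {', '.join(missing)}")
    if csv_path is not None:
        matrix.to_csv(csv_path)
    if figure_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(1.0 + 0.6 * matrix.shape[1], 1.0 + 0.35 * matrix.shape[0])
        )
        im = ax.imshow(matrix.values, aspect="auto", cmap="viridis")
        ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=45, ha="right")
        ax.set_yticks(range(matrix.shape[0]), matrix.index)
        ax.set_title(f"ln gamma of {solute} ({grid.T_C:g} degC)")
        fig.colorbar(im, ax=ax, label="ln gamma")
        fig.tight_layout()
        fig.savefig(figure_path, dpi=150)
        plt.close(fig)
    return matrix
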