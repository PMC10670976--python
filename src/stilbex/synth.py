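"""Seeded generators for every input the pipeline consumes.

Real sigma profiles come from quantum-chemical continuum-solvation
calculations; those are out of scope here, so profiles are emulated as
sums of Gaussian bumps on the canonical 51-bin lattice.  A stilbenoid-like
solute carries a broad apolar bump between +-0.01 e/A^2 plus
hydrogen-bonding wings near -0.017 (phenolic OH donors) and +0.012
(acceptor oxygens); the dimer analogue has the same shape scaled to a
larger cavity surface.  Solvent families span apolar to polar character so
polarity-driven trends (activity coefficients, partition ratios, water
dilution) are testable on known ground truth.

Chromatograms use the plate model: a solute of partition ratio K_D elutes
as a Gaussian centered at its retention volume with standard deviation
V_R / sqrt(N) for N theoretical plates.  Extraction studies emulate a
content that falls linearly with predicted ln gamma plus replicate noise.

All generators are pure functions of (spec, seed): randomness comes from a
``numpy.random.default_rng(seed)`` created per call — no global state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .ccc import CoilSystem, CCCPeak, plan_fractions, retention_volume
from .sigma import SIGMA_GRID, SigmaProfile

__all__ = [
    "ProfileSpec",
    "StudySpec",
    "make_profile",
    "make_solvent_family",
    "stilbenoid_like_profile",
    "simulate_chromatogram",
    "simulate_extraction_study",
]


@dataclass(frozen=True)
class ProfileSpec:
    """Gaussian-bump recipe for a synthetic sigma profile.

    Each bump is (center e/A^2, width e/A^2, area A^2); the discretised
    profile is renormalised so each bump contributes its area exactly.
    """

    name: str
    bumps: Tuple[Tuple[float, float, float], ...]
    total_volume: Optional[float] = None  # A^3; sphere-equivalent if None

    def __post_init__(self):
        if not self.bumps:
            raise ValueError("at least one bump required")
        for c, w, a in self.bumps:
            if w <= 0:
                raise ValueError("bump width must be positive")
            if a <= 0:
                raise ValueError("bump area must be positive")

    @property
    def total_area(self) -> float:
        return sum(a for _, _, a in self.bumps)


@dataclass(frozen=True)
class StudySpec:
    """Design of a synthetic extraction study: content = a - b*ln_gamma."""

    n_systems: int
    intercept: float  # a, mg/g DW
    slope: float  # b, mg/g DW per ln-gamma unit
    noise_sd: float = 0.1  # mg/g DW
    replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_systems < 1:
            raise ValueError("need at least one system")
        if self.noise_sd < 0:
            raise ValueError("noise_sd cannot be negative")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


def make_profile(spec: ProfileSpec) -> SigmaProfile:
    """Discretise a bump recipe onto the canonical grid (deterministic)."""
    lo, hi = SIGMA_GRID[0], SIGMA_GRID[-1]
    p = np.zeros_like(SIGMA_GRID)
    hb = np.zeros_like(SIGMA_GRID)
    for center, width, area in spec.bumps:
        if not lo <= center <= hi:
            raise ValueError(
                f"{spec.name}: bump center {center} outside grid [{lo}, {hi}]"
            )
        w = np.exp(-0.5 * ((SIGMA_GRID - center) / width) ** 2)
        bump = area * w / w.sum()  # per-bump area exact after renormalisation
        p += bump
        if abs(center) > 0.0084:
            hb += bump
    area_total = spec.total_area
    volume = (
        spec.total_volume
        if spec.total_volume is not None
        # sphere of equal surface: V = A^{3/2} / (6 sqrt(pi))
        else float(area_total**1.5 / (6.0 * np.sqrt(np.pi)))
    )
    return SigmaProfile(
        name=spec.name,
        area=float(p.sum()),
        volume=volume,
        p=p,
        p_hb=hb,
    )


def stilbenoid_like_profile(
    name: str = "stilbenoid", scale: float = 1.0
) -> SigmaProfile:
    """Apolar bulk with hb wings at -0.017 / +0.012 e/A^2.

    ``scale`` > 1 yields a larger-area analogue of the same shape (a dimer
    has more cavity surface than its monomer), keeping polarity fractions
    fixed so size and polarity effects can be separated in tests.
    """
    return make_profile(
        ProfileSpec(
            name=name,
            bumps=(
                (0.0, 0.005, 195.0 * scale),
                (-0.017, 0.0025, 22.0 * scale),
                (0.012, 0.003, 26.0 * scale),
            ),
        )
    )


def make_solvent_family(
    n: int, seed: int = 0, total_area: float = 150.0
) -> List[SigmaProfile]:
    """Synthetic solvents spanning apolar -> polar character.

    The polar surface fraction increases strictly across the family (from
    0 to 0.6); the seed only jitters bump widths, so ordering is
    reproducible and monotone by construction.
    """
    if n < 2:
        raise ValueError("a family needs at least 2 members")
    rng = np.random.default_rng(seed)
    fractions = np.linspace(0.0, 0.6, n)
    family = []
    for i, f in enumerate(fractions):
        w_apolar = 0.004 + 0.002 * rng.random()
        w_polar = 0.002 + 0.001 * rng.random()
        bumps = [(0.0, w_apolar, total_area * (1.0 - f))]
        if f > 0:
            bumps.append((-0.016, w_polar, total_area * f / 2.0))
            bumps.append((0.016, w_polar, total_area * f / 2.0))
        family.append(
            make_profile(ProfileSpec(name=f"synsolv_{i:02d}", bumps=tuple(bumps)))
        )
    return family


def simulate_chromatogram(
    peaks: Sequence[Tuple[float, float]],
    coil: CoilSystem,
    S_F_pct: float,
    plates: float = 1000.0,
    total_minutes: Optional[float] = None,
    fraction_minutes: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    points_per_ml: int = 10,
) -> dict:
    """Plate-model chromatogram from (K_D, mass mg) ground-truth peaks.

    Returns a dict with the trace (volume mL, signal mg/mL), the fraction
    plan with integrated per-fraction masses (exact Gaussian integrals, so
    mass is conserved up to truncation at the run end), and the simulated
    :class:`~stilbex.ccc.CCCPeak` list carrying widths ``4 sigma`` with
    ``sigma = V_R / sqrt(N)``.
    """
    if plates <= 0:
        raise ValueError("plate count must be positive")
    from scipy.stats import norm

    rng = np.random.default_rng(seed)
    peak_objs = []
    for i, (kd, mass) in enumerate(peaks):
        v_r = retention_volume(kd, S_F_pct, coil.V_C, coil.V_ext)
        sigma = v_r / np.sqrt(plates)
        peak_objs.append(
            (CCCPeak(solute=f"peak_{i + 1}", V_R=v_r, K_D=kd,
                     R_t=v_r / coil.flow, width=4.0 * sigma), mass, sigma)
        )
    if total_minutes is None:
        last = max(p.V_R + 2.0 * p.width for p, _, _ in peak_objs)
        total_minutes = float(np.ceil(last / coil.flow / fraction_minutes)) * (
            fraction_minutes
        )
    plan = plan_fractions(coil.flow, fraction_minutes, total_minutes)
    total_volume = coil.flow * total_minutes

    v = np.linspace(0.0, total_volume, int(total_volume * points_per_ml) + 1)
    signal = np.zeros_like(v)
    for p, mass, sigma in peak_objs:
        signal += mass * norm.pdf(v, loc=p.V_R, scale=sigma)
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=signal.size)

    fraction_masses = []
    for idx, start, end in plan:
        m = sum(
            mass * (norm.cdf(end, p.V_R, sigma) - norm.cdf(start, p.V_R, sigma))
            for p, mass, sigma in peak_objs
        )
        fraction_masses.append({"fraction": idx, "v_start": start, "v_end": end,
                                "mass_mg": float(m)})

    # annotate the fraction span containing the central 4-sigma window
    peaks_out = []
    for p, mass, sigma in peak_objs:
        lo = next((i for i, s, e in plan if s <= max(p.V_R - 2 * sigma, 0.0) < e), 1)
        hi = next((i for i, s, e in plan if s <= min(p.V_R + 2 * sigma,
                                                     total_volume - 1e-9) < e),
                  plan[-1][0])
        peaks_out.append(
            CCCPeak(solute=p.solute, V_R=p.V_R, K_D=p.K_D, R_t=p.R_t,
                    width=p.width, fraction_span=(lo, hi))
        )
    return {
        "trace": pd.DataFrame({"volume_ml": v, "signal": signal}),
        "fractions": pd.DataFrame(fraction_masses),
        "peaks": peaks_out,
        "plan": plan,
    }


def simulate_extraction_study(
    spec: StudySpec,
    lngamma_by_spec: Mapping[str, float],
) -> pd.DataFrame:
    """Replicate extraction contents from planted linear dependence.

    content_ij = a - b * ln_gamma_i + eps_ij with eps ~ N(0, noise_sd^2).
    Negative draws are clipped to 0 with a warning (contents are masses).
    """
    keys = sorted(lngamma_by_spec)[: spec.n_systems]
    if len(keys) < spec.n_systems:
        raise ValueError(
            f"only {len(keys)} ln_gamma values for {spec.n_systems} systems"
        )
    rng = np.random.default_rng(spec.seed)
    rows = []
    clipped = 0
    for key in keys:
        lng = lngamma_by_spec[key]
        mean = spec.intercept - spec.slope * lng
        for rep in range(1, spec.replicates + 1):
            c = mean + rng.normal(0.0, spec.noise_sd)
            if c < 0:
                clipped += 1
                c = 0.0
            rows.append(
                {"spec": key, "ln_gamma": lng, "replicate": rep, "content": c}
            )
    if clipped:
        warnings.warn(f"{clipped} negative contents clipped to 0", stacklevel=2)
    return pd.DataFrame(rows)
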