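"""Biphasic liquid–liquid equilibrium for multicomponent solvent recipes.

Given an overall composition ``z`` (derived from the volumetric parts a
bench chemist would pour, e.g. n-hexane/ethyl acetate/methanol/water
1.0/2.0/1.0/2.0), the flash finds two liquid phases in isoactivity
equilibrium, ``x_u gamma_u = x_l gamma_l`` for every component, using
successive substitution on the distribution coefficients ``K_i =
gamma_l,i / gamma_u,i`` wrapped around a Rachford–Rice solve for the phase
fraction.  Two initial guesses are tried — one rich in the most apolar
component, one rich in the most polar — and the split with the lower total
Gibbs energy is kept.

Phase naming follows CCC practice: the phase with the lower mass density is
the "upper" (organic, typically stationary) phase.  Mixing volumes are
ideal (``v = sum x_i v_i``); no excess-volume model is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .engine import EngineParams, MixtureState, ln_gamma_all
from .sigma import ComponentRecord

__all__ = [
    "SolventRecipe",
    "PhaseSplit",
    "NoPhaseSplitError",
    "FlashConvergenceError",
    "recipe_to_overall_moles",
    "phase_molar_volume",
    "phase_mass_density",
    "lle_flash",
]

ISOACTIVITY_TOL = 1e-8
TRIVIAL_TOL = 1e-6


class NoPhaseSplitError(RuntimeError):
    """The composition is single-phase (flash converged to x_u == x_l)."""


class FlashConvergenceError(RuntimeError):
    def __init__(self, message: str, residual: float):
        self.residual = residual
        super().__init__(f"{message} (residual {residual:.3e})")


@dataclass(frozen=True)
class SolventRecipe:
    """Volumetric recipe for a biphasic solvent system."""

    components: tuple
    volume_parts: tuple
    T_lle: float = 20.0  # deg C

    def __init__(self, components: Sequence[ComponentRecord], volume_parts, T_lle=20.0):
        comps = tuple(components)
        parts = tuple(float(p) for p in volume_parts)
        if len(comps) < 2:
            raise ValueError("a biphasic recipe needs at least 2 components")
        if len(parts) != len(comps):
            raise ValueError("one volume part per component required")
        if any(p <= 0 for p in parts):
            raise ValueError("volume parts must be positive")
        object.__setattr__(self, "components", comps)
        object.__setattr__(self, "volume_parts", parts)
        object.__setattr__(self, "T_lle", float(T_lle))


@dataclass(frozen=True)
class PhaseSplit:
    """Converged two-phase split (upper = lower mass density)."""

    components: tuple
    x_upper: np.ndarray
    x_lower: np.ndarray
    beta: float  # mole fraction of material in the upper phase
    v_upper: float  # cm^3/mol
    v_lower: float  # cm^3/mol
    isoactivity_residual: float
    T: float  # K at which equilibrium was solved

    def __post_init__(self):
        for name in ("x_upper", "x_lower"):
            x = np.asarray(getattr(self, name), dtype=float)
            x.setflags(write=False)
            object.__setattr__(self, name, x)
            if abs(x.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if not 0 < self.beta < 1:
            raise ValueError("beta must lie strictly between 0 and 1")
        if self.isoactivity_residual > ISOACTIVITY_TOL:
            raise ValueError(
                f"isoactivity residual {self.isoactivity_residual:.2e} above "
                f"{ISOACTIVITY_TOL:.0e}"
            )

    @property
    def overall(self) -> np.ndarray:
        return self.beta * self.x_upper + (1 - self.beta) * self.x_lower

    def swapped(self) -> "PhaseSplit":
        """Same equilibrium with the phase labels exchanged."""
        return PhaseSplit(
            components=self.components,
            x_upper=self.x_lower,
            x_lower=self.x_upper,
            beta=1 - self.beta,
            v_upper=self.v_lower,
            v_lower=self.v_upper,
            isoactivity_residual=self.isoactivity_residual,
            T=self.T,
        )


def recipe_to_overall_moles(recipe: SolventRecipe) -> np.ndarray:
    """Convert volumetric parts to overall mole fractions.

    z_i is proportional to parts_i * density_i / molar_mass_i; every
    component must carry a density and molar mass in its registry record.
    """
    z = np.empty(len(recipe.components))
    for i, (comp, part) in enumerate(zip(recipe.components, recipe.volume_parts)):
        if comp.density is None:
            raise ValueError(f"{comp.name}: density required to convert volume parts")
        z[i] = part * comp.density / comp.molar_mass
    return z / z.sum()


def phase_molar_volume(x, components: Sequence[ComponentRecord]) -> float:
    """Ideal-mixing molar volume, cm^3/mol."""
    x = np.asarray(x, dtype=float)
    v = np.array([c.liquid_molar_volume for c in components])
    return float(x @ v)


def phase_mass_density(x, components: Sequence[ComponentRecord]) -> float:
    """Ideal-mixing mass density, g/cm^3."""
    x = np.asarray(x, dtype=float)
    m = np.array([c.molar_mass for c in components])
    return float((x @ m) / phase_molar_volume(x, components))


def _gibbs_mix(x: np.ndarray, lng: np.ndarray) -> float:
    """Dimensionless molar Gibbs energy of mixing, x ln(x gamma)."""
    mask = x > 0
    return float(np.sum(x[mask] * (np.log(x[mask]) + lng[mask])))


def _rachford_rice(z: np.ndarray, K: np.ndarray) -> float:
    """Phase fraction beta in (0,1) solving sum z(K-1)/(1+beta(K-1)) = 0."""
    dm = K - 1.0
    def f(beta):
        return float(np.sum(z * dm / (1.0 + beta * dm)))
    lo = max(0.0, *(1.0 / (1.0 - k) for k in K if k > 1.0)) if np.any(K > 1) else None
    hi = min(1.0, *(1.0 / (1.0 - k) for k in K if k < 1.0)) if np.any(K < 1) else None
    if lo is None or hi is None:
        raise NoPhaseSplitError("all K on one side of unity: single phase")
    eps = 1e-12
    a, b = lo + eps, hi - eps
    if a >= b or f(a) * f(b) > 0:
        raise NoPhaseSplitError("Rachford–Rice has no root in (0, 1)")
    return brentq(f, a, b, xtol=1e-14)


def _seed_K(
    z: np.ndarray,
    components: Sequence[ComponentRecord],
    key: int,
) -> np.ndarray:
    """Initial K from a trial phase heavily enriched in component `key`."""
    n = z.size
    x_rich = np.full(n, 0.05 / (n - 1))
    x_rich[key] = 0.95
    x_dep = z.copy()
    x_dep[key] *= 0.05
    x_dep /= x_dep.sum()
    return x_rich / x_dep


def lle_flash(
    z,
    T: float,
    components: Sequence[ComponentRecord],
    params: EngineParams = EngineParams(),
    max_iter: int = 400,
    damping: float = 0.5,
) -> PhaseSplit:
    """Two-phase isoactivity flash at temperature `T` (K).

    Raises :class:`NoPhaseSplitError` if the mixture is single-phase and
    :class:`FlashConvergenceError` if iteration stalls above tolerance.
    """
    z = np.asarray(z, dtype=float)
    z = z / z.sum()
    comps = list(components)
    polar = np.array([c.require_profile().polar_fraction() for c in comps])
    seeds = [int(np.argmin(polar)), int(np.argmax(polar))]
    if seeds[0] == seeds[1]:
        seeds = seeds[:1]

    best = None
    best_g = np.inf
    failure: Exception = NoPhaseSplitError("no stable two-phase solution found")
    for key in seeds:
        try:
            split, g = _flash_from_K(_seed_K(z, comps, key), z, T, comps, params,
                                      max_iter, damping)
        except (NoPhaseSplitError, FlashConvergenceError) as exc:
            failure = exc
            continue
        if g < best_g:
            best, best_g = split, g
    if best is None:
        raise failure

    # a returned split must lower Gibbs energy versus the single phase
    g_single = _gibbs_mix(z, ln_gamma_all(MixtureState(comps, z, T), params).ln_gamma)
    if best_g >= g_single - 1e-12:
        raise NoPhaseSplitError("split does not lower Gibbs energy: single phase")
    return best


def _flash_from_K(K, z, T, comps, params, max_iter, damping):
    K = np.asarray(K, dtype=float)
    resid = np.inf
    x_a = x_b = None
    for _ in range(max_iter):
        beta = _rachford_rice(z, K)
        x_b = z / (1.0 + beta * (K - 1.0))  # K-lean phase
        x_a = K * x_b  # K-rich phase
        x_a = x_a / x_a.sum()
        x_b = x_b / x_b.sum()
        lng_a = ln_gamma_all(MixtureState(comps, x_a, T), params).ln_gamma
        lng_b = ln_gamma_all(MixtureState(comps, x_b, T), params).ln_gamma
        resid = float(np.max(np.abs(x_a * np.exp(lng_a) - x_b * np.exp(lng_b))))
        K_new = np.exp(lng_b - lng_a)
        if resid < ISOACTIVITY_TOL:
            K = K_new
            break
        K = np.exp((1 - damping) * np.log(K) + damping * np.log(K_new))
    else:
        raise FlashConvergenceError("flash did not converge", resid)

    if float(np.max(np.abs(x_a - x_b))) < TRIVIAL_TOL:
        raise NoPhaseSplitError("flash converged to identical phases")

    g = beta * _gibbs_mix(x_a, lng_a) + (1 - beta) * _gibbs_mix(x_b, lng_b)

    # label by ideal-mixing mass density: lighter phase on top
    rho_a = phase_mass_density(x_a, comps)
    rho_b = phase_mass_density(x_b, comps)
    if rho_a <= rho_b:
        x_u, x_l, beta_u = x_a, x_b, beta
    else:
        x_u, x_l, beta_u = x_b, x_a, 1.0 - beta
    split = PhaseSplit(
        components=tuple(comps),
        x_upper=x_u,
        x_lower=x_l,
        beta=beta_u,
        v_upper=phase_molar_volume(x_u, comps),
        v_lower=phase_molar_volume(x_l, comps),
        isoactivity_residual=resid,
        T=T,
    )
    return split, g
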