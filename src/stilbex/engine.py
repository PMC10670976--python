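"""Segment-activity-coefficient engine on sigma profiles.

The engine implements the single-reference COSMO-SAC formulation of the
Lin--Sandler family: a molecule's interactions with a liquid are reduced to
pairwise contacts of surface segments characterised only by their screening
charge density sigma.  The activity coefficient splits into

* a **residual** part from the self-consistent segment activity
  coefficients ``Gamma(sigma)`` of the mixture versus the pure liquid, and
* a **combinatorial** (Staverman--Guggenheim) part from molecular size and
  shape.

The exchange energy between two segments is

    dW(s_m, s_n) = (alpha'/2) (s_m + s_n)^2
                   + c_hb * max(0, s_acc - s_hb) * min(0, s_don + s_hb)

with ``s_acc = max(s_m, s_n)`` and ``s_don = min(s_m, s_n)``: the misfit
term penalises contacts of like-signed charge, the hydrogen-bond term
rewards donor/acceptor contacts beyond the cutoff ``s_hb``.  The segment
activity coefficients satisfy the fixed point

    ln Gamma(s_m) = -ln sum_n p(s_n) Gamma(s_n) exp(-dW(s_m, s_n) / RT)

solved by damped successive substitution with a Newton polish (see
:func:`segment_gamma`).

Default constants are the widely used open COSMO-SAC set (a_eff = 7.5 A^2,
alpha' = 16466.72 kcal A^4 mol^-1 e^-2, c_hb = 85580 kcal A^4 mol^-1 e^-2,
s_hb = 0.0084 e/A^2, z = 10, r_norm = 66.69 A^3, q_norm = 79.53 A^2).
These are *not* a reparameterisation of any proprietary solver: absolute
agreement with numbers produced by commercial COSMO-RS implementations is
neither expected nor targeted — the workflow built on top consumes values
and trends of gamma, which this model provides from the same inputs.

Infinite dilution is evaluated exactly at x_solute = 0: the solute does not
perturb the solvent ensemble, so no small-x extrapolation (and no attendant
tolerance) enters the downstream screens.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np

from .sigma import ComponentRecord, SIGMA_GRID

__all__ = [
    "R_KCAL",
    "EngineParams",
    "MixtureState",
    "ActivityResult",
    "ConvergenceError",
    "exchange_energy",
    "mixture_profile",
    "segment_gamma",
    "ln_gamma",
    "ln_gamma_all",
    "ln_gamma_infinite_dilution",
]

#: gas constant, kcal/(mol K) — the unit system of the segment constants
R_KCAL = 1.987204259e-3
#: gas constant, J/(mol K) — for excess chemical potentials
R_J = 8.31446261815324


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, residual: float):
        self.residual = residual
        super().__init__(f"{message} (residual {residual:.3e})")


@dataclass(frozen=True)
class EngineParams:
    """Engine constants. All energies kcal-based; lengths in Angstrom."""

    alpha_prime: float = 16466.72  # misfit constant, kcal A^4 / (mol e^2)
    c_hb: float = 85580.0  # hb constant, same units
    sigma_hb: float = 0.0084  # hb cutoff, e/A^2
    a_eff: float = 7.5  # effective segment area, A^2
    z: float = 10.0  # coordination number
    r_norm: float = 66.69  # volume normalisation, A^3
    q_norm: float = 79.53  # area normalisation, A^2
    hb_enabled: bool = True
    damping: float = 0.5  # successive-substitution damping
    max_iter: int = 500
    tol: float = 1e-10

    def __post_init__(self):
        for name in ("alpha_prime", "c_hb", "sigma_hb", "a_eff", "z", "r_norm", "q_norm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.damping <= 1:
            raise ValueError("damping must be in (0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EngineParams":
        return cls(**d)


@dataclass(frozen=True)
class MixtureState:
    """A liquid: components, mole fractions and temperature (K)."""

    components: tuple
    x: np.ndarray
    T: float

    def __init__(self, components: Sequence[ComponentRecord], x, T: float):
        object.__setattr__(self, "components", tuple(components))
        xa = np.asarray(x, dtype=float)
        if xa.shape != (len(self.components),):
            raise ValueError("x length must match number of components")
        if np.any(xa < 0):
            raise ValueError("mole fractions must be non-negative")
        if abs(xa.sum() - 1.0) > 1e-12:
            raise ValueError(f"mole fractions sum to {xa.sum()!r}, not 1")
        if T <= 0:
            raise ValueError("temperature must be positive (K)")
        xa.setflags(write=False)
        object.__setattr__(self, "x", xa)
        object.__setattr__(self, "T", float(T))


@dataclass(frozen=True)
class ActivityResult:
    """ln gamma decomposition for every component of a state."""

    ln_gamma: np.ndarray
    ln_gamma_comb: np.ndarray
    ln_gamma_res: np.ndarray
    mu_excess: np.ndarray  # RT ln gamma, J/mol

    def __post_init__(self):
        if not np.allclose(
            self.ln_gamma, self.ln_gamma_comb + self.ln_gamma_res, atol=1e-10
        ):
            raise ValueError("ln_gamma must equal comb + res")


def exchange_energy(
    grid: np.ndarray, params: EngineParams
) -> np.ndarray:
    """Symmetric segment exchange-energy matrix dW (kcal/mol) on `grid`."""
    s = np.asarray(grid, dtype=float)
    sm = s[:, None]
    sn = s[None, :]
    dw = 0.5 * params.alpha_prime * (sm + sn) ** 2
    if params.hb_enabled:
        s_acc = np.maximum(sm, sn)
        s_don = np.minimum(sm, sn)
        dw = dw + params.c_hb * np.maximum(0.0, s_acc - params.sigma_hb) * np.minimum(
            0.0, s_don + params.sigma_hb
        )
    return dw


def mixture_profile(state: MixtureState) -> np.ndarray:
    """Area-normalised sigma distribution of a liquid.

    p_S(sigma) = sum_i x_i p_i(sigma) / sum_i x_i A_i, so sum_sigma p_S = 1.
    """
    profs = [c.require_profile() for c in state.components]
    areas = np.array([pr.area for pr in profs])
    total_area = float(state.x @ areas)
    if total_area <= 0:
        raise ValueError("mixture has zero total surface area")
    p = np.zeros_like(SIGMA_GRID)
    for xi, pr in zip(state.x, profs):
        if xi > 0:
            p = p + xi * pr.p
    return p / total_area


def segment_gamma(
    p_S: np.ndarray,
    T: float,
    params: EngineParams = EngineParams(),
    grid: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Solve the segment self-consistency for ``Gamma(sigma)``.

    `p_S` may be 1-D (one liquid) or 2-D ``(n_liquids, n_bins)`` — batches
    share the exchange-energy matrix and iterate together.  Converged to
    ``max |delta ln Gamma| < tol``; raises :class:`ConvergenceError`
    carrying the residual otherwise.

    Damped successive substitution alone contracts linearly with a factor
    close to 1 for strongly hydrogen-bonding liquids, so it is used only
    as a warm start; a Newton iteration on ``F(ln Gamma) = ln Gamma +
    ln sum_n p_n Gamma_n exp(-dW/RT) = 0`` (dense 51x51 Jacobian, batched)
    then converges quadratically to the fixed point.
    """
    g = SIGMA_GRID if grid is None else np.asarray(grid, dtype=float)
    p = np.atleast_2d(np.asarray(p_S, dtype=float))
    if p.shape[-1] != g.size:
        raise ValueError("profile/grid size mismatch")
    sums = p.sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=1e-10):
        raise ValueError("p_S must be normalised to 1")
    W = np.exp(-exchange_energy(g, params) / (R_KCAL * T))  # (m, n)
    ln_G = np.zeros_like(p)
    d = params.damping
    residual = np.inf
    n_warm = min(50, params.max_iter)
    for _ in range(n_warm):
        # denominator_m = sum_n p_n Gamma_n W_{m,n}
        ln_new = -np.log((p * np.exp(ln_G)) @ W.T)
        residual = float(np.max(np.abs(ln_new - ln_G)))
        ln_G = (1 - d) * ln_G + d * ln_new
        if residual < params.tol:
            break
    if residual >= params.tol:
        eye = np.eye(g.size)
        for _ in range(params.max_iter - n_warm):
            pe = p * np.exp(ln_G)  # (k, n)
            denom = pe @ W.T  # (k, m)
            F = ln_G + np.log(denom)
            residual = float(np.max(np.abs(F)))
            if residual < params.tol:
                break
            J = eye + pe[:, None, :] * W[None, :, :] / denom[:, :, None]
            step = np.linalg.solve(J, -F[..., None])[..., 0]
            # cap the Newton step so the warm start cannot be overshot
            step = np.clip(step, -2.0, 2.0)
            ln_G = ln_G + step
        else:
            raise ConvergenceError("segment fixed point did not converge", residual)
    out = np.exp(ln_G)
    return out[0] if np.ndim(p_S) == 1 else out


def _sg_combinatorial(state: MixtureState, params: EngineParams) -> np.ndarray:
    """Staverman–Guggenheim term, written in x->0-safe ratio form."""
    profs = [c.require_profile() for c in state.components]
    r = np.array([pr.volume for pr in profs]) / params.r_norm
    q = np.array([pr.area for pr in profs]) / params.q_norm
    if np.any(r <= 0) or np.any(q <= 0):
        raise ValueError("components need positive cavity volume and area")
    l = 0.5 * params.z * (r - q) - (r - 1.0)
    xr = float(state.x @ r)
    xq = float(state.x @ q)
    xl = float(state.x @ l)
    phi_over_x = r / xr
    theta_over_phi = (q / r) * (xr / xq)
    return (
        np.log(phi_over_x)
        + 0.5 * params.z * q * np.log(theta_over_phi)
        + l
        - phi_over_x * xl
    )


def ln_gamma_all(
    state: MixtureState, params: EngineParams = EngineParams()
) -> ActivityResult:
    """Activity coefficients of every component of `state`.

    Components at x = 0 are legal: they see the ensemble of the others
    (this is exactly the infinite-dilution limit).
    """
    profs = [c.require_profile() for c in state.components]
    p_S = mixture_profile(state)
    pure = np.stack([pr.normalized for pr in profs])
    ln_G_all = np.log(segment_gamma(np.vstack([p_S, pure]), state.T, params))
    ln_G_mix, ln_G_pure = ln_G_all[0], ln_G_all[1:]
    res = np.array(
        [
            (pr.area / params.a_eff)
            * float(pr.normalized @ (ln_G_mix - ln_G_pure[i]))
            for i, pr in enumerate(profs)
        ]
    )
    comb = _sg_combinatorial(state, params)
    total = comb + res
    return ActivityResult(
        ln_gamma=total,
        ln_gamma_comb=comb,
        ln_gamma_res=res,
        mu_excess=R_J * state.T * total,
    )


def ln_gamma(
    component_index: int,
    state: MixtureState,
    params: EngineParams = EngineParams(),
) -> float:
    """ln gamma of one component in `state`."""
    return float(ln_gamma_all(state, params).ln_gamma[component_index])


def ln_gamma_infinite_dilution(
    solute: ComponentRecord,
    solvent: MixtureState,
    params: EngineParams = EngineParams(),
) -> float:
    """ln gamma of `solute` infinitely diluted in `solvent`.

    Evaluated analytically at x_solute = 0: the solvent ensemble is
    unperturbed, so the result is exact rather than an extrapolation.
    """
    comps = list(solvent.components) + [solute]
    x = np.append(solvent.x, 0.0)
    state = MixtureState(comps, x, solvent.T)
    return ln_gamma(len(comps) - 1, state, params)
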