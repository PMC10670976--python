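"""Activity-coefficient engine: mixing rules, segment fixed point, limits.

The dense oracle used here re-implements the segment self-consistency and
the size/shape term with plain Python loops, independently of the engine's
vectorised Newton solver, so agreement is a genuine cross-check.
"""

import math

import numpy as np
import pytest

from stilbex.engine import (
    EngineParams,
    MixtureState,
    R_KCAL,
    exchange_energy,
    ln_gamma,
    ln_gamma_all,
    ln_gamma_infinite_dilution,
    mixture_profile,
    segment_gamma,
)
from stilbex.sigma import SIGMA_GRID
from stilbex.synth import make_solvent_family, stilbenoid_like_profile
from tests.conftest import synth_component


# --- independent oracle -----------------------------------------------------


def oracle_delta_w(sm, sn, prm):
    """Exchange energy, scalar arithmetic only."""
    dw = 0.5 * prm.alpha_prime * (sm + sn) ** 2
    if prm.hb_enabled:
        s_acc, s_don = max(sm, sn), min(sm, sn)
        dw += prm.c_hb * max(0.0, s_acc - prm.sigma_hb) * min(0.0, s_don + prm.sigma_hb)
    return dw


def oracle_segment_gamma(grid, p, T, prm, tol=1e-12, iters=100000):
    """Undamped scalar fixed-point iteration, loop-per-bin."""
    n = len(grid)
    gamma = [1.0] * n
    for _ in range(iters):
        new = []
        for m in range(n):
            s = 0.0
            for k in range(n):
                s += p[k] * gamma[k] * math.exp(
                    -oracle_delta_w(grid[m], grid[k], prm) / (R_KCAL * T)
                )
            new.append(1.0 / s)
        # geometric half-step for stability, still independent arithmetic
        nxt = [math.sqrt(a * b) for a, b in zip(gamma, new)]
        if max(abs(math.log(a) - math.log(b)) for a, b in zip(gamma, nxt)) < tol:
            return nxt
        gamma = nxt
    raise RuntimeError("oracle did not converge")


def oracle_ln_gamma_binary(comps, x, T, prm):
    """Direct evaluation of residual + Staverman-Guggenheim, scalar math."""
    profs = [c.sigma_profile for c in comps]
    grid = list(SIGMA_GRID)
    areas = [pr.area for pr in profs]
    total_area = sum(xi * a for xi, a in zip(x, areas))
    p_mix = [
        sum(x[i] * profs[i].p[k] for i in range(len(comps))) / total_area
        for k in range(51)
    ]
    gam_mix = oracle_segment_gamma(grid, p_mix, T, prm)
    out = []
    r = [pr.volume / prm.r_norm for pr in profs]
    q = [pr.area / prm.q_norm for pr in profs]
    l = [0.5 * prm.z * (ri - qi) - (ri - 1.0) for ri, qi in zip(r, q)]
    xr = sum(xi * ri for xi, ri in zip(x, r))
    xq = sum(xi * qi for xi, qi in zip(x, q))
    xl = sum(xi * li for xi, li in zip(x, l))
    for i, pr in enumerate(profs):
        p_i = [pr.p[k] / pr.area for k in range(51)]
        gam_i = oracle_segment_gamma(grid, p_i, T, prm)
        res = (pr.area / prm.a_eff) * sum(
            p_i[k] * (math.log(gam_mix[k]) - math.log(gam_i[k]))
            for k in range(51)
            if p_i[k] > 0
        )
        comb = (
            math.log(r[i] / xr)
            + 0.5 * prm.z * q[i] * math.log((q[i] / r[i]) * (xr / xq))
            + l[i]
            - (r[i] / xr) * xl
        )
        out.append(comb + res)
    return out


# --- mixing rule ------------------------------------------------------------


class TestMixtureProfile:
    def test_single_component_is_its_normalized_profile(self):
        c = synth_component("c", [(0.0, 0.005, 150.0)])
        st = MixtureState([c], [1.0], 298.15)
        np.testing.assert_allclose(
            mixture_profile(st), c.sigma_profile.normalized, atol=1e-14
        )

    def test_two_identical_components_match_single(self):
        c = synth_component("c", [(0.0, 0.005, 150.0)])
        st2 = MixtureState([c, c], [0.3, 0.7], 298.15)
        np.testing.assert_allclose(
            mixture_profile(st2), c.sigma_profile.normalized, atol=1e-14
        )

    def test_single_bin_mass_balance(self):
        # 50/50 mix of single-bin profiles with areas 100 and 300:
        # total area 200 -> bin weights 0.25 and 0.75
        from stilbex.sigma import ComponentRecord, SigmaProfile

        def spike(idx, area, name):
            p = np.zeros(51)
            p[idx] = area
            return ComponentRecord(
                name, 100.0, 100.0,
                sigma_profile=SigmaProfile(name, area, 50.0, p),
            )

        a = spike(20, 100.0, "a")
        b = spike(30, 300.0, "b")
        p_S = mixture_profile(MixtureState([a, b], [0.5, 0.5], 298.15))
        assert p_S[20] == pytest.approx(0.25)
        assert p_S[30] == pytest.approx(0.75)
        assert p_S.sum() == pytest.approx(1.0, abs=1e-10)


# --- segment fixed point ----------------------------------------------------


class TestSegmentGamma:
    def test_neutral_spike_has_unit_gamma_where_populated(self, params):
        p = np.zeros(51)
        p[25] = 1.0  # all surface at sigma = 0, dW(0,0) = 0
        gamma = segment_gamma(p, 298.15, params)
        assert gamma[25] == pytest.approx(1.0, abs=1e-9)

    def test_fixed_point_self_consistent(self, params):
        prof = stilbenoid_like_profile("fp")
        p = prof.normalized
        gamma = segment_gamma(p, 298.15, params)
        W = np.exp(-exchange_energy(SIGMA_GRID, params) / (R_KCAL * 298.15))
        recomputed = 1.0 / ((p * gamma) @ W.T)
        np.testing.assert_allclose(recomputed, gamma, rtol=1e-8)

    def test_exchange_energy_symmetric(self, params):
        dw = exchange_energy(SIGMA_GRID, params)
        np.testing.assert_array_equal(dw, dw.T)

    @pytest.mark.parametrize("nbins", [3, 5])
    def test_matches_dense_scalar_oracle_on_toy_grids(self, nbins, params):
        grid = np.linspace(-0.012, 0.012, nbins)
        rng = np.random.default_rng(42 + nbins)
        p = rng.random(nbins)
        p /= p.sum()
        gamma = segment_gamma(p, 310.0, params, grid=grid)
        oracle = oracle_segment_gamma(list(grid), list(p), 310.0, params)
        np.testing.assert_allclose(gamma, oracle, rtol=1e-8)


# --- ln gamma ---------------------------------------------------------------


class TestLnGamma:
    def test_pure_component_reference_state(self, params):
        c = synth_component("pure", [(0.0, 0.005, 150.0), (0.014, 0.003, 30.0)])
        assert ln_gamma(0, MixtureState([c], [1.0], 298.15), params) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_ideal_mixture_of_identical_species(self, params):
        c = synth_component("twin", [(0.0, 0.005, 120.0), (-0.013, 0.003, 25.0)])
        for x in ([0.2, 0.8], [0.5, 0.5], [0.9, 0.1]):
            res = ln_gamma_all(MixtureState([c, c], x, 298.15), params)
            np.testing.assert_allclose(res.ln_gamma, 0.0, atol=1e-9)

    def test_decomposition_invariant(self, params):
        a = synth_component("a", [(0.0, 0.004, 180.0)], 120.0)
        b = synth_component("b", [(-0.012, 0.003, 40.0), (0.012, 0.003, 40.0)], 70.0)
        res = ln_gamma_all(MixtureState([a, b], [0.3, 0.7], 298.15), params)
        np.testing.assert_allclose(
            res.ln_gamma, res.ln_gamma_comb + res.ln_gamma_res, atol=1e-12
        )

    def test_matches_independent_direct_evaluation(self, params):
        a = synth_component("a", [(-0.004, 0.002, 120.0)], 110.0, 90.0)
        b = synth_component("b", [(0.006, 0.002, 60.0)], 60.0, 50.0)
        state = MixtureState([a, b], [0.3, 0.7], 298.15)
        got = ln_gamma_all(state, params).ln_gamma
        want = oracle_ln_gamma_binary([a, b], [0.3, 0.7], 298.15, params)
        np.testing.assert_allclose(got, want, rtol=1e-6, atol=1e-8)

    def test_reordering_components_permutes_results(self, params):
        a = synth_component("a", [(0.0, 0.004, 150.0)], 100.0)
        b = synth_component("b", [(0.01, 0.003, 80.0)], 80.0)
        fwd = ln_gamma_all(MixtureState([a, b], [0.4, 0.6], 298.15), params).ln_gamma
        rev = ln_gamma_all(MixtureState([b, a], [0.6, 0.4], 298.15), params).ln_gamma
        np.testing.assert_allclose(fwd, rev[::-1], atol=1e-10)

    def test_duplicating_component_with_split_fraction(self, params):
        a = synth_component("a", [(0.0, 0.004, 150.0)], 100.0)
        b = synth_component("b", [(0.01, 0.003, 80.0)], 80.0)
        base = ln_gamma_all(MixtureState([a, b], [0.4, 0.6], 298.15), params).ln_gamma
        split = ln_gamma_all(
            MixtureState([a, a, b], [0.15, 0.25, 0.6], 298.15), params
        ).ln_gamma
        assert split[0] == pytest.approx(split[1], abs=1e-10)
        np.testing.assert_allclose(split[[0, 2]], base, atol=1e-10)


class TestInfiniteDilution:
    def test_solute_identical_to_solvent_is_ideal(self, params):
        c = synth_component("same", [(0.0, 0.005, 130.0), (0.013, 0.003, 20.0)])
        solvent = MixtureState([c], [1.0], 298.15)
        assert ln_gamma_infinite_dilution(c, solvent, params) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_equals_small_x_limit(self, params):
        solute = synth_component("mild_oil", [(0.0, 0.004, 80.0)], 60.0)
        solv_c = synth_component(
            "mild_polar", [(-0.012, 0.003, 40.0), (0.012, 0.003, 40.0)], 55.0
        )
        solvent = MixtureState([solv_c], [1.0], 298.15)
        exact = ln_gamma_infinite_dilution(solute, solvent, params)
        for eps in (1e-6, 1e-8):
            st = MixtureState([solv_c, solute], [1 - eps, eps], 298.15)
            assert ln_gamma(1, st, params) == pytest.approx(exact, abs=1e-4)

    def test_hydrophobe_prefers_apolar_solvent(self, params, apolar_solvent,
                                               polar_solvent):
        hydrophobe = synth_component("oil", [(0.0, 0.004, 160.0)], 110.0)
        in_polar = ln_gamma_infinite_dilution(
            hydrophobe, MixtureState([polar_solvent], [1.0], 298.15), params
        )
        in_apolar = ln_gamma_infinite_dilution(
            hydrophobe, MixtureState([apolar_solvent], [1.0], 298.15), params
        )
        assert in_polar > in_apolar

    def test_monotone_across_polarity_family(self, params):
        family = make_solvent_family(6, seed=3)
        hydrophobe = synth_component("oil", [(0.0, 0.004, 160.0)], 110.0)
        values = []
        for prof in family:
            solv = synth_component(prof.name, [(0.0, 0.004, 1.0)], 90.0)
            solv = type(solv)(
                solv.name, solv.molar_mass, solv.liquid_molar_volume,
                sigma_profile=prof,
            )
            values.append(
                ln_gamma_infinite_dilution(
                    hydrophobe, MixtureState([solv], [1.0], 298.15), params
                )
            )
        assert all(b > a for a, b in zip(values, values[1:]))


class TestGibbsDuhem:
    def test_binary_consistency_random_states(self, params):
        rng = np.random.default_rng(7)
        a = synth_component("a", [(0.0, 0.004, 170.0), (0.011, 0.003, 30.0)], 115.0)
        b = synth_component(
            "b", [(-0.013, 0.003, 45.0), (0.013, 0.003, 45.0)], 75.0
        )
        h = 1e-4
        for _ in range(20):
            t = rng.uniform(0.05, 0.95)
            lg_hi = ln_gamma_all(
                MixtureState([a, b], [t + h, 1 - t - h], 298.15), params
            ).ln_gamma
            lg_lo = ln_gamma_all(
                MixtureState([a, b], [t - h, 1 - t + h], 298.15), params
            ).ln_gamma
            deriv = (lg_hi - lg_lo) / (2 * h)
            resid = t * deriv[0] + (1 - t) * deriv[1]
            assert abs(resid) < 1e-5
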