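"""NADES composition arithmetic, screening grid, ranking and correlation."""

import numpy as np
import pandas as pd
import pytest

from stilbex import datasets
from stilbex.nades import (
    NADESSpec,
    ScreeningGrid,
    correlate,
    heatmap_export,
    nades_composition,
    rank_specs,
    screen,
)
from stilbex.synth import StudySpec, simulate_extraction_study
from tests.conftest import synth_component


class TestComposition:
    def test_equimolar_anhydrous(self, registry):
        spec = NADESSpec(
            hba=registry["betaine"], hbd=registry["sorbitol"], ratio=(1, 1)
        )
        np.testing.assert_allclose(nades_composition(spec), [0.5, 0.5, 0.0])

    def test_one_to_five_anhydrous(self, registry):
        spec = NADESSpec(
            hba=registry["choline chloride"],
            hbd=registry["1,2-propanediol"],
            ratio=(1, 5),
            nonstandard_ratio=True,
        )
        np.testing.assert_allclose(
            nades_composition(spec), [1 / 6, 5 / 6, 0.0], atol=1e-15
        )

    def test_hydrated_glucose_urea_mass_balance(self, registry):
        # direct arithmetic oracle: 1 mol glucose + 1 mol urea, 60 wt% water
        spec = NADESSpec(
            hba=registry["glucose"], hbd=registry["urea"], ratio=(1, 1),
            water_wt_pct=60.0,
        )
        m_glu, m_urea = 180.16, 60.06
        dry = m_glu + m_urea
        m_water = 0.6 / 0.4 * dry
        n_water = m_water / 18.015
        want = np.array([1.0, 1.0, n_water])
        want /= want.sum()
        got = nades_composition(spec)
        np.testing.assert_allclose(got, want, atol=1e-12)
        # registry molar masses match the oracle's inputs
        assert registry["glucose"].molar_mass == m_glu
        assert registry["urea"].molar_mass == m_urea

    def test_uncanonical_ratio_requires_flag(self, registry):
        with pytest.raises(ValueError, match="canonical"):
            NADESSpec(
                hba=registry["glucose"], hbd=registry["urea"], ratio=(1, 5)
            )


class TestScreen:
    def test_pure_solute_pseudo_nades_is_ideal(self, registry, params):
        res = registry["trans-resveratrol"]
        spec = NADESSpec(hba=res, hbd=res, ratio=(1, 1))
        grid = screen([res], [spec], params=params)
        assert grid.entries["ln_gamma"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_small_lattice_complete_and_finite(self, registry, params):
        hbas = [registry["choline chloride"], registry["betaine"]]
        hbds = [registry["1,2-propanediol"], registry["urea"]]
        specs = [
            NADESSpec(hba=a, hbd=d, ratio=r, water_wt_pct=w)
            for a in hbas
            for d in hbds
            for r in ((1, 1), (1, 2))
            for w in (0.0, 30.0)
        ]
        grid = screen(
            [registry["trans-resveratrol"]], specs, params=params,
            water=registry["water"],
        )
        assert len(grid.entries) == 16
        assert np.isfinite(grid.entries["ln_gamma"]).all()

    def test_repeat_runs_identical(self, registry, params):
        specs = [
            NADESSpec(
                hba=registry["betaine"], hbd=registry["glycerol"], ratio=(1, 2)
            )
        ]
        g1 = screen([registry["trans-resveratrol"]], specs, params=params)
        g2 = screen([registry["trans-resveratrol"]], specs, params=params)
        pd.testing.assert_frame_equal(g1.entries, g2.entries)

    def test_water_dilution_raises_lngamma_of_hydrophobe(self, registry, params):
        hydrophobe = synth_component("oil", [(0.0, 0.004, 160.0)], 110.0)
        specs = [
            NADESSpec(
                hba=registry["choline chloride"],
                hbd=registry["1,2-propanediol"],
                ratio=(1, 2),
                water_wt_pct=w,
            )
            for w in (0, 10, 20, 30, 40, 50, 60, 70)
        ]
        grid = screen([hydrophobe], specs, params=params, water=registry["water"])
        values = grid.entries.sort_values("water_wt_pct")["ln_gamma"].to_numpy()
        assert all(b > a for a, b in zip(values, values[1:]))


class TestRanking:
    @staticmethod
    def grid_from(entries):
        rows = []
        for (hba, hbd, ratio, water, solute, lng) in entries:
            rows.append(
                {
                    "spec": f"{hba}/{hbd} {ratio} {water:g}wt%",
                    "hba": hba, "hbd": hbd, "ratio": ratio,
                    "water_wt_pct": water, "solute": solute,
                    "ln_gamma": lng, "T_C": 25.0, "error": "",
                }
            )
        return ScreeningGrid(entries=pd.DataFrame(rows))

    def test_lower_lngamma_ranks_first(self):
        grid = self.grid_from(
            [
                ("Ch", "Pdiol", "1/5", 0.0, "res", -8.42),
                ("B", "Bdiol", "1/1", 30.0, "res", -5.08),
            ]
        )
        ranked = rank_specs(grid, "res")
        assert ranked.iloc[0]["hbd"] == "Pdiol"
        assert ranked.iloc[0]["ln_gamma"] == -8.42

    def test_single_entry_ranks_itself(self):
        grid = self.grid_from([("Ch", "Gly", "1/1", 0.0, "res", -2.0)])
        assert len(rank_specs(grid, "res")) == 1

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(5)
        entries = [
            (f"A{i%3}", f"D{i%5}", "1/1", float(10 * (i % 4)), "res",
             float(rng.normal()))
            for i in range(30)
        ]
        grid = self.grid_from(entries)
        ranked = rank_specs(grid, "res")["ln_gamma"].to_numpy()
        np.testing.assert_array_equal(ranked, np.sort([e[5] for e in entries]))

    def test_enumeration_order_irrelevant(self):
        entries = [
            ("Ch", "Pdiol", "1/5", 0.0, "res", -8.42),
            ("B", "Bdiol", "1/1", 30.0, "res", -5.08),
            ("Glu", "U", "1/3", 30.0, "res", 2.1),
        ]
        fwd = rank_specs(self.grid_from(entries), "res")["spec"].tolist()
        rev = rank_specs(self.grid_from(entries[::-1]), "res")["spec"].tolist()
        assert fwd == rev


class TestCorrelate:
    def test_perfect_negative_relation(self):
        lng = {"a": -8.0, "b": -5.0, "c": -2.0, "d": 0.0}
        content = {k: -v for k, v in lng.items()}
        rep = correlate(lng, content, solute="res")
        assert rep.r == pytest.approx(-1.0)
        assert rep.n == 4

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(17)
        keys = [f"s{i}" for i in range(8)]
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        rep = correlate(dict(zip(keys, x)), dict(zip(keys, y)))
        want = float(
            np.sum((x - x.mean()) * (y - y.mean()))
            / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        assert rep.r == pytest.approx(want, abs=1e-12)

    def test_unpaired_specs_dropped_and_reported(self):
        lng = {"a": -8.0, "b": -5.0, "c": -2.0, "d": 1.0}
        content = {"a": 4.0, "b": 3.0, "c": 1.0, "e": 9.9}
        rep = correlate(lng, content)
        assert rep.n == 3
        assert set(rep.dropped) == {"d", "e"}

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            correlate({"a": 1.0, "b": 1.0, "c": 1.0}, {"a": 1, "b": 2, "c": 3})

    def test_generator_round_trip_recovers_planted_slope_sign(self):
        lng = {"a": -8.0, "b": -6.0, "c": -4.0, "d": -2.0, "e": 0.0}
        spec = StudySpec(n_systems=5, intercept=1.0, slope=0.4, noise_sd=0.15,
                         replicates=3, seed=9)
        table = simulate_extraction_study(spec, lng)
        means = table.groupby("spec")["content"].mean().to_dict()
        rep = correlate(lng, means)
        assert rep.r < -0.9
        assert rep.p_value < 0.05


class TestHeatmap:
    def test_one_by_one_matrix(self):
        grid = TestRanking.grid_from([("Ch", "Gly", "1/1", 0.0, "res", -2.0)])
        m = heatmap_export(grid, "res")
        assert m.shape == (1, 1)
        assert m.iloc[0, 0] == -2.0

    def test_full_overview_slice_dimensions(self, registry, params):
        specs = datasets.heatmap_specs(registry)
        grid = screen([registry["trans-resveratrol"]], specs, params=params)
        m = heatmap_export(grid, "trans-resveratrol")
        assert m.shape == (13, 4)  # every registry HBD x every HBA

    def test_csv_round_trip(self, tmp_path):
        grid = TestRanking.grid_from(
            [
                ("Ch", "Gly", "1/1", 0.0, "res", -2.0),
                ("Ch", "U", "1/1", 0.0, "res", 1.5),
                ("B", "Gly", "1/1", 0.0, "res", -3.5),
                ("B", "U", "1/1", 0.0, "res", 0.5),
            ]
        )
        path = tmp_path / "m.csv"
        m = heatmap_export(grid, "res", csv_path=path)
        back = pd.read_csv(path, index_col=0)
        np.testing.assert_allclose(back.to_numpy(), m.to_numpy())

    def test_ragged_selection_lists_missing_cells(self):
        grid = TestRanking.grid_from(
            [
                ("Ch", "Gly", "1/1", 0.0, "res", -2.0),
                ("B", "U", "1/1", 0.0, "res", 0.5),
            ]
        )
        with pytest.raises(ValueError, match="missing cells"):
            heatmap_export(grid, "res")
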