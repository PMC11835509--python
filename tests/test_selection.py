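"""Selection intensity, truncation and the stage ladder."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tetracross as tc
from tetracross.phenogs import GSProxy
from tetracross.selection import STRATEGY_PRESETS
from tetracross.traits import TraitValues


class TestSelectionIntensity:
    @pytest.mark.parametrize(
        "p,expected", [(0.1, 1.755), (1.0, 0.0), (0.5, 0.7979)]
    )
    def test_known_values(self, p, expected):
        assert tc.selection_intensity(p) == pytest.approx(expected, abs=5e-4)

    def test_matches_numerical_truncated_normal_mean(self):
        # independent oracle: mean of the top-p fraction of a fine normal grid
        from scipy.stats import norm

        p = 0.1
        z = np.linspace(-8, 8, 2_000_001)
        pdf = norm.pdf(z)
        thresh = norm.ppf(1 - p)
        mask = z >= thresh
        numeric = np.trapezoid(z[mask] * pdf[mask], z[mask]) / p
        assert tc.selection_intensity(p) == pytest.approx(numeric, abs=1e-4)

    @given(st.floats(min_value=1e-4, max_value=1.0))
    def test_non_negative_and_decreasing_in_p(self, p):
        i = tc.selection_intensity(p)
        assert i >= 0
        assert tc.selection_intensity(min(1.0, p * 1.5)) <= i + 1e-12

    def test_invalid_proportion_rejected(self):
        for p in (0.0, -0.1, 1.2):
            with pytest.raises(ValueError):
                tc.selection_intensity(p)


class TestTruncate:
    def test_selects_largest(self):
        sel = tc.truncate(np.array([5.0, 1.0, 9.0, 3.0, 7.0]), 0.4)
        np.testing.assert_array_equal(sel, [2, 4])

    def test_ties_broken_by_index_order(self):
        sel = tc.truncate(np.zeros(10), 0.3)
        np.testing.assert_array_equal(sel, [0, 1, 2])

    def test_full_proportion_keeps_everything(self):
        sel = tc.truncate(np.array([3.0, 1.0]), 1.0)
        np.testing.assert_array_equal(sel, [0, 1])

    def test_empty_and_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            tc.truncate(np.array([]), 0.5)
        with pytest.raises(ValueError):
            tc.truncate(np.array([1.0, np.nan]), 0.5)


class TestStrategyPresets:
    @pytest.mark.parametrize("name", sorted(STRATEGY_PRESETS))
    def test_ladder_reaches_target_census(self, name):
        strat = STRATEGY_PRESETS[name](n_sl=3000, n_d=60)
        census = strat.expected_census()
        assert census["SL"] == 3000
        assert census["D"] == 60
        sizes = list(census.values())
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_gs_stages_only_in_genomic_strategy(self):
        assert STRATEGY_PRESETS["standard-ps"]().gs_stages == ()
        assert STRATEGY_PRESETS["optimal-gs"]().gs_stages == ("SH", "A")

    def test_alpha_must_cover_selected_proportion(self):
        with pytest.raises(ValueError, match="alpha"):
            tc.SelectionStrategy(
                kind="optimal-gs",
                proportions={"SL": 0.5, "SH": 0.5, "A": 0.5, "B": 0.5, "C": 0.5},
                gs_stages=("SH",),
                alpha={"SH": 0.2},
            )


def _ladder_inputs(small_founders, dominance="none", n_sl=200):
    rng = np.random.default_rng(77)
    arch_t = tc.sample_architecture(30, small_founders, seed=1, dominance_scale=dominance)
    arch_a = tc.derive_auxiliary_architecture(arch_t, 0.15, small_founders, seed=2)
    pairs = np.array([[i, i + 1] for i in range(0, 10, 2)])
    hap = tc.progeny_for_crosses(small_founders, pairs, n_sl // 5, rng)
    sl_pop = tc.HaplotypeSet(
        hap, np.array([f"s{i}" for i in range(hap.shape[0])], dtype=object),
        small_founders.gmap,
    )
    vm = tc.calibrate_variances(
        tc.true_values(sl_pop, arch_t), tc.true_values(sl_pop, arch_a, "Ta")
    )
    return sl_pop, arch_t, arch_a, vm, rng


class TestStageLadder:
    def _strategy(self, kind, n_sl, n_d):
        return STRATEGY_PRESETS[kind](n_sl=n_sl, n_d=n_d)

    def test_census_log_monotone_and_final_census(self, small_founders):
        sl_pop, arch_t, arch_a, vm, rng = _ladder_inputs(small_founders)
        strat = self._strategy("optimal-gs", 200, 4)
        res = tc.run_stage_ladder(sl_pop, strat, arch_t, arch_a, vm, GSProxy(0.5), rng)
        assert res.d_population.n_clones == 4
        log = res.census_log
        assert list(log["stage"]) == ["SL", "SH", "A", "B", "C", "D"]
        assert (log["n_selected"] <= log["n_entering"]).all()
        assert log["n_entering"].is_monotonic_decreasing

    def test_phenotypic_strategy_never_touches_gs(self, small_founders):
        sl_pop, arch_t, arch_a, vm, rng = _ladder_inputs(small_founders)
        strat = self._strategy("standard-ps", 200, 4)
        # gs=None proves no estimated values are computed anywhere
        res = tc.run_stage_ladder(sl_pop, strat, arch_t, arch_a, vm, None, rng)
        assert res.d_population.n_clones == 4
        assert set(res.census_log["mode"]) == {"PS", "phenotyped"}

    def test_genomic_strategy_requires_proxy(self, small_founders):
        sl_pop, arch_t, arch_a, vm, rng = _ladder_inputs(small_founders)
        strat = self._strategy("optimal-gs", 200, 4)
        with pytest.raises(ValueError, match="GSProxy"):
            tc.run_stage_ladder(sl_pop, strat, arch_t, arch_a, vm, None, rng)

    def test_alpha_one_is_pure_gs_ranking(self, small_founders):
        # with alpha=1 at a GS stage the phenotype pre-screen keeps everyone,
        # so the stage reduces to an EGV ranking of the whole census
        sl_pop, arch_t, arch_a, vm, _ = _ladder_inputs(small_founders)
        strat = tc.SelectionStrategy(
            kind="optimal-gs",
            proportions={"SL": 1.0, "SH": 0.1, "A": 1.0, "B": 1.0, "C": 1.0},
            n_sl=sl_pop.n_clones,
            n_d=20,
            gs_stages=("SH",),
            alpha={"SH": 1.0},
        )
        vm.sigma_gxl_tt = vm.sigma_trial_tt = vm.sigma_trial_ta = 0.0
        res = tc.run_stage_ladder(
            sl_pop, strat, arch_t, arch_a, vm, GSProxy(1.0),
            np.random.default_rng(0),
        )
        tgv = tc.true_values(sl_pop, arch_t).tgv
        expected = np.sort(tgv)[::-1][:20]
        got = np.sort(tc.true_values(res.d_population, arch_t).tgv)[::-1]
        np.testing.assert_allclose(got, expected)

    def test_perfect_information_makes_strategies_agree(self, small_founders):
        # with PA=1 and no phenotype noise, GS and PS rank identically, so
        # ladders with the same proportions select the same clone sets
        sl_pop, arch_t, _, vm, _ = _ladder_inputs(small_founders)
        arch_a = arch_t  # selection trait = target trait in this limit
        vm.sigma_gxl_tt = vm.sigma_trial_tt = vm.sigma_trial_ta = 0.0
        props = {"SL": 0.8, "SH": 0.5, "A": 0.5, "B": 0.5, "C": 1.0}
        ps = tc.SelectionStrategy("optimal-ps", dict(props), sl_pop.n_clones, 10)
        gsx = tc.SelectionStrategy(
            "optimal-gs", dict(props), sl_pop.n_clones, 10,
            gs_stages=("SH", "A"), alpha={"SH": 1.0, "A": 1.0},
        )
        res_ps = tc.run_stage_ladder(
            sl_pop, ps, arch_t, arch_a, vm, None, np.random.default_rng(4)
        )
        res_gs = tc.run_stage_ladder(
            sl_pop, gsx, arch_t, arch_a, vm, GSProxy(1.0), np.random.default_rng(4)
        )
        assert list(res_ps.d_population.ids) == list(res_gs.d_population.ids)

    def test_weakly_correlated_auxiliary_selection_still_gains(self, small_founders):
        # selecting on the auxiliary trait (r = 0.15) should shift the target
        # trait upward on average across repeated ladders
        diffs = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            arch_t = tc.sample_architecture(30, small_founders, seed=seed)
            arch_a = tc.derive_auxiliary_architecture(
                arch_t, 0.15, small_founders, seed=seed + 1
            )
            pairs = np.array([[i, i + 1] for i in range(0, 16, 2)])
            hap = tc.progeny_for_crosses(small_founders, pairs, 50, rng)
            pop = tc.HaplotypeSet(
                hap, np.array([f"s{i}" for i in range(hap.shape[0])], dtype=object),
                small_founders.gmap,
            )
            vm = tc.calibrate_variances(
                tc.true_values(pop, arch_t), tc.true_values(pop, arch_a, "Ta")
            )
            tgv_t = tc.true_values(pop, arch_t).tgv
            tgv_a = tc.true_values(pop, arch_a, "Ta").tgv
            phen_a = tc.simulate_phenotypes(tgv_a, vm, "SL", rng)
            sel = tc.truncate(phen_a, 0.2)
            diffs.append(tgv_t[sel].mean() - tgv_t.mean())
        assert np.mean(diffs) > 0
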