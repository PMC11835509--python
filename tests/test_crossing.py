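"""Candidate enumeration, criterion arithmetic and cross scoring."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tetracross as tc
from tetracross.traits import values_from_dosage


class TestCandidateCrosses:
    def test_half_diallel_count_at_burn_in(self):
        parents = [f"F{i}" for i in range(80)]
        assert len(tc.candidate_crosses(0, parents, [])) == 3160

    def test_cycle_one_excludes_used(self):
        parents = [f"P{i}" for i in range(100)]
        burn_in = tc.candidate_crosses(0, parents[:80], [])
        used = {frozenset(p) for p in burn_in[:300]}
        assert len(tc.candidate_crosses(1, parents[:80], parents[80:], used)) == 4650

    def test_later_cycles_old_by_new_plus_new_diallel(self):
        old = [f"O{i}" for i in range(80)]
        new = [f"N{i}" for i in range(20)]
        assert len(tc.candidate_crosses(5, old, new)) == 80 * 20 + 190  # 1790

    def test_no_self_crosses_and_no_reuse(self):
        old = ["a", "b"]
        new = ["c"]
        used = {frozenset(("a", "c"))}
        got = tc.candidate_crosses(2, old, new, used)
        assert got == [("b", "c")]

    def test_overlapping_pools_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            tc.candidate_crosses(2, ["a", "b"], ["b"])


class TestCriterionArithmetic:
    def test_euc_worked_example(self):
        # mu=10, sigma=2, w1=1, i=1.755, PA=0.5 -> 10 + 1.755 = 11.755
        assert tc.score_euc(10, 2, 1, 1.755, 0.5) == pytest.approx(11.755)
        assert tc.score_euc(10, 2, 100, 1.755, 0.5) == pytest.approx(185.5)

    def test_eucd_worked_examples(self):
        assert tc.score_eucd(10, 2, 0.5, 1, 50, 1.755, 0.5) == pytest.approx(36.755)
        assert tc.score_eucd(10, 2, 0.875, 1, 5000, 1.755, 0.5) == pytest.approx(4386.755)

    def test_mid_parent_values(self):
        assert tc.score_mpv((10.0, 14.0)) == 12.0
        assert tc.score_mpv((7.0, 7.0)) == 7.0

    @given(
        st.floats(-100, 100), st.floats(0, 50), st.floats(0, 100),
        st.floats(0, 0.875),
    )
    def test_criterion_algebra(self, mu, sigma, w1, he):
        # EUCD with w2=0 collapses to EUC; EUC with w1=0 is the plain mean
        assert tc.score_eucd(mu, sigma, he, w1, 0.0) == pytest.approx(
            tc.score_euc(mu, sigma, w1)
        )
        assert tc.score_euc(mu, sigma, 0.0) == pytest.approx(mu)

    def test_rank_invariance_under_mu_shift(self, rng):
        mu = rng.normal(size=50)
        sigma = rng.uniform(0, 3, 50)
        base = np.array([tc.score_euc(m, s) for m, s in zip(mu, sigma)])
        shifted = np.array([tc.score_euc(m + 7.0, s) for m, s in zip(mu, sigma)])
        np.testing.assert_array_equal(np.argsort(base), np.argsort(shifted))

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            tc.score_euc(1.0, -0.1)


class TestHePerCross:
    def test_monomorphic_progeny(self, small_founders):
        hs = tc.HaplotypeSet(
            np.zeros((5, 4, small_founders.n_markers), dtype=np.uint8),
            np.array([f"c{i}" for i in range(5)], dtype=object),
            small_founders.gmap,
        )
        assert tc.he_per_cross(hs) == 0.0

    def test_half_frequency_marker(self):
        gmap = tc.GeneticMap(np.array([1, 1]), np.array([10, 20]), np.array([0.0, 0.1]))
        hap = np.zeros((2, 4, 2), dtype=np.uint8)
        hap[:, :2, 0] = 1  # marker 0 at p = 0.5
        hap[:, :, 1] = 1  # marker 1 fixed
        hs = tc.HaplotypeSet(hap, np.array(["a", "b"], dtype=object), gmap)
        assert tc.he_per_cross(hs) == pytest.approx((0.875 + 0.0) / 2)


@pytest.fixture(scope="module")
def arch(small_founders):
    return tc.sample_architecture(25, small_founders, seed=13, dominance_scale="none")


class TestCrossSelectorScoring:

    def test_mpv_scores_are_mid_parent_phenotypes(self, small_founders, arch, rng):
        phen = rng.normal(size=small_founders.n_clones)
        sel = tc.CrossSelector(method="MPV")
        pairs = [("F000", "F001"), ("F002", "F005")]
        scores = sel.score(small_founders, pairs, arch, rng, parent_phenotypes=phen)
        assert scores["mu"][0] == pytest.approx(0.5 * (phen[0] + phen[1]))
        assert scores["mu"][1] == pytest.approx(0.5 * (phen[2] + phen[5]))

    def test_mpv_without_phenotypes_rejected(self, small_founders, arch, rng):
        with pytest.raises(ValueError, match="phenotypes"):
            tc.CrossSelector(method="MPV").score(
                small_founders, [("F000", "F001")], arch, rng
            )

    def test_parent_mean_with_perfect_accuracy_is_mid_parent_tbv(
        self, small_founders, arch, rng
    ):
        sel = tc.CrossSelector(method="MEBV-P", pa=1.0)
        pairs = [("F000", "F001")]
        scores = sel.score(small_founders, pairs, arch, rng)
        tv = tc.true_values(small_founders, arch)
        assert scores["mu"][0] == pytest.approx(0.5 * (tv.tbv[0] + tv.tbv[1]))

    def test_offspring_mean_converges_to_mid_parent_without_dominance(
        self, small_founders, arch
    ):
        sel = tc.CrossSelector(method="MEGV-O", pa=1.0, n_sim=4000)
        pairs = [("F000", "F001")]
        scores = sel.score(small_founders, pairs, arch, np.random.default_rng(4))
        tv = tc.true_values(small_founders, arch)
        mid = 0.5 * (tv.tbv[0] + tv.tbv[1])
        se = scores["sigma_g"][0] / np.sqrt(4000)
        assert abs(scores["mu"][0] - mid) < 4 * se

    def test_identical_homozygous_parents_give_zero_sigma(self, small_founders, arch, rng):
        hap = np.zeros((2, 4, small_founders.n_markers), dtype=np.uint8)
        # differ at one non-QTL marker to dodge the self-cross guard
        free = next(
            m for m in range(small_founders.n_markers) if m not in set(arch.qtl_idx)
        )
        hap[1, 0, free] = 1
        hs = tc.HaplotypeSet(hap, np.array(["x", "y"], dtype=object), small_founders.gmap)
        sel = tc.CrossSelector(method="MEGV-O", pa=1.0, n_sim=30)
        scores = sel.score(hs, [("x", "y")], arch, rng)
        assert scores["sigma_g"][0] == pytest.approx(0.0, abs=1e-10)

    def test_eucd_uses_per_cross_he(self, small_founders, arch, rng):
        sel = tc.CrossSelector(method="EUCD", w1=1.0, w2=500.0, n_sim=60)
        pairs = [("F000", "F001"), ("F004", "F009")]
        scores = sel.score(small_founders, pairs, arch, rng)
        assert np.all((scores["he"] >= 0) & (scores["he"] <= 0.875))
        expected = (
            scores["mu"]
            + 1.0 * sel.intensity * sel.pa * scores["sigma_g"]
            + 500.0 * scores["he"]
        )
        np.testing.assert_allclose(scores["score"], expected)

    def test_shared_progeny_sample_is_deterministic_per_stream(
        self, small_founders, arch
    ):
        sel = tc.CrossSelector(method="EUC", n_sim=40)
        pairs = [("F000", "F001"), ("F002", "F003")]
        a = sel.score(small_founders, pairs, arch, np.random.default_rng(8))
        b = sel.score(small_founders, pairs, arch, np.random.default_rng(8))
        np.testing.assert_allclose(a["score"], b["score"])

    def test_too_few_progenies_rejected(self):
        with pytest.raises(ValueError):
            tc.CrossSelector(method="MEGV-O", n_sim=1)

    def test_progeny_he_tracks_parental_pool_he(self, small_founders, arch):
        # per-cross He from simulated progeny correlates near-perfectly with
        # He of the two parents' pooled haplotypes
        rng = np.random.default_rng(15)
        pairs = [
            tuple(small_founders.ids[i] for i in rng.choice(16, 2, replace=False))
            for _ in range(60)
        ]
        sel = tc.CrossSelector(method="EUCD", w2=1.0, n_sim=150)
        scores = sel.score(small_founders, pairs, arch, rng)
        pooled = []
        for p1, p2 in pairs:
            pool = small_founders.subset_clones(small_founders.index_of([p1, p2]))
            pooled.append(pool.expected_heterozygosity())
        corr = np.corrcoef(scores["he"], pooled)[0, 1]
        assert corr > 0.99


class TestSelectCrossingPlan:
    def test_top_by_score(self, rng):
        import pandas as pd

        scores = pd.DataFrame(
            {"parent1": list("abcd"), "parent2": list("efgh"),
             "score": [3.0, 9.0, 1.0, 5.0]}
        )
        plan = tc.select_crossing_plan(scores, 2)
        assert list(plan["parent1"]) == ["b", "d"]

    def test_ties_keep_candidate_order(self):
        import pandas as pd

        scores = pd.DataFrame(
            {"parent1": list("abcd"), "parent2": list("efgh"), "score": [1.0] * 4}
        )
        plan = tc.select_crossing_plan(scores, 3)
        assert list(plan["parent1"]) == ["a", "b", "c"]

    def test_insufficient_candidates_rejected(self):
        import pandas as pd

        scores = pd.DataFrame({"parent1": ["a"], "parent2": ["b"], "score": [1.0]})
        with pytest.raises(ValueError):
            tc.select_crossing_plan(scores, 2)
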