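import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mirecur as m
from mirecur.evaluate import (
    hypergeometric_enrichment,
    km_estimate,
    location_shift_test,
    logrank_test,
    mean_split,
    prognostic_screen,
    resampling_geneset_enrichment,
    shuffle_baseline,
    topk_overlap_curve,
)
from mirecur.simulate import SurvivalConfig, simulate_survival


def _pairs(n):
    return [(f"m{j}", f"g{j}") for j in range(n)]


class TestTopkOverlap:
    def test_reference_equals_topk(self):
        ranked = _pairs(100)
        curve = topk_overlap_curve(ranked, set(ranked[:10]), ks=[10, 50])
        assert curve["count"].tolist() == [10, 10]

    def test_disjoint_reference_all_zero(self):
        curve = topk_overlap_curve(_pairs(50), {("x", "y")}, ks=[10, 20])
        assert (curve["count"] == 0).all()

    def test_matches_loop_oracle_and_binomial_expectation(self, rng):
        n, nref = 10_000, 500
        ranked = _pairs(n)
        ref = set(tuple(ranked[j]) for j in rng.choice(n, nref, replace=False))
        ks = list(range(2000, 10001, 2000))
        curve = topk_overlap_curve(ranked, ref, ks=ks)
        for k, cnt in zip(curve["k"], curve["count"]):
            oracle = sum(1 for p in ranked[:k] if p in ref)
            assert cnt == oracle
            expect = k * nref / n
            sd = np.sqrt(k * 0.05 * 0.95)
            assert abs(cnt - expect) <= 3 * sd
        assert (np.diff(curve["count"]) >= 0).all()
        assert (curve["count"] <= np.minimum(curve["k"], nref)).all()

    def test_k_beyond_length_truncated(self):
        curve = topk_overlap_curve(_pairs(5), set(_pairs(5)), ks=[3, 10])
        assert curve["count"].tolist() == [3, 5]
        assert curve["truncated"].tolist() == [False, True]


class TestShuffleBaseline:
    def test_seed_reproducible(self):
        ranked = _pairs(20)
        assert shuffle_baseline(ranked, 5) == shuffle_baseline(ranked, 5)

    def test_all_permutations_attainable_n3(self):
        ranked = _pairs(3)
        seen = {tuple(shuffle_baseline(ranked, s)) for s in range(200)}
        assert seen == set(itertools.permutations(ranked))


class TestLocationShiftTest:
    def test_null_p_uniform(self):
        rng = np.random.default_rng(8)
        pvals = [location_shift_test(rng.normal(size=200), rng.normal(size=200))
                 for _ in range(500)]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_complete_separation(self, rng):
        a = rng.normal(size=50)
        assert location_shift_test(a, a + 10, alternative="less") < 1e-6

    def test_textbook_exact_p(self):
        # all 20 arrangements of {1,2,3} vs {4,5,6}: only one as extreme
        p = location_shift_test([1, 2, 3], [4, 5, 6], alternative="less")
        assert p == pytest.approx(1 / 20)

    def test_paired_signed_rank(self, rng):
        a = rng.normal(size=30)
        p = location_shift_test(a, a + 0.5, alternative="less", paired=True)
        assert p < 0.01
        assert location_shift_test(a, a.copy(), paired=True) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            location_shift_test([], [1.0])


class TestHypergeometric:
    def test_zero_hits_p_one(self):
        assert hypergeometric_enrichment(0, 5, 3, 20) == pytest.approx(1.0)

    def test_full_overlap_combinatorial(self):
        # P(all 5 draws are the 5 successes out of 10) = 1 / C(10,5)
        assert hypergeometric_enrichment(5, 5, 5, 10) == pytest.approx(1 / 252)

    def test_matches_pmf_summation(self, rng):
        pop, succ, draws, hits = 200, 40, 30, 10
        p = hypergeometric_enrichment(hits, draws, succ, pop)
        total = sum(stats.hypergeom.pmf(x, pop, succ, draws)
                    for x in range(hits, min(draws, succ) + 1))
        assert p == pytest.approx(total, rel=1e-10)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(6, 5, 10, 20)


class TestResamplingEnrichment:
    def test_saturated_geneset_p_near_one(self, rng):
        pool = _pairs(100)
        sig = pool[:10]
        res = resampling_geneset_enrichment(pool, sig, {g for _, g in pool},
                                            reps=200, seed=1)
        assert res.p_value > 0.9

    def test_planted_enrichment_minimal_p(self, rng):
        pool = _pairs(500)
        geneset = {"g0", "g1", "g2"}
        sig = pool[:3]  # contains every geneset target
        res = resampling_geneset_enrichment(pool, sig, geneset, reps=999, seed=2)
        assert res.observed == 3
        assert res.p_value <= 5 / 1000  # few null draws can reach 3 of 3

    def test_reproducible_null(self):
        pool = _pairs(50)
        r1 = resampling_geneset_enrichment(pool, pool[:5], {"g1"}, reps=10,
                                           seed=3, keep_null=True)
        r2 = resampling_geneset_enrichment(pool, pool[:5], {"g1"}, reps=10,
                                           seed=3, keep_null=True)
        np.testing.assert_array_equal(r1.null_counts, r2.null_counts)

    def test_random_signature_p_valid_and_super_uniform(self):
        """Add-one empirical p-values under a random signature are valid:
        P(p <= a) <= a (up to Monte-Carlo error) at every level, never 0."""
        rng = np.random.default_rng(4)
        pool = _pairs(200)
        geneset = {f"g{j}" for j in range(50)}
        pvals = []
        for s in range(500):
            idx = rng.choice(200, 20, replace=False)
            sig = [pool[j] for j in idx]
            res = resampling_geneset_enrichment(pool, sig, geneset, reps=199, seed=s)
            pvals.append(res.p_value)
        pvals = np.array(pvals)
        assert ((0 < pvals) & (pvals <= 1)).all()
        for alpha in (0.05, 0.1, 0.25, 0.5):
            emp = (pvals <= alpha).mean()
            mc_sd = np.sqrt(alpha * (1 - alpha) / 500)
            assert emp <= alpha + 3 * mc_sd
        assert pvals.mean() > 0.4  # not degenerate toward 0

    def test_empty_geneset_rejected(self):
        with pytest.raises(ValueError):
            resampling_geneset_enrichment(_pairs(10), _pairs(2), set(), reps=10, seed=0)


class TestMeanSplit:
    def test_simple_split(self):
        labels, degen = mean_split([0, 0, 10, 10])
        assert labels.tolist() == ["low", "low", "high", "high"]
        assert not degen

    def test_constant_vector_all_low_flagged(self):
        labels, degen = mean_split([2.0, 2.0, 2.0])
        assert degen and (labels == "low").all()

    def test_matches_direct_comparison(self, rng):
        v = rng.normal(size=100)
        labels, _ = mean_split(v)
        np.testing.assert_array_equal(labels == "high", v > v.mean())


class TestKaplanMeier:
    def test_all_censored_flat_curve(self):
        km = km_estimate([5.0, 8.0, 12.0], [0, 0, 0])
        assert km(100.0) == 1.0

    def test_hand_computed_worked_example(self):
        # times 1 (event), 2 (censored), 3 (event):
        # S(1) = 1 - 1/3 = 2/3; at t=3 risk set = 1, death -> S(3) = 0
        km = km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
        assert km(1.0) == pytest.approx(2 / 3)
        assert km(2.5) == pytest.approx(2 / 3)
        assert km(3.0) == pytest.approx(0.0)
        assert km(0.5) == 1.0

    def test_matches_independent_product_limit(self, rng):
        times = rng.exponential(10, size=50).round(1) + 0.1
        events = (rng.random(50) < 0.7).astype(int)
        km = km_estimate(times, events)

        def oracle(t):
            s = 1.0
            for ti in sorted(set(times[events == 1])):
                if ti > t:
                    break
                n_at_risk = np.sum(times >= ti)
                d = np.sum((times == ti) & (events == 1))
                s *= 1 - d / n_at_risk
            return s

        for t in np.linspace(0.1, times.max(), 25):
            assert km(t) == pytest.approx(oracle(t), abs=1e-12)

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([0.0, 1.0], [1, 1])

    def test_non_increasing_right_continuous(self, rng):
        times = rng.exponential(10, size=40) + 0.1
        events = (rng.random(40) < 0.5).astype(int)
        km = km_estimate(times, events)
        grid = np.linspace(0, times.max() * 1.1, 200)
        vals = km(grid)
        assert (np.diff(vals) <= 1e-12).all()
        assert km(0.0) == 1.0


def logrank_oracle(times_a, events_a, times_b, events_b):
    """Hand-tabulated O/E/V log-rank computation."""
    times = np.concatenate([times_a, times_b])
    events = np.concatenate([events_a, events_b])
    group = np.concatenate([np.zeros(len(times_a)), np.ones(len(times_b))])
    O_E, V = 0.0, 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & (group == 0)).sum()
        d = ((times == t) & (events == 1)).sum()
        d_a = ((times == t) & (events == 1) & (group == 0)).sum()
        e_a = d * n_a / n
        O_E += d_a - e_a
        if n > 1:
            V += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    stat = O_E**2 / V
    return stat, stats.chi2.sf(stat, 1)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 1, 0, 1]
        stat, p, degen = logrank_test(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_tabulated_worked_example(self):
        ta, ea = np.array([1.0, 2.0]), np.array([1, 1])
        tb, eb = np.array([3.0, 4.0]), np.array([1, 1])
        stat, p, degen = logrank_test(ta, ea, tb, eb)
        stat_o, p_o = logrank_oracle(ta, ea, tb, eb)
        assert not degen
        assert stat == pytest.approx(stat_o, rel=1e-9)
        assert p == pytest.approx(p_o, rel=1e-9)

    def test_matches_oracle_on_random_data(self, rng):
        ta = rng.exponential(10, 30) + 0.1
        tb = rng.exponential(15, 25) + 0.1
        ea = (rng.random(30) < 0.8).astype(int)
        eb = (rng.random(25) < 0.8).astype(int)
        stat, p, _ = logrank_test(ta, ea, tb, eb)
        stat_o, p_o = logrank_oracle(ta, ea, tb, eb)
        assert stat == pytest.approx(stat_o, rel=1e-6)
        assert p == pytest.approx(p_o, rel=1e-6)

    def test_no_events_degenerate(self):
        stat, p, degen = logrank_test([1.0, 2.0], [0, 0], [3.0], [0])
        assert degen and p == 1.0

    def test_invariant_to_relabeling_and_time_scaling(self, rng):
        ta = rng.exponential(10, 20) + 0.1
        tb = rng.exponential(20, 20) + 0.1
        ea = np.ones(20, int)
        eb = np.ones(20, int)
        s1, p1, _ = logrank_test(ta, ea, tb, eb)
        s2, p2, _ = logrank_test(tb, eb, ta, ea)
        s3, p3, _ = logrank_test(ta * 3.5, ea, tb * 3.5, eb)
        assert s1 == pytest.approx(s2, rel=1e-9)
        assert p1 == pytest.approx(p3, rel=1e-9)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(6)
        pvals = []
        for _ in range(500):
            ta = rng.exponential(10, 100)
            tb = rng.exponential(10, 100)
            _, p, _ = logrank_test(ta, np.ones(100, int), tb, np.ones(100, int))
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestPrognosticScreen:
    def test_conjunction_rule_and_power(self, small_compendium):
        comp, _ = small_compendium
        gene = comp.common_genes[0]
        mir = comp.common_mirnas[0]
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            clin = simulate_survival(
                comp, SurvivalConfig(coefficients={gene: 1.2, mir: 1.2}, seed=seed))
            res = prognostic_screen([(mir, gene)], comp, clin, alpha=0.1)
            hits += len(res["flags"]) > 0
        assert hits / n_seeds >= 0.8

    def test_not_flagged_when_one_member_null(self, small_compendium):
        comp, _ = small_compendium
        gene = comp.common_genes[1]
        mir = comp.common_mirnas[1]
        # survival depends on neither member: flagging both at alpha=1e-6 is
        # effectively impossible
        clin = simulate_survival(comp, SurvivalConfig(seed=0))
        res = prognostic_screen([(mir, gene)], comp, clin, alpha=1e-6)
        assert len(res["flags"]) == 0

    def test_contingency_table_shape(self, small_compendium):
        comp, _ = small_compendium
        clin = simulate_survival(comp, SurvivalConfig(seed=2))
        rec_pairs = [(comp.common_mirnas[0], comp.common_genes[0])]
        cmp_pairs = [(comp.common_mirnas[1], comp.common_genes[1]),
                     (comp.common_mirnas[2], comp.common_genes[2])]
        res = prognostic_screen(rec_pairs, comp, clin, alpha=0.5,
                                comparison=cmp_pairs)
        table = res["contingency"]
        assert table.shape == (2, 2)
        assert table[0].sum() == 1 and table[1].sum() == 2

    def test_no_usable_clinical_errors(self, small_compendium):
        comp, _ = small_compendium
        with pytest.raises(ValueError, match="usable"):
            prognostic_screen([("m", "g")], comp, {}, alpha=0.1)
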