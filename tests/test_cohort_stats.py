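import math

import numpy as np
import pytest
from scipy import stats

from circafly.cohort_stats import (
    DegenerateTableError,
    aggregate_runs,
    bh_adjust,
    bonferroni,
    cochran_q,
    fisher_mxn,
    ks_two_sample,
    lnv_count_proportions,
    mcnemar,
    rank_test_suite,
    summarize_window,
)
from circafly.dam_io import AgeWindow
from circafly.periodogram import RhythmCall


def _calls(genotype, n_rhythmic, n_total, window="AW1"):
    calls = []
    for i in range(n_total):
        rhythmic = i < n_rhythmic
        calls.append(
            RhythmCall(
                f"{genotype}_f{i}", genotype, "run1", window, rhythmic,
                24.0 if rhythmic else None, 5.0 if rhythmic else None, 504,
            )
        )
    return calls


class TestSummarizeWindow:
    WINDOW = AgeWindow("AW1", 3, 9)

    def test_percentage_over_alive_flies(self):
        summaries = summarize_window(_calls("g1", 15, 20), {}, self.WINDOW)
        (s,) = summaries
        assert s.pct_rhythmic == pytest.approx(75.0)
        assert not s.excluded

    def test_small_group_excluded(self):
        (s,) = summarize_window(_calls("g1", 5, 8), {}, self.WINDOW)
        assert s.excluded and s.exclusion_reason == "n<10"

    def test_few_rhythmic_flies_excluded(self):
        (s,) = summarize_window(_calls("g1", 4, 20), {}, self.WINDOW)
        assert s.excluded and s.exclusion_reason == "n_rhythmic<10"

    def test_dead_flies_not_counted_alive(self):
        calls = _calls("g1", 12, 12)
        deaths = {c.fly_id: 5.0 for c in calls[:4]}  # died inside the window
        (s,) = summarize_window(calls, deaths, self.WINDOW)
        assert s.n_alive == 8
        assert s.excluded

    def test_all_dead_flagged(self):
        calls = _calls("g1", 0, 6)
        deaths = {c.fly_id: 3.5 for c in calls}
        (s,) = summarize_window(calls, deaths, self.WINDOW)
        assert s.n_alive == 0
        assert math.isnan(s.pct_rhythmic)


class TestAggregateRuns:
    def test_mean_and_sem(self):
        agg = aggregate_runs([50.0, 60.0, 70.0])
        assert agg.mean_pct == pytest.approx(60.0)
        assert agg.sem_pct == pytest.approx(10 / math.sqrt(3))

    def test_arcsine_square_root_boundaries(self):
        agg = aggregate_runs([0.0, 100.0])
        assert agg.transformed[0] == pytest.approx(0.0)
        assert agg.transformed[1] == pytest.approx(math.pi / 2)

    def test_single_run_sem_missing(self):
        assert aggregate_runs([80.0]).sem_pct is None

    def test_out_of_range_percentage_rejected(self):
        with pytest.raises(ValueError):
            aggregate_runs([50.0, 104.0])


class TestFisher:
    def test_extreme_2x2_exact(self):
        res = fisher_mxn([[10, 0], [0, 10]])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_balanced_2x2_is_null(self):
        assert fisher_mxn([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    def test_mc_agrees_with_exact_on_2x2(self):
        table = [[12, 4], [5, 11]]
        exact = fisher_mxn(table).p_value
        mc = fisher_mxn(table, n_mc=20_000, seed=0, force_mc=True)
        assert mc.method == "monte_carlo"
        assert abs(mc.p_value - exact) <= 3 * mc.mc_se + 1e-12

    def test_identical_rows_2x3_is_null(self):
        res = fisher_mxn([[6, 6, 6], [6, 6, 6]], n_mc=20_000, seed=1)
        assert res.p_value >= 1.0 - 3 * res.mc_se

    def test_strong_association_2x3_detected(self):
        res = fisher_mxn([[15, 0, 0], [0, 15, 0], [0, 0, 15]], n_mc=20_000, seed=2)
        assert res.p_value < 1e-3

    def test_degenerate_margin_rejected(self):
        with pytest.raises(DegenerateTableError):
            fisher_mxn([[0, 0], [3, 4]])


class TestBHAdjust:
    def test_step_up_hand_example(self):
        # matches R p.adjust(c(0.01, 0.04, 0.03), "BH")
        adj, reject = bh_adjust([0.01, 0.04, 0.03], fdr=0.05)
        np.testing.assert_allclose(adj, [0.03, 0.04, 0.04])
        assert reject.all()

    def test_all_ones_never_rejected(self):
        adj, reject = bh_adjust([1.0, 1.0, 1.0])
        np.testing.assert_allclose(adj, 1.0)
        assert not reject.any()

    def test_single_p_unchanged(self):
        adj, _ = bh_adjust([0.02])
        assert adj[0] == pytest.approx(0.02)

    def test_monotone_and_permutation_invariant(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=25)
        adj, _ = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        perm = rng.permutation(25)
        adj_perm, _ = bh_adjust(p[perm])
        np.testing.assert_allclose(adj_perm, adj[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestCochranQMcNemar:
    def test_all_rhythmic_everywhere_undefined(self):
        res = cochran_q(np.ones((8, 3)))
        assert res.statistic is None and res.note

    def test_k2_equals_mcnemar_without_continuity(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            x = rng.integers(0, 2, size=(rng.integers(4, 30), 2))
            q = cochran_q(x)
            b = int(((x[:, 0] == 1) & (x[:, 1] == 0)).sum())
            c = int(((x[:, 0] == 0) & (x[:, 1] == 1)).sum())
            m = mcnemar(b, c, continuity=False)
            if q.statistic is None or m.statistic is None:
                assert q.statistic is None and m.statistic is None
            else:
                assert q.statistic == pytest.approx(m.statistic, abs=1e-9)
                assert q.p_value == pytest.approx(m.p_value, abs=1e-9)

    def test_hand_computed_three_fly_case(self):
        # flies x windows = [[1,0],[1,0],[1,1]]: C=(3,1), R=(1,1,2), N=4
        # Q = 1*(2*(9+1) - 16) / (2*4 - (1+1+4)) = 4/2 = 2
        res = cochran_q([[1, 0], [1, 0], [1, 1]])
        assert res.statistic == pytest.approx(2.0)
        assert res.p_value == pytest.approx(float(stats.chi2.sf(2.0, 1)))

    def test_mcnemar_symmetric_discordance_is_null(self):
        res = mcnemar(7, 7)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_mcnemar_one_sided_discordance(self):
        assert mcnemar(10, 0).statistic == pytest.approx(10.0)

    def test_mcnemar_continuity_correction(self):
        assert mcnemar(10, 0, continuity=True).statistic == pytest.approx(8.1)

    def test_mcnemar_no_discordant_pairs_missing(self):
        res = mcnemar(0, 0)
        assert res.statistic is None and res.note


class TestKSAndProportions:
    def test_identical_samples_null(self):
        res = ks_two_sample([0, 1, 2, 3], [0, 1, 2, 3])
        assert res.d_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_disjoint_support_maximal_d(self):
        res = ks_two_sample([0, 0, 0], [5, 5, 5])
        assert res.d_statistic == pytest.approx(1.0)

    def test_hand_computed_ecdf_difference(self):
        res = ks_two_sample([0, 0, 5, 5], [0, 5, 5, 5])
        assert res.d_statistic == pytest.approx(0.25)

    def test_bonferroni_caps_at_one(self):
        assert bonferroni(0.4, 5) == 1.0
        assert bonferroni(0.01, 3) == pytest.approx(0.03)

    def test_count_proportions_sum_to_one(self):
        props = lnv_count_proportions([0, 4, 4, 5, 2, 4])
        assert props.sum() == pytest.approx(1.0)
        assert props[4] == pytest.approx(0.5)

    def test_count_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lnv_count_proportions([2, 6])


class TestRankTestSuite:
    def test_identical_groups_are_null(self):
        rep = rank_test_suite({"a": [1, 2, 3, 4, 5], "b": [1, 2, 3, 4, 5]})
        assert rep.p_value == pytest.approx(1.0, abs=0.05)
        assert "kruskal" in rep.method

    def test_strongly_shifted_groups_detected(self):
        rng = np.random.default_rng(21)
        rep = rank_test_suite(
            {
                "a": rng.normal(0, 1, 30),
                "b": rng.normal(10, 1, 30),
                "c": rng.normal(20, 1, 30),
            }
        )
        assert rep.p_value < 1e-3
        assert rep.posthoc["reject"].all()

    def test_repeated_design_uses_friedman(self):
        rng = np.random.default_rng(22)
        base = rng.normal(0, 1, 15)
        rep = rank_test_suite(
            {"w1": base, "w2": base + 3, "w3": base + 6},
            design="repeated",
            correction="bonferroni",
        )
        assert "friedman" in rep.method
        assert rep.p_value < 1e-3

    def test_mismatched_repeated_lengths_rejected(self):
        with pytest.raises(ValueError):
            rank_test_suite({"a": [1, 2], "b": [1, 2, 3]}, design="repeated")

    def test_metadata_records_correction(self):
        rep = rank_test_suite({"a": [1, 2, 3], "b": [4, 5, 6]}, correction="bonferroni")
        assert rep.metadata["correction"] == "bonferroni"
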