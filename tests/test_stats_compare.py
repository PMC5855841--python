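"""Statistical battery: formula-level implementations vs independent oracles.

scipy.stats serves only as the cross-check oracle here; the implementations
under test compute every statistic from first principles.
"""

import math

import numpy as np
import pytest
import scipy.stats

from cavgate.errors import InvalidInputError
from cavgate.stats_compare import (
    dunn_posthoc,
    fisher_exact,
    kruskal_wallis,
    mann_whitney_u,
    rank_with_ties,
    students_t,
    summarize,
)


class TestSummarize:
    def test_sem_is_sd_over_sqrt_n(self):
        s = summarize("g", [1.0, 2.0, 3.0, 4.0])
        assert s.n == 4
        assert s.sem == pytest.approx(s.sd / 2.0)

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            summarize("g", [])


class TestRanks:
    def test_midranks_and_tie_groups(self):
        ranks, ties = rank_with_ties([10.0, 20.0, 20.0, 30.0])
        assert list(ranks) == [1.0, 2.5, 2.5, 4.0]
        assert ties == [2]


class TestMannWhitney:
    def test_complete_separation_exact(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2/20 labelings
        assert "exact" in res.flags

    def test_identical_samples_p_one(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0

    def test_exact_matches_scipy_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.normal(size=5)
            y = rng.normal(size=5)
            mine = mann_whitney_u(x, y, mode="exact")
            ref = scipy.stats.mannwhitneyu(x, y, method="exact")
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_close_to_asymptotic_at_8_per_group(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            exact = mann_whitney_u(x, y, mode="exact")
            asym = mann_whitney_u(x, y, mode="asymptotic")
            assert abs(exact.p_value - asym.p_value) < 0.02

    def test_monotone_transform_invariance(self):
        x, y = [1.0, 5.0, 9.0], [2.0, 3.0, 11.0]
        base = mann_whitney_u(x, y)
        trans = mann_whitney_u(np.exp(x), np.exp(y))
        assert trans.p_value == base.p_value
        assert trans.statistic == base.statistic

    def test_empty_sample_rejected(self):
        with pytest.raises(InvalidInputError):
            mann_whitney_u([], [1.0])


class TestKruskalWallis:
    def test_hand_computed_three_groups(self):
        # ranks 1..6, rank sums 3, 7, 11:
        # H = 12/(6*7) * (9/2 + 49/2 + 121/2) - 3*7 = 4.5714...
        res = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert res.statistic == pytest.approx(32.0 / 7.0, abs=1e-12)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            groups = [list(rng.integers(0, 6, size=7)) for _ in range(3)]
            mine = kruskal_wallis(groups)
            ref = scipy.stats.kruskal(*groups)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_all_identical_degenerate(self):
        res = kruskal_wallis([[3.0, 3.0], [3.0, 3.0]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_two_groups_equals_mann_whitney_asymptotic(self):
        """Chi-square p of 2-group KW == two-sided MW normal p without CC."""
        rng = np.random.default_rng(3)
        for _ in range(5):
            x = list(rng.normal(size=9))
            y = list(rng.normal(size=12))
            kw = kruskal_wallis([x, y])
            mw = mann_whitney_u(x, y, mode="asymptotic", continuity=False)
            assert kw.p_value == pytest.approx(mw.p_value, abs=1e-6)


class TestDunn:
    def test_identical_pair_z_zero(self):
        res = dunn_posthoc([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [10.0, 11.0, 12.0]])
        pair01 = next(e for e in res.pairwise if (e["i"], e["j"]) == (0, 1))
        assert pair01["z"] == pytest.approx(0.0, abs=1e-12)
        assert pair01["p_value"] == 1.0

    def test_bonferroni_monotone(self):
        groups = [[1, 5, 3], [2, 8, 4], [9, 7, 6]]
        adj = dunn_posthoc(groups, adjustment="bonferroni")
        raw = dunn_posthoc(groups, adjustment="none")
        for e_adj, e_raw in zip(adj.pairwise, raw.pairwise):
            assert e_adj["p_value"] >= e_raw["p_value"]

    def test_hand_rank_oracle_on_fixed_dataset(self):
        """z values agree with an independent spreadsheet-style computation."""
        groups = [[1, 2, 3, 7], [4, 5, 6], [8, 9, 10, 11]]
        res = dunn_posthoc(groups, adjustment="none")
        # independent rank arithmetic: no ties, ranks are the values' order
        all_vals = sorted(v for g in groups for v in g)
        ranks = {v: i + 1 for i, v in enumerate(all_vals)}
        mean_ranks = [np.mean([ranks[v] for v in g]) for g in groups]
        n = 11
        var = n * (n + 1) / 12.0
        for entry in res.pairwise:
            i, j = entry["i"], entry["j"]
            se = math.sqrt(var * (1 / len(groups[i]) + 1 / len(groups[j])))
            z_oracle = (mean_ranks[i] - mean_ranks[j]) / se
            assert entry["z"] == pytest.approx(z_oracle, abs=1e-12)

    def test_needs_three_groups(self):
        with pytest.raises(InvalidInputError):
            dunn_posthoc([[1.0], [2.0]])


class TestStudentsT:
    def test_identical_samples(self):
        res = students_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_antisymmetric_in_group_order(self):
        x, y = [1.0, 2.0, 4.0], [3.0, 5.0, 6.0]
        a = students_t(x, y)
        b = students_t(y, x)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_matches_scipy_pooled(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            x = rng.normal(size=6)
            y = rng.normal(1.0, 2.0, size=9)
            mine = students_t(x, y)
            ref = scipy.stats.ttest_ind(x, y, equal_var=True)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_degenerate_zero_variance(self):
        same = students_t([2.0, 2.0], [2.0, 2.0])
        assert same.p_value == 1.0 and "degenerate_zero_variance" in same.flags
        diff = students_t([2.0, 2.0], [3.0, 3.0])
        assert diff.p_value == 0.0 and "degenerate_zero_variance" in diff.flags


class TestFisherExact:
    def test_tea_tasting_table(self):
        res = fisher_exact([[3, 1], [1, 3]])
        assert res.p_value == pytest.approx(0.4857142857, abs=1e-9)

    def test_perfect_separation(self):
        res = fisher_exact([[0, 5], [5, 0]])
        assert res.p_value == pytest.approx(2.0 / 252.0, abs=1e-12)

    def test_identical_rows_independent(self):
        for a, b in [(1, 2), (4, 4), (7, 3)]:
            assert fisher_exact([[a, b], [a, b]]).p_value == pytest.approx(1.0)

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            table = rng.integers(0, 12, size=(2, 2))
            if 0 in table.sum(axis=0) or 0 in table.sum(axis=1):
                continue
            mine = fisher_exact(table.tolist())
            ref = scipy.stats.fisher_exact(table)
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_transposition_and_swap_symmetry(self):
        table = [[3, 7], [5, 2]]
        p = fisher_exact(table).p_value
        assert fisher_exact([[3, 5], [7, 2]]).p_value == pytest.approx(p)
        assert fisher_exact([[5, 2], [3, 7]]).p_value == pytest.approx(p)
        assert fisher_exact([[7, 3], [2, 5]]).p_value == pytest.approx(p)

    def test_zero_margin_degenerate(self):
        res = fisher_exact([[0, 0], [3, 4]])
        assert res.p_value == 1.0
        assert "degenerate_zero_margin" in res.flags

    def test_negative_or_fractional_rejected(self):
        with pytest.raises(InvalidInputError):
            fisher_exact([[1, -2], [3, 4]])


class TestTypeIError:
    def test_null_rejection_rates_near_nominal(self):
        """All tests reject ~5% of 2000 null datasets (n = 10 per group)."""
        rng = np.random.default_rng(20)
        reps = 2000
        rej = {"mw": 0, "kw": 0, "t": 0}
        for _ in range(reps):
            g = [rng.normal(size=10) for _ in range(3)]
            if mann_whitney_u(g[0], g[1], mode="asymptotic").p_value < 0.05:
                rej["mw"] += 1
            if kruskal_wallis(g).p_value < 0.05:
                rej["kw"] += 1
            if students_t(g[0], g[1]).p_value < 0.05:
                rej["t"] += 1
        for name, count in rej.items():
            assert 0.03 <= count / reps <= 0.07, (name, count / reps)
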