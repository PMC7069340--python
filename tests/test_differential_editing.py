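"""Mann–Whitney exact/approximate branches against enumeration, BH against
brute force, eligibility rules, and power/type-I behaviour on simulated
cohorts."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edikit.differential_editing import (
    bh_adjust,
    diff_table,
    eligible_sites,
    mw_test,
    ranked_wilcoxon_procedure,
)
from edikit.synthetic_data import simulate_differential_cohort


def enumeration_p(x, y):
    """Independent two-sided exact p by full enumeration."""
    def u_stat(a, b):
        return sum(1.0 if ai > bj else 0.5 if ai == bj else 0.0
                   for ai in a for bj in b)

    pooled = list(x) + list(y)
    n1, n = len(x), len(x) + len(y)
    u_obs = u_stat(x, y)
    us = []
    for idx in combinations(range(n), n1):
        sel = set(idx)
        us.append(u_stat([pooled[i] for i in idx],
                         [pooled[i] for i in range(n) if i not in sel]))
    le = sum(1 for u in us if u <= u_obs + 1e-12) / len(us)
    ge = sum(1 for u in us if u >= u_obs - 1e-12) / len(us)
    return min(1.0, 2 * min(le, ge))


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        u, p = mw_test([0.1, 0.2, 0.3], [0.4, 0.5, 0.6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_two_vs_two_separated(self):
        _, p = mw_test([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_identical_multisets_p_one(self):
        _, p = mw_test([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_exact_branch_matches_enumeration_all_small_sizes(self):
        rng = np.random.default_rng(3)
        for n1 in range(1, 7):
            for n2 in range(1, 7):
                x = list(rng.permutation(np.arange(n1 + n2) * 1.0 + 1)[:n1])
                y = list(rng.uniform(0, 10, size=n2))
                u, p = mw_test(x, y)
                assert p == pytest.approx(enumeration_p(x, y)), (n1, n2)

    def test_exact_branch_matches_scipy(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(4)
        for _ in range(30):
            n1, n2 = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            x, y = list(vals[:n1]), list(vals[n1:])
            u, p = mw_test(x, y)
            ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_normal_approximation_close_to_exact(self):
        # 13 tie-free observations force the approximate branch; compare it
        # with the independent enumeration oracle
        rng = np.random.default_rng(5)
        diffs = []
        for _ in range(30):
            x = list(rng.uniform(size=6))
            y = list(rng.uniform(size=7))
            _, p_apx = mw_test(x, y)
            diffs.append(abs(p_apx - enumeration_p(x, y)))
        assert max(diffs) <= 0.02
        assert np.median(diffs) <= 0.01

    def test_all_missing_group_rejected(self):
        with pytest.raises(ValueError):
            mw_test([], [1.0])


class TestBenjaminiHochberg:
    def test_reference_vectors(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
        assert bh_adjust([0.05, 0.5]) == pytest.approx([0.10, 0.50])
        assert bh_adjust([0.2]) == [0.2]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_min_over_suffix_brute_force(self):
        rng = np.random.default_rng(6)
        for _ in range(1000):
            m = int(rng.integers(1, 12))
            p = list(rng.uniform(size=m))
            order = sorted(range(m), key=lambda i: p[i])
            expected = [0.0] * m
            for k, i in enumerate(order, start=1):
                expected[i] = min(
                    min(p[order[j - 1]] * m / j for j in range(k, m + 1)), 1.0
                )
            assert bh_adjust(p) == pytest.approx(expected)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        p = list(rng.uniform(size=40))
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        assert bh_adjust(p) == pytest.approx(list(ref))

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_monotone_along_sorted_order(self, p):
        adj = bh_adjust(p)
        pairs = sorted(zip(p, adj))
        for (_, a1), (__, a2) in zip(pairs, pairs[1:]):
            assert a1 <= a2 + 1e-12


def make_group(samples, sites, cov=20, level=0.2):
    return {
        f"s{i}": {site: (level, cov) for site in sites} for i in range(samples)
    }


class TestEligibility:
    def test_fraction_rule(self):
        sites = [("c", 0)]
        g1 = {f"a{i}": {("c", 0): (0.1, 10 if i < 7 else 5)} for i in range(14)}
        g2 = {f"b{i}": {("c", 0): (0.1, 10 if i < 6 else 5)} for i in range(12)}
        assert eligible_sites(g1, g2) == [("c", 0)]
        g2["b5"] = {("c", 0): (0.1, 5)}  # now only 5/12 reach depth
        assert eligible_sites(g1, g2) == []

    def test_site_uncovered_in_one_group_ineligible(self):
        g1 = make_group(4, [("c", 0)])
        g2 = make_group(4, [("c", 1)])
        assert eligible_sites(g1, g2) == []

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            eligible_sites({}, make_group(3, [("c", 0)]))

    def test_synthetic_cohort_matches_recount(self):
        g1, g2, _ = simulate_differential_cohort(seed=8, mean_coverage=12)
        out = set(eligible_sites(g1, g2))
        for site in {s for g in (g1, g2) for lv in g.values() for s in lv}:
            expected = all(
                sum(1 for lv in g.values() if lv[site][1] >= 10)
                >= math.ceil(0.5 * len(g))
                for g in (g1, g2)
            )
            assert (site in out) == expected


class TestDiffTable:
    def test_empty_on_no_eligible_sites(self):
        g1 = make_group(4, [("c", 0)], cov=5)
        g2 = make_group(4, [("c", 0)], cov=5)
        assert diff_table(g1, g2) == []

    def test_power_and_type_I_on_programmed_shift(self):
        powers, false_pos = [], []
        for seed in range(20):
            g1, g2, shifted = simulate_differential_cohort(seed=seed)
            rows = diff_table(g1, g2)
            sig = {r.site for r in rows if r.direction != "ns"}
            powers.append(len(sig & set(shifted)))
            false_pos.append(len(sig - set(shifted)))
        assert np.median(powers) >= 8
        assert np.median(false_pos) <= 1

    def test_direction_follows_delta_sign(self):
        g1, g2, shifted = simulate_differential_cohort(seed=9)
        for r in diff_table(g1, g2):
            if r.direction != "ns":
                assert r.direction == ("up" if r.delta > 0 else "down")
            assert r.p_adj >= r.p_value - 1e-12

    def test_invariant_to_sample_order(self):
        g1, g2, _ = simulate_differential_cohort(seed=10)
        rows = diff_table(g1, g2)
        g1_shuf = dict(reversed(list(g1.items())))
        rows_shuf = diff_table(g1_shuf, g2)
        assert [(r.site, r.p_adj, r.direction) for r in rows] == [
            (r.site, r.p_adj, r.direction) for r in rows_shuf
        ]

    def test_type_I_controlled_under_null(self):
        fracs = []
        for seed in range(10):
            g1, g2, _ = simulate_differential_cohort(seed=seed, n_shifted=0)
            rows = diff_table(g1, g2)
            fracs.append(np.mean([r.direction != "ns" for r in rows]))
        assert np.mean(fracs) <= 0.05


class TestRankedWilcoxon:
    def test_min_samples_gate(self):
        sites = [("c", 0)]
        g1 = {f"a{i}": {("c", 0): (0.2, 20 if i < 4 else 5)} for i in range(8)}
        g2 = make_group(8, sites, cov=20)
        assert ranked_wilcoxon_procedure(g1, g2, min_samples=5) == []
        g1["a4"] = {("c", 0): (0.2, 20)}
        assert len(ranked_wilcoxon_procedure(g1, g2, min_samples=5)) == 1

    def test_output_ordered_by_total_coverage(self):
        g1 = {"a": {("c", i): (0.1 * i, (3 - i) * 100) for i in range(3)}}
        g1 = {f"a{j}": dict(g1["a"]) for j in range(6)}
        g2 = {f"b{j}": {("c", i): (0.05, (3 - i) * 100) for i in range(3)} for j in range(6)}
        rows = ranked_wilcoxon_procedure(g1, g2, min_samples=5)
        covs = [r.total_coverage for r in rows]
        assert covs == sorted(covs, reverse=True)

    def test_tested_set_within_mw_eligible_set_when_thresholds_coincide(self):
        g1, g2, _ = simulate_differential_cohort(seed=11, n_per_group=10,
                                                 mean_coverage=12)
        mw_sites = set(eligible_sites(g1, g2, min_cov=10, min_frac=0.5))
        rw_sites = {r.site for r in ranked_wilcoxon_procedure(
            g1, g2, min_cov=10, min_samples=5)}
        assert rw_sites <= mw_sites
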