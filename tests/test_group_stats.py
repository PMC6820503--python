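"""Exact nonparametric tests against enumeration oracles and scipy."""

from itertools import combinations, product

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from cytoboot import (
    Contrast,
    StudyDesign,
    compare_frequency_table,
    mann_whitney_u,
    stars,
    wilcoxon_signed_rank,
)
from cytoboot.errors import ContractError


# -- independent brute-force oracles (plain loops, no shared code) -------

def mw_oracle_p(a, b):
    pooled = list(a) + list(b)
    n1 = len(a)
    ranks = scipy.stats.rankdata(pooled)
    u_obs = sum(ranks[:n1]) - n1 * (n1 + 1) / 2

    def u_of(subset):
        return sum(ranks[i] for i in subset) - n1 * (n1 + 1) / 2

    us = [u_of(c) for c in combinations(range(len(pooled)), n1)]
    lo = sum(1 for u in us if u <= u_obs + 1e-9) / len(us)
    hi = sum(1 for u in us if u >= u_obs - 1e-9) / len(us)
    return min(1.0, 2 * min(lo, hi))


def wsr_oracle_p(diffs):
    d = [x for x in diffs if x != 0]
    ranks = scipy.stats.rankdata([abs(x) for x in d])
    w_obs = sum(r for r, x in zip(ranks, d) if x > 0)
    ws = [sum(r for r, s in zip(ranks, signs) if s) for signs in product([0, 1], repeat=len(d))]
    lo = sum(1 for w in ws if w <= w_obs + 1e-9) / len(ws)
    hi = sum(1 for w in ws if w >= w_obs - 1e-9) / len(ws)
    return min(1.0, 2 * min(lo, hi))


class TestMannWhitney:
    def test_fully_separated_three_vs_three(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.method == "exact"
        assert res.p_two_sided == pytest.approx(0.1)

    def test_complete_ties(self):
        res = mann_whitney_u([1, 1], [1, 1])
        assert res.statistic == 2.0
        assert res.p_two_sided == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ContractError):
            mann_whitney_u([], [1.0])

    def test_exact_matches_scipy_tie_free(self, rng):
        for n1 in range(1, 7):
            for n2 in range(1, 7):
                a = rng.normal(size=n1)
                b = rng.normal(size=n2)
                mine = mann_whitney_u(a, b)
                ref = scipy.stats.mannwhitneyu(a, b, method="exact", alternative="two-sided")
                assert mine.method == "exact"
                assert mine.p_two_sided == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_matches_brute_force_with_ties(self, rng):
        for _ in range(10):
            a = rng.integers(0, 4, size=rng.integers(2, 5)).astype(float)
            b = rng.integers(0, 4, size=rng.integers(2, 5)).astype(float)
            mine = mann_whitney_u(a, b)
            assert mine.p_two_sided == pytest.approx(mw_oracle_p(a, b), abs=1e-12)

    def test_exact_and_normal_agree_near_crossover(self, rng):
        """Tie-free n1=n2=10: exact vs forced normal approximation within 0.02."""
        for _ in range(10):
            a = rng.normal(size=10)
            b = rng.normal(0.5, 1, size=10)
            exact = mann_whitney_u(a, b)
            approx = mann_whitney_u(a, b, exact_max_n=0, exact_max_n_noties=0)
            assert exact.method == "exact" and approx.method == "normal_approx"
            assert abs(exact.p_two_sided - approx.p_two_sided) < 0.02

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-50, 50), min_size=1, max_size=7),
        st.lists(st.floats(-50, 50), min_size=1, max_size=7),
    )
    def test_label_swap_invariance_and_u_sum(self, a, b):
        r1 = mann_whitney_u(a, b)
        r2 = mann_whitney_u(b, a)
        assert 0 <= r1.p_two_sided <= 1
        assert r1.p_two_sided == pytest.approx(r2.p_two_sided, abs=1e-12)
        assert r1.statistic + r2.statistic == pytest.approx(len(a) * len(b))


class TestWilcoxon:
    def test_all_positive_five(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5])
        assert res.statistic == 15.0
        assert res.method == "exact"
        assert res.p_two_sided == pytest.approx(2 / 32)

    def test_tied_symmetric_pair(self):
        res = wilcoxon_signed_rank([-1, 1])
        assert res.statistic == 1.5
        assert res.p_two_sided == 1.0

    def test_all_zero_differences_degenerate(self):
        res = wilcoxon_signed_rank([0.0, 0.0])
        assert res.p_two_sided == 1.0
        assert res.method == "exact"
        assert res.degenerate

    def test_exact_matches_scipy_tie_free(self, rng):
        for n in range(2, 11):
            d = rng.normal(0.3, 1, size=n)
            mine = wilcoxon_signed_rank(d)
            ref = scipy.stats.wilcoxon(d, method="exact", alternative="two-sided")
            assert mine.method == "exact"
            assert mine.p_two_sided == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_matches_brute_force_with_ties(self, rng):
        for _ in range(8):
            d = (rng.integers(-3, 4, size=6) + 0.0).tolist()
            if all(x == 0 for x in d):
                continue
            mine = wilcoxon_signed_rank(d)
            assert mine.p_two_sided == pytest.approx(wsr_oracle_p(d), abs=1e-12)

    def test_exact_and_normal_agree_near_crossover(self, rng):
        for _ in range(10):
            d = rng.normal(0.4, 1, size=15)
            exact = wilcoxon_signed_rank(d)
            approx = wilcoxon_signed_rank(d, exact_max_n=0)
            assert abs(exact.p_two_sided - approx.p_two_sided) < 0.02

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-20, 20), min_size=1, max_size=9))
    def test_negation_invariance(self, d):
        r1 = wilcoxon_signed_rank(d)
        r2 = wilcoxon_signed_rank([-x for x in d])
        assert 0 <= r1.p_two_sided <= 1
        assert r1.p_two_sided == pytest.approx(r2.p_two_sided, abs=1e-12)


def test_star_convention():
    assert stars(0.2) == "ns"
    assert stars(0.049) == "*"
    assert stars(0.009) == "**"
    assert stars(0.0009) == "***"


def _freq_frame(values_by_donor):
    return pd.DataFrame(
        [
            {
                "donor": d, "population": "NK", "combination": "CD38+NKp46+",
                "numerator": 0, "denominator": 100, "percentage": v, "undefined": False,
            }
            for d, v in values_by_donor.items()
        ]
    )


class TestCompareFrequencyTable:
    def test_identical_frequencies_not_significant(self, three_group_design):
        freq = _freq_frame({d: 40.0 for d in three_group_design.donor_ids})
        results = compare_frequency_table(
            freq, three_group_design,
            [Contrast("control", "pregnant"), Contrast("postpartum", "pregnant", paired=True)],
        )
        assert all(r.p_two_sided == 1.0 and r.stars == "ns" for r in results)

    def test_absent_group_rejected(self, three_group_design):
        freq = _freq_frame({d: 40.0 for d in three_group_design.donor_ids})
        with pytest.raises(ContractError):
            compare_frequency_table(freq, three_group_design, [Contrast("control", "missing")])

    def test_paired_contrast_orientation(self, three_group_design):
        vals = {"c1": 10, "c2": 12, "p1": 50, "p2": 52, "q1": 20, "q2": 22}
        freq = _freq_frame(vals)
        (res,) = compare_frequency_table(
            freq, three_group_design, [Contrast("postpartum", "pregnant", paired=True)]
        )
        # pregnant minus postpartum differences are +30 each: W = full positive sum
        assert res.test == "wilcoxon_signed_rank"
        assert res.statistic == 3.0
        assert res.n_pairs == 2

    def test_configured_frequency_shift_detected(self):
        """20-point pregnant shift, donor sd 5, 10+10 donors: p<0.05 in >=90%."""
        donors = [f"c{i}" for i in range(10)] + [f"p{i}" for i in range(10)]
        design = StudyDesign(
            donors=pd.DataFrame(
                {"group": ["control"] * 10 + ["pregnant"] * 10, "cohort": "discovery"},
                index=pd.Index(donors, name="donor"),
            )
        )
        hits = 0
        root = np.random.SeedSequence(77)
        for ss in root.spawn(50):
            r = np.random.default_rng(ss)
            vals = dict(zip(donors, np.r_[r.normal(30, 5, 10), r.normal(50, 5, 10)]))
            freq = _freq_frame(vals)
            (res,) = compare_frequency_table(freq, design, [Contrast("control", "pregnant")])
            hits += res.p_two_sided < 0.05
        assert hits / 50 >= 0.9
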