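"""Concordance statistics: exact hypergeometric overlap, Venn regions,
multi-study occurrence histogram, Monte-Carlo null and its closed form."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ptoa.errors import ConfigurationError, SupportError
from ptoa.overlap import (
    GeneSet,
    harmonize_symbols,
    hypergeom_overlap,
    occurrence_expectation,
    occurrence_histogram,
    occurrence_null,
    venn_regions,
    venn_table,
)


def enumerate_overlap_pmf(k, n1, n2, U):
    """Oracle: exhaustive enumeration of all C(U, n2) second-set draws."""
    first = set(range(n1))
    hits = total = 0
    for draw in combinations(range(U), n2):
        total += 1
        hits += len(first & set(draw)) == k
    return hits / total


class TestHypergeomOverlap:
    def test_matches_exhaustive_enumeration(self):
        """p.m.f. equals brute-force enumeration for every support point, U <= 12."""
        for U in (5, 8, 12):
            for n1 in (0, 2, U // 2, U):
                for n2 in (0, 1, U // 2):
                    lo, hi = max(0, n1 + n2 - U), min(n1, n2)
                    for k in range(lo, hi + 1):
                        expected = enumerate_overlap_pmf(k, n1, n2, U)
                        got = hypergeom_overlap(k, n1, n2, U).pmf
                        assert got == pytest.approx(expected, abs=1e-12)

    def test_printed_toy_value(self):
        # 9 of the 15 possible 2-subsets of 6 elements hit the fixed 3-set once
        assert hypergeom_overlap(1, 3, 2, 6).pmf == pytest.approx(0.6, abs=1e-12)

    def test_saturated_second_set(self):
        res = hypergeom_overlap(4, 4, 10, 10)
        assert res.pmf == pytest.approx(1.0)
        assert res.p_upper == pytest.approx(1.0)

    def test_singleton_sets(self):
        assert hypergeom_overlap(1, 1, 1, 1000).pmf == pytest.approx(1 / 1000)

    @given(st.integers(2, 20_000), st.data())
    @settings(max_examples=300, deadline=None)
    def test_pmf_sums_to_one_over_support(self, U, data):
        n1 = data.draw(st.integers(0, U))
        n2 = data.draw(st.integers(0, U))
        lo, hi = max(0, n1 + n2 - U), min(n1, n2)
        total = sum(hypergeom_overlap(k, n1, n2, U).pmf for k in range(lo, min(hi, lo + 300) + 1))
        if hi - lo <= 300:
            assert total == pytest.approx(1.0, abs=1e-12)
        else:
            assert total <= 1.0 + 1e-12

    def test_upper_tail_dominates_pmf(self):
        res = hypergeom_overlap(3, 10, 12, 40)
        assert res.p_upper >= res.pmf

    def test_support_violation_raises(self):
        with pytest.raises(SupportError, match=r"support"):
            hypergeom_overlap(5, 3, 2, 100)
        with pytest.raises(ConfigurationError):
            hypergeom_overlap(1, 200, 2, 100)


class TestHarmonize:
    def test_uppercases_symbols(self):
        (out,) = harmonize_symbols([GeneSet("s", frozenset({"Fmod", "Tnn"}))])
        assert out.symbols == {"FMOD", "TNN"}

    def test_ortholog_translation(self):
        (out,) = harmonize_symbols([GeneSet("s", frozenset({"Fn1"}))], {"Fn1": "FN1"})
        assert out.symbols == {"FN1"}

    def test_many_to_one_collapses(self):
        (out,) = harmonize_symbols([GeneSet("s", frozenset({"A", "b"}))], {"A": "X", "B": "X"})
        assert out.symbols == {"X"}

    def test_unmapped_kept_uppercased(self):
        (out,) = harmonize_symbols([GeneSet("s", frozenset({"Jag1", "Kera"}))], {"Jag1": "JAG1"})
        assert out.symbols == {"JAG1", "KERA"}


class TestVennRegions:
    def test_two_set_example(self):
        regions = venn_regions([
            GeneSet("A", frozenset({"x", "y"})),
            GeneSet("B", frozenset({"y", "z"})),
        ])
        assert regions[("A",)] == {"x"}
        assert regions[("B",)] == {"z"}
        assert regions[("A", "B")] == {"y"}

    def test_identical_sets_concentrate_in_full_intersection(self):
        s = frozenset({"a", "b", "c"})
        regions = venn_regions([GeneSet("A", s), GeneSet("B", s)])
        assert regions[("A", "B")] == s
        assert not regions[("A",)] and not regions[("B",)]

    def test_region_counts_sum_to_union(self):
        rng = np.random.default_rng(0)
        universe = [f"g{i}" for i in range(40)]
        sets = [
            GeneSet(f"S{i}", frozenset(rng.choice(universe, size=15, replace=False)))
            for i in range(4)
        ]
        regions = venn_regions(sets)
        union = frozenset().union(*[s.symbols for s in sets])
        assert sum(len(m) for m in regions.values()) == len(union)
        assert len(regions) == 2**4 - 1

    @given(st.permutations([0, 1, 2]))
    @settings(deadline=None)
    def test_permutation_invariance(self, perm):
        """Region contents do not depend on input order, only labels permute."""
        rng = np.random.default_rng(42)
        universe = [f"g{i}" for i in range(30)]
        sets = [GeneSet(f"S{i}", frozenset(rng.choice(universe, 12, replace=False))) for i in range(3)]
        base = venn_regions(sets)
        permuted = venn_regions([sets[i] for i in perm])
        assert {frozenset(k): v for k, v in base.items()} == {
            frozenset(k): v for k, v in permuted.items()
        }

    def test_unsupported_arity(self):
        one = [GeneSet("A", frozenset({"x"}))]
        with pytest.raises(ValueError, match="2-4"):
            venn_regions(one)
        with pytest.raises(ValueError, match="2-4"):
            venn_regions([GeneSet(f"S{i}", frozenset({"x"})) for i in range(5)])

    def test_table_counts(self):
        regions = venn_regions([
            GeneSet("A", frozenset({"x", "y"})),
            GeneSet("B", frozenset({"y", "z"})),
        ])
        table = venn_table(regions)
        assert table["count"].sum() == 3


class TestOccurrenceHistogram:
    def test_toy_example(self):
        prof = occurrence_histogram([
            GeneSet("s1", frozenset({"a", "b"})),
            GeneSet("s2", frozenset({"b", "c"})),
            GeneSet("s3", frozenset({"b"})),
        ])
        assert prof.observed[1] == 2  # a, c
        assert prof.observed[3] == 1  # b
        assert prof.members[3] == {"b"}
        assert prof.observed_ge[2] == 1

    def test_single_set(self):
        prof = occurrence_histogram([GeneSet("s", frozenset({"a", "b", "c"}))])
        assert prof.observed[1] == 3

    def test_union_bookkeeping_and_level_zero(self):
        sets = [GeneSet("s1", frozenset({"a", "b"})), GeneSet("s2", frozenset({"b", "c"}))]
        prof = occurrence_histogram(sets, U=10)
        assert prof.observed[1:].sum() == 3  # |union|
        assert prof.observed[0] == 7


class TestOccurrenceNull:
    def test_saturated_sizes(self):
        prof = occurrence_null((10, 10, 10), U=10, n_sims=5, seed=0)
        assert prof.expected[3] == pytest.approx(10.0)
        assert prof.expected[:3].sum() == pytest.approx(0.0)

    def test_two_half_sets_match_closed_form(self):
        """sizes (5,5), U=10: both-membership probability 0.25 -> expected[2]=2.5."""
        prof = occurrence_null((5, 5), U=10, n_sims=4000, seed=1)
        se = prof.sim_sd[2] / np.sqrt(prof.n_sims)
        assert abs(prof.expected[2] - 2.5) <= 3 * se

    @pytest.mark.parametrize("sizes,U", [
        ((5, 5), 10),
        ((30, 50, 70), 100),
        ((1224, 200, 300, 400, 500, 600, 700, 800, 900), 10_000),
    ])
    def test_agrees_with_poisson_binomial(self, sizes, U):
        n_sims = 2000
        prof = occurrence_null(sizes, U, n_sims=n_sims, seed=3)
        closed = occurrence_expectation(sizes, U)
        for j in range(len(sizes) + 1):
            # rare levels may never occur in simulation (estimated SD 0);
            # floor the SE with the Poisson approximation sqrt(mu/n)
            se = max(prof.sim_sd[j], np.sqrt(closed[j])) / np.sqrt(n_sims)
            assert abs(prof.expected[j] - closed[j]) <= 4 * se + 1e-9

    def test_bookkeeping_identities(self):
        sizes, U = (30, 50, 70), 100
        prof = occurrence_null(sizes, U, n_sims=500, seed=9)
        # each study contributes exactly n_i occurrences in every replicate
        levels = np.arange(len(sizes) + 1)
        assert (levels * prof.expected).sum() == pytest.approx(sum(sizes), abs=1e-9)
        assert prof.expected.sum() == pytest.approx(U, abs=1e-9)

    def test_seeded_reproducibility(self):
        a = occurrence_null((5, 8), 20, n_sims=200, seed=5)
        b = occurrence_null((5, 8), 20, n_sims=200, seed=5)
        c = occurrence_null((5, 8), 20, n_sims=200, seed=6)
        np.testing.assert_array_equal(a.expected, b.expected)
        assert not np.array_equal(a.expected, c.expected)

    def test_size_exceeding_pool_rejected(self):
        with pytest.raises(ConfigurationError):
            occurrence_null((11,), U=10, n_sims=10, seed=0)


class TestOccurrenceExpectation:
    def test_two_half_sets(self):
        # (0.5 + 0.5 x)^2 expanded and scaled by U = 10
        np.testing.assert_allclose(occurrence_expectation((5, 5), 10), [2.5, 5.0, 2.5])

    def test_single_study(self):
        np.testing.assert_allclose(occurrence_expectation((4,), 10), [6.0, 4.0])

    def test_all_empty(self):
        np.testing.assert_allclose(occurrence_expectation((0, 0), 7), [7.0, 0.0, 0.0])

    @given(st.integers(10, 200), st.lists(st.integers(0, 10), min_size=1, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_identities_hold_generally(self, U, fracs):
        sizes = [min(f * U // 10, U) for f in fracs]
        e = occurrence_expectation(sizes, U)
        assert e.sum() == pytest.approx(U, abs=1e-9)
        assert (np.arange(len(sizes) + 1) * e).sum() == pytest.approx(sum(sizes), abs=1e-9)
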