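"""Fisher overlap test, BH adjustment, interference and segment overlap."""

import itertools
from fractions import Fraction
from math import comb

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netpharm.mcode import ProcessSegment
from netpharm.signature_io import GeneId
from netpharm.stats import (
    bh_adjust,
    fisher_overrepresentation,
    interfere,
    segment_overlap_map,
)

from conftest import gid, gset, sig


def enumeration_tail(a: int, b: int, c: int, d: int) -> Fraction:
    """Independent oracle: enumerate every draw of the |D|-margin from the
    universe and count draws with >= a successes."""
    n_total = a + b + c + d
    successes = set(range(a + c))  # drug-set margin as the 'success' labels
    n_draw = a + b
    hits = 0
    total = 0
    for draw in itertools.combinations(range(n_total), n_draw):
        total += 1
        if len(successes.intersection(draw)) >= a:
            hits += 1
    return Fraction(hits, total)


def hypergeom_tail_fraction(a, b, c, d) -> Fraction:
    """Closed-form rational tail, independent of the implementation path."""
    n_total, k_m, n_m = a + b + c + d, a + b, a + c
    tail = sum(
        comb(k_m, k) * comb(n_total - k_m, n_m - k)
        for k in range(a, min(k_m, n_m) + 1)
    )
    return Fraction(tail, comb(n_total, n_m))


class TestFisherOverrepresentation:
    def test_zero_overlap_has_p_one(self):
        assert fisher_overrepresentation(0, 5, 5, 10) == 1.0

    def test_3223_table_matches_draw_enumeration(self):
        expected = enumeration_tail(3, 2, 2, 3)
        assert fisher_overrepresentation(3, 2, 2, 3) == pytest.approx(float(expected))

    def test_maximal_overlap_is_the_extreme_point_mass(self):
        # a = min margins: the most extreme attainable table
        expected = enumeration_tail(4, 0, 2, 6)
        assert fisher_overrepresentation(4, 0, 2, 6) == pytest.approx(float(expected))

    def test_exact_and_large_sample_paths_agree(self):
        # straddle the exact-summation cutoff with the same margins scaled
        small = fisher_overrepresentation(8, 42, 42, 208)  # N=300, exact path
        large = fisher_overrepresentation(8, 42, 42, 209)  # N=301, scipy path
        assert small == pytest.approx(hypergeom_tail_fraction(8, 42, 42, 208))
        assert large == pytest.approx(hypergeom_tail_fraction(8, 42, 42, 209))

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            fisher_overrepresentation(-1, 1, 1, 1)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_overrepresentation(0, 0, 0, 0)


def hand_bh(pvalues):
    """Step-up rule applied literally: q_(i) = min_{j>=i} p_(j) * m / j."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, pvalues[i] * m / rank)
        adjusted[i] = min(1.0, running_min)
    return adjusted


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == [0.03]

    def test_hand_applied_step_up_rule(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_fixed_vector_against_hand_rule(self):
        p = [0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205, 0.212, 0.216]
        assert bh_adjust(p) == pytest.approx(hand_bh(p))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_output_dominates_input_and_preserves_ranks(self, p):
        q = bh_adjust(p)
        assert all(qi >= pi for qi, pi in zip(q, p))
        for i, j in itertools.combinations(range(len(p)), 2):
            if p[i] < p[j]:
                assert q[i] <= q[j] + 1e-12

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.permutations(list(range(8))))
    def test_invariant_under_permutation(self, perm):
        p = [0.005, 0.009, 0.04, 0.05, 0.2, 0.5, 0.8, 0.99]
        shuffled = [p[i] for i in perm]
        q_ref = bh_adjust(p)
        q_perm = bh_adjust(shuffled)
        assert [q_perm[perm.index(i)] for i in range(len(p))] == pytest.approx(q_ref)

    def test_out_of_range_value_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.2])

    def test_empty_input(self):
        assert bh_adjust([]) == []


class TestInterfere:
    def test_identical_sets_spanning_universe_give_p_one(self):
        uni = gset(*range(1, 11))
        res = interfere(sig("d", *range(1, 11)), sig("g", *range(1, 11)), uni)
        assert res.table == (10, 0, 0, 0)
        assert res.p_raw == 1.0

    def test_disjoint_sets_give_p_one(self):
        uni = gset(*range(1, 101))
        res = interfere(sig("d", *range(1, 6)), sig("g", *range(6, 11)), uni)
        assert res.table[0] == 0 and res.p_raw == 1.0

    def test_shared_ten_of_twenty_matches_rational_tail(self):
        uni = gset(*range(1, 101))
        d = sig("d", *range(1, 21))
        g = sig("g", *range(11, 31))  # shares 11..20
        res = interfere(d, g, uni)
        assert res.table == (10, 10, 10, 70)
        assert res.p_raw == pytest.approx(float(hypergeom_tail_fraction(10, 10, 10, 70)))
        assert res.significant

    def test_symmetric_in_d_and_g_with_equal_sizes(self):
        uni = gset(*range(1, 61))
        d = sig("d", *range(1, 16))
        g = sig("g", *range(10, 25))
        assert interfere(d, g, uni).p_raw == pytest.approx(interfere(g, d, uni).p_raw)

    def test_genes_outside_universe_dropped_with_warning(self):
        uni = gset(*range(1, 21))
        with pytest.warns(UserWarning, match="outside the universe"):
            res = interfere(sig("d", 1, 2, 99), sig("g", 2, 3), uni)
        assert sum(res.table) == 20

    def test_empty_universe_is_error(self):
        with pytest.raises(ValueError):
            interfere(sig("d", 1), sig("g", 1), set())


class TestSegmentOverlapMap:
    # Entrez IDs of the matrix-remodeling cluster genes
    COL1A1, MMP1, MMP2, MMP9, MMP13 = 1277, 4312, 4313, 4318, 4322

    def test_named_cluster_fixture_ordering_and_totals(self):
        ecm = {self.COL1A1, self.MMP1, self.MMP2, self.MMP9, self.MMP13}
        s1 = ProcessSegment(1, gset(*ecm, 9001), gid(self.COL1A1), 5.0)
        s2 = ProcessSegment(2, gset(7001, 7002, 7003), gid(7001), 3.0)
        drug = sig("drug", *ecm, 8801, 8802)
        report = segment_overlap_map([s2, s1], drug)
        assert [o.segment_id for o in report.overlaps] == [1, 2]
        assert [o.n_shared for o in report.overlaps] == [5, 0]
        assert report.total_shared == 5 and report.max_shared == 5

    def test_empty_drug_set(self):
        s1 = ProcessSegment(1, gset(1, 2), gid(1), 2.0)
        report = segment_overlap_map([s1], sig("drug"))
        assert report.total_shared == 0 and report.max_shared == 0

    def test_drug_superset_shares_whole_segments(self):
        s1 = ProcessSegment(1, gset(1, 2, 3), gid(1), 3.0)
        s2 = ProcessSegment(2, gset(4, 5), gid(4), 2.0)
        report = segment_overlap_map([s1, s2], sig("drug", *range(1, 10)))
        assert [o.n_shared for o in report.overlaps] == [3, 2]
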