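"""Window occurrence counting, random-ligation expectation, Fisher test."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import fisher_greater_exact

from crosslink_chimera.annotation_io import WindowIndex
from crosslink_chimera.chimera_caller import ReadCall
from crosslink_chimera.interaction_stats import (
    aggregate_to_transcripts,
    call_significant_pairs,
    count_occurrences,
    count_pair_support,
    evaluate_pairs,
    expected_frequency,
    fisher_pair_test,
    pair_table,
)
from crosslink_chimera.mapper import ExactHit


def single(rid, gs, ge, gene="g1", biotype="tRNA"):
    return ReadCall(read_id=rid, category="single_continuous",
                    part_a=ExactHit(0, ge - gs, gs, ge, "+"),
                    gene_a=gene, gene_b=gene, biotype_a=biotype, biotype_b=biotype)


def chimera(rid, a_iv, b_iv, genes=("g1", "g2"), biotypes=("tRNA", "rRNA"),
            category="chimera_inter"):
    la, lb = a_iv[1] - a_iv[0], b_iv[1] - b_iv[0]
    return ReadCall(read_id=rid, category=category,
                    part_a=ExactHit(0, la, *a_iv, "+"),
                    part_b=ExactHit(la, la + lb, *b_iv, "+"),
                    junction_offset=0,
                    gene_a=genes[0], gene_b=genes[1],
                    biotype_a=biotypes[0], biotype_b=biotypes[1])


IDX = WindowIndex(window_size=100, genome_length=2000)


class TestCountOccurrences:
    def test_token_totals(self):
        calls = [single(f"s{i}", 10, 50) for i in range(5)]
        calls += [chimera(f"c{i}", (210, 250), (710, 750)) for i in range(3)]
        occ = count_occurrences(calls, IDX)
        assert occ.T1 == 5 + 2 * 3 == 11
        assert occ.C == 3
        assert occ.T1 == sum(occ.N.values())

    def test_midpoint_window_rule(self):
        # part spanning [90, 130): midpoint 110 -> window 1
        calls = [chimera("c", (90, 130), (700, 740))]
        occ = count_occurrences(calls, IDX)
        assert occ.N == {1: 1, 7: 1}

    def test_empty_input_refused_by_stats(self):
        occ = count_occurrences([], IDX)
        assert occ.T1 == 0
        with pytest.raises(ValueError):
            evaluate_pairs({}, occ)

    def test_discards_do_not_count(self):
        calls = [single("s", 10, 50),
                 ReadCall(read_id="d", category="discard_unmapped")]
        assert count_occurrences(calls, IDX).T1 == 1


class TestExpectedFrequency:
    def test_printed_formula(self):
        assert expected_frequency(5, 10, 100) == pytest.approx(2 * (5 / 100) * (10 / 99))

    def test_zero_count_gives_zero(self):
        assert expected_frequency(0, 10, 100) == 0.0

    def test_symmetry(self):
        assert expected_frequency(7, 3, 50) == expected_frequency(3, 7, 50)

    def test_t1_too_small_rejected(self):
        with pytest.raises(ValueError):
            expected_frequency(1, 1, 1)

    def test_total_probability_is_one(self):
        """Summed over all unordered pairs plus self pairs, the expectation
        is exactly 1 (two draws without replacement from the token pool)."""
        rng = np.random.default_rng(0)
        N = rng.integers(1, 30, 12)
        t1 = int(N.sum())
        total = sum(expected_frequency(int(N[i]), int(N[j]), t1)
                    for i in range(12) for j in range(i + 1, 12))
        total += sum(expected_frequency(int(N[i]), int(N[i]), t1, same_window=True)
                     for i in range(12))
        assert total == pytest.approx(1.0)

    def test_matches_monte_carlo_pair_draws(self):
        """Empirical pair frequencies from the token-pool null match the
        formula within 3 Monte-Carlo standard errors."""
        rng = np.random.default_rng(42)
        N = np.array([5, 40, 15, 25, 10])
        tokens = np.repeat(np.arange(5), N)
        t1 = tokens.size
        n = 100_000
        i = rng.integers(0, t1, n)
        j = rng.integers(0, t1 - 1, n)
        j = j + (j >= i)
        counts = {}
        for wi, wj in zip(tokens[i], tokens[j]):
            key = (min(wi, wj), max(wi, wj))
            counts[key] = counts.get(key, 0) + 1
        for x in range(5):
            for y in range(x, 5):
                fe = expected_frequency(int(N[x]), int(N[y]), t1, same_window=(x == y))
                se = math.sqrt(fe * (1 - fe) / n)
                assert abs(counts.get((x, y), 0) / n - fe) <= 3 * se + 1e-12


class TestFisher:
    def test_matches_enumeration_oracle_exactly(self):
        for table in [(12, 8, 10, 170), (1, 0, 0, 1), (5, 5, 5, 5), (0, 3, 7, 20)]:
            assert fisher_pair_test(*table) == pytest.approx(
                fisher_greater_exact(*table), abs=1e-12)

    def test_zero_joint_count_p_is_one(self):
        assert fisher_pair_test(0, 10, 10, 100) == pytest.approx(1.0)

    def test_enrichment_monotonicity(self):
        """Moving mass onto the diagonal at fixed margins strictly decreases p."""
        p1 = fisher_pair_test(10, 10, 10, 10)
        p2 = fisher_pair_test(12, 8, 8, 12)
        p3 = fisher_pair_test(14, 6, 6, 14)
        assert p3 < p2 < p1

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_pair_test(5, -1, 3, 10)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_random_tables_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = (int(x) for x in rng.integers(0, 60, 4))
        assert fisher_pair_test(a, b, c, d) == pytest.approx(
            fisher_greater_exact(a, b, c, d), abs=1e-12)


class TestSignificanceFilter:
    def _occ(self, pair_counts, n_extra_tokens=0):
        N = {}
        C = sum(pair_counts.values())
        for (x, y), n in pair_counts.items():
            N[x] = N.get(x, 0) + n
            N[y] = N.get(y, 0) + n
        if n_extra_tokens:
            N[999] = n_extra_tokens
        from crosslink_chimera.interaction_stats import WindowOccurrenceCounts
        return WindowOccurrenceCounts(N=N, T1=sum(N.values()), C=C)

    def test_support_below_ten_not_tested(self):
        pc = {(0, 1): 9, (2, 3): 200}
        res = {(r.x, r.y): r for r in evaluate_pairs(pc, self._occ(pc))}
        assert not res[(0, 1)].tested and res[(0, 1)].p is None

    def test_low_ratio_excluded(self):
        # one dominant pair: its own ratio is ~1 (it IS the background)
        pc = {(0, 1): 500}
        (r,) = evaluate_pairs(pc, self._occ(pc))
        assert r.ratio <= 2 and not r.significant

    def test_enriched_pair_is_significant(self):
        pc = {(0, 1): 30}
        pc.update({(i, i + 1): 12 for i in range(2, 40, 2)})
        res = {(r.x, r.y): r for r in evaluate_pairs(pc, self._occ(pc, n_extra_tokens=400))}
        assert res[(0, 1)].significant
        assert res[(0, 1)].p < 0.01 and res[(0, 1)].ratio > 2

    def test_observed_frequencies_sum_to_one(self):
        pc = {(0, 1): 5, (2, 2): 7, (1, 3): 8}
        occ = self._occ(pc)
        res = evaluate_pairs(pc, occ, min_support=1)
        assert sum(r.f_obs for r in res) == pytest.approx(1.0)

    def test_pair_table_consistency(self):
        pc = {(0, 1): 5, (0, 2): 3, (1, 2): 2, (3, 3): 4}
        C = sum(pc.values())
        for pair in pc:
            a, b, c, d = pair_table(pair, pc, C)
            assert a + b + c + d == C if pair[0] != pair[1] else True
            assert min(a, b, c, d) >= 0


class TestAggregation:
    def test_window_pairs_group_by_gene_pair(self):
        calls = [chimera(f"c{i}", (110, 150), (710, 750)) for i in range(12)]
        calls += [chimera(f"d{i}", (130, 170), (810, 850)) for i in range(12)]
        occ = count_occurrences(calls, IDX)
        pc = count_pair_support(calls, IDX)
        res = evaluate_pairs(pc, occ, min_support=1, min_ratio=0.0, alpha=1.01)
        sig = call_significant_pairs(res)
        out = aggregate_to_transcripts(sig, calls, IDX)
        assert len(out) == 1  # both window pairs belong to (g1, g2)
        assert out[0].n_reads == 24
        assert len(out[0].window_pairs) == 2
        assert out[0].class_pair == "rRNA - tRNA"

    def test_homodimer_self_pair_class(self):
        calls = [chimera(f"h{i}", (710, 750), (720, 760), genes=("rrsG", "rrsG"),
                         biotypes=("rRNA", "rRNA"), category="chimera_homodimer")
                 for i in range(11)]
        occ = count_occurrences(calls, IDX)
        pc = count_pair_support(calls, IDX)
        assert list(pc) == [(7, 7)]
        res = evaluate_pairs(pc, occ, min_support=1, min_ratio=0.0, alpha=1.01)
        out = aggregate_to_transcripts(call_significant_pairs(res), calls, IDX)
        assert out[0].gene_a == out[0].gene_b == "rrsG"
        assert out[0].class_pair == "rRNA - rRNA"
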