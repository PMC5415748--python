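"""Helix search, cross-link-site scanning, and constrained energy minimisation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_dna
from oracles import brute_force_helices, min_energy_by_enumeration

from crosslink_chimera.annotation_io import Genome
from crosslink_chimera.duplex_finder import (
    NoValidConstraintError,
    find_helices,
    find_self_helices,
    normalized_mfe,
    random_chimera_sample,
    scan_amt_sites,
    select_min_energy_structure,
)
from crosslink_chimera.fold import InternalEvaluator, ViennaRNAEvaluator, structure_energy


def helix_tuples(helices):
    return {(h.a_start, h.a_end, h.b_start, h.b_end) for h in helices}


class TestFindHelices:
    def test_perfect_complement(self):
        (h,) = find_helices("GGGGAA", "UUCCCC", min_len=6)
        assert (h.a_start, h.a_end, h.b_start, h.b_end) == (0, 6, 0, 6)
        assert h.pair_classes == ("WC",) * 6

    def test_gu_wobble_helix(self):
        (h,) = find_helices("GGGGG", "UUUUU", min_len=5, allow_gu=True)
        assert h.length == 5
        assert h.pair_classes == ("GU",) * 5
        assert find_helices("GGGGG", "UUUUU", min_len=5, allow_gu=False) == []

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1),
           st.sampled_from([4, 5, 8]))
    def test_agrees_with_brute_force(self, seed, min_len):
        rng = np.random.default_rng(seed)
        a, b = random_dna(rng, 60), random_dna(rng, 60)
        assert helix_tuples(find_helices(a, b, min_len=min_len)) == \
            brute_force_helices(a, b, min_len)


class TestAmtSites:
    def test_ur_site_on_a_strand(self):
        # A: GGUA pairs B: UACC; A strand carries 5'-UA (U then purine)
        (h,) = find_helices("GGUA", "UACC", min_len=4)
        h = scan_amt_sites(h, "GGUA", "UACC")
        assert ("A", 2) in h.amt_sites

    def test_ru_site(self):
        # strand containing G then U (5'-RU)
        (h,) = find_helices("AGUC", "GACU", min_len=4)
        h = scan_amt_sites(h, "AGUC", "GACU")
        assert any(strand == "A" and pos == 2 for strand, pos in h.amt_sites)

    def test_u_free_helix_has_no_sites(self):
        (h,) = find_helices("GGCGC", "GCGCC", min_len=5)
        h = scan_amt_sites(h, "GGCGC", "GCGCC")
        assert h.amt_sites == ()


class TestSelectMinEnergy:
    def test_single_helix_is_forced(self):
        seq_a, seq_b = "AAGUGGGAA", "AACCCACAA"
        helices = [scan_amt_sites(h, seq_a, seq_b)
                   for h in find_helices(seq_a, seq_b, min_len=5)]
        model = select_min_energy_structure((seq_a, seq_b), helices)
        forced = set()
        for h in model.helices:
            forced |= set(h.forced_pairs(len(seq_a) + 4))
        assert forced <= set(model.fold.pairs)

    def test_exclusive_helices_best_single_wins(self):
        """Two mutually exclusive helices (same arm, two partner sites): the
        model equals the better of the two individually constrained solutions."""
        ev = InternalEvaluator()
        seq_a = "AGGUGGA"
        seq_b = "CCACCAAACCACC"  # two alternative partner arms for GGUGG
        helices = [scan_amt_sites(h, seq_a, seq_b)
                   for h in find_helices(seq_a, seq_b, min_len=5)]
        helices = [h for h in helices if h.amt_sites]
        assert len(helices) >= 2
        model = select_min_energy_structure((seq_a, seq_b), helices, ev)
        singles = []
        for h in helices:
            try:
                singles.append(select_min_energy_structure((seq_a, seq_b), [h], ev).energy)
            except NoValidConstraintError:
                pass
        assert model.energy == pytest.approx(min(singles))

    def test_no_amt_helix_raises(self):
        seq_a, seq_b = "GGCGC", "GCGCC"
        helices = [scan_amt_sites(h, seq_a, seq_b)
                   for h in find_helices(seq_a, seq_b, min_len=5)]
        with pytest.raises(NoValidConstraintError):
            select_min_energy_structure((seq_a, seq_b), helices)

    def test_hairpin_reference_energy(self):
        ev = InternalEvaluator()
        r = ev.fold("GGGAAAACCC")
        assert r.energy == -9.0
        assert r.pairs == ((0, 9), (1, 8), (2, 7))


class TestEnergyOracle:
    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1),
           st.integers(min_value=8, max_value=18))
    def test_dp_matches_enumeration(self, seed, n):
        """The DP minimum equals exhaustive enumeration over all structures."""
        seq = random_dna(np.random.default_rng(seed), n).replace("T", "U")
        ev = InternalEvaluator()
        r = ev.fold(seq)
        assert r.energy == pytest.approx(min_energy_by_enumeration(seq))
        assert structure_energy(seq, r.pairs) == pytest.approx(r.energy)


class TestNormalizedMfe:
    def test_arithmetic(self):
        class Fixed:
            min_loop = 3

            def fold(self, seq, forced_pairs=(), unpairable=()):
                from crosslink_chimera.fold import FoldResult
                return FoldResult(energy=-21.0, pairs=(), structure="." * len(seq))

        assert normalized_mfe("A" * 70, Fixed()) == pytest.approx(-0.3)

    def test_homopolymer_is_zero(self):
        assert normalized_mfe("A" * 40) == 0.0

    def test_planted_duplex_reads_fold_lower_than_shuffled(self):
        """Reads built around a perfect internal duplex have lower normalized
        minimum folding energy than their shuffled controls (one-sided t-test)."""
        from scipy import stats

        rng = np.random.default_rng(123)
        ev = InternalEvaluator()
        planted, shuffled = [], []
        for _ in range(200):
            stem = random_dna(rng, 12)
            from crosslink_chimera.annotation_io import reverse_complement
            read = (random_dna(rng, 10) + stem + random_dna(rng, 6)
                    + reverse_complement(stem) + random_dna(rng, 10))
            planted.append(normalized_mfe(read, ev))
            ctrl = list(read)
            rng.shuffle(ctrl)
            shuffled.append(normalized_mfe("".join(ctrl), ev))
        t, p = stats.ttest_ind(planted, shuffled, alternative="less")
        assert p < 0.01


class TestRandomChimeraSample:
    def test_deterministic_and_length_bounded(self):
        genome = Genome(id="g", sequence=random_dna(np.random.default_rng(1), 5000))
        s1 = random_chimera_sample(genome, n=200, seed=7)
        s2 = random_chimera_sample(genome, n=200, seed=7)
        assert s1 == s2
        assert all(40 <= len(s) <= 100 for s in s1)

    def test_single_fragment_sequences_are_genomic(self):
        genome = Genome(id="g", sequence=random_dna(np.random.default_rng(2), 5000))
        sample = random_chimera_sample(genome, n=50, frag_count_range=(1, 1), seed=3)
        g_rna = genome.sequence.replace("T", "U")
        assert all(s in g_rna for s in sample)


class TestSelfHelices:
    def test_hairpin_stem_found(self):
        helices = find_self_helices("GCUAGCAAAAGCUAGC", min_len=4)
        assert helices  # palindromic arms pair
        for h in helices:
            assert h.a_end <= h.b_start  # intervals ordered and disjoint

    def test_min_loop_respected(self):
        # arms adjacent with a 2 nt gap cannot form a stem (loop >= 3)
        assert find_self_helices("GGGGGAACCCCC", min_len=5) == []


class TestViennaAdapter:
    def test_rnafold_smoke(self):
        try:
            ev = ViennaRNAEvaluator()
        except RuntimeError:
            pytest.skip("RNAfold executable not available")
        r = ev.fold("GGGCCCAAAGGGCCC")
        assert r.energy <= 0.0
        assert len(r.structure) == 15
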