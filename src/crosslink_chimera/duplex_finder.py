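"""Helix search between RNA fragments, psoralen cross-link site scanning,
and constrained minimum-energy duplex selection.

A helical region is a maximal stretch of antiparallel base pairing
(Watson-Crick plus G·U wobble) between two fragments, or between two
non-overlapping regions of one read.  Psoralen (AMT) cross-links uridines
inside helices, so a helix only supports a cross-linked duplex when it
contains a 5'-UR or 5'-RU dinucleotide on either strand; helices carrying
such a site are used as forced-pair constraints for the energy model, and
the lowest-energy constrained structure is reported as the duplex frozen by
the cross-linker.

For dimeric (two-fragment) structures the fragments are joined through an
explicit run of unpairable linker positions rather than plain
concatenation, so no spurious junction-spanning pairs can form and the
minimum-loop rule never bridges the two molecules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np

from crosslink_chimera.fold import FoldResult, InternalEvaluator, can_pair, to_rna

PURINES = frozenset("AG")


class NoValidConstraintError(ValueError):
    """No candidate helix carries a cross-linking site."""


@dataclass(frozen=True)
class HelixMatch:
    """A maximal antiparallel complementary stretch between two fragments.

    ``a_start:a_end`` on fragment A pairs, in reverse, with
    ``b_start:b_end`` on fragment B: position ``a_start + k`` pairs
    ``b_end - 1 - k``.  ``pair_classes`` holds "WC" or "GU" per position
    (along A); ``amt_sites`` lists ``(strand, position-of-U)`` for every
    5'-UR / 5'-RU dinucleotide found inside the helix.
    """

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    pair_classes: tuple[str, ...]
    amt_sites: tuple[tuple[str, int], ...] = ()

    @property
    def length(self) -> int:
        return self.a_end - self.a_start

    def forced_pairs(self, b_offset: int) -> tuple[tuple[int, int], ...]:
        """Pairs in joint coordinates where fragment B starts at ``b_offset``."""
        return tuple(
            (self.a_start + k, b_offset + self.b_end - 1 - k) for k in range(self.length)
        )


@dataclass
class DuplexModel:
    """Chosen constraint helices plus the selected minimum-energy structure."""

    helices: tuple[HelixMatch, ...]
    fold: FoldResult
    structure: str  # dot-bracket; '&' separates fragments in dimers
    energy: float


def find_helices(seq_a: str, seq_b: str, min_len: int = 5, allow_gu: bool = True) -> list[HelixMatch]:
    """All maximal antiparallel complementary stretches of length >= ``min_len``.

    Exhaustive over every substring pair of the two (RNA or DNA) sequences.
    """
    a = to_rna(seq_a)
    b = to_rna(seq_b)
    la, lb = len(a), len(b)
    out: list[HelixMatch] = []
    for i in range(la):
        for j in range(lb - 1, -1, -1):
            if not can_pair(a[i], b[j], allow_gu):
                continue
            if i > 0 and j < lb - 1 and can_pair(a[i - 1], b[j + 1], allow_gu):
                continue  # not a run start
            t = 1
            while i + t < la and j - t >= 0 and can_pair(a[i + t], b[j - t], allow_gu):
                t += 1
            if t >= min_len:
                classes = tuple(
                    "GU" if frozenset((a[i + k], b[j - k])) == frozenset("GU") else "WC"
                    for k in range(t)
                )
                out.append(HelixMatch(i, i + t, j - t + 1, j + 1, classes))
    out.sort(key=lambda h: (h.a_start, h.b_start, -h.length))
    return out


def find_self_helices(seq: str, min_len: int = 5, min_loop: int = 3,
                      allow_gu: bool = True) -> list[HelixMatch]:
    """Maximal intramolecular stems of a single read (interval A 5' of B)."""
    s = to_rna(seq)
    n = len(s)
    out: list[HelixMatch] = []
    for i in range(n):
        for j in range(n - 1, i + min_loop, -1):
            if not can_pair(s[i], s[j], allow_gu):
                continue
            if i > 0 and j < n - 1 and can_pair(s[i - 1], s[j + 1], allow_gu):
                continue
            t = 1
            while (i + t < j - t - min_loop + 0) and can_pair(s[i + t], s[j - t], allow_gu):
                t += 1
            # re-check: innermost pair must keep the loop
            while t > 0 and (j - (t - 1)) - (i + (t - 1)) <= min_loop:
                t -= 1
            if t >= min_len:
                classes = tuple(
                    "GU" if frozenset((s[i + k], s[j - k])) == frozenset("GU") else "WC"
                    for k in range(t)
                )
                out.append(HelixMatch(i, i + t, j - t + 1, j + 1, classes))
    out.sort(key=lambda h: (h.a_start, h.b_start, -h.length))
    return out


def scan_amt_sites(helix: HelixMatch, seq_a: str, seq_b: str) -> HelixMatch:
    """Record every 5'-UR / 5'-RU dinucleotide inside the helix.

    Both strands are read 5' to 3' within the helix; every helix position is
    base-paired, so any such dinucleotide wholly inside the helix has its
    uridine in a paired position.
    """
    a = to_rna(seq_a)
    b = to_rna(seq_b)
    sites: list[tuple[str, int]] = []
    for strand, seq, start, end in (("A", a, helix.a_start, helix.a_end),
                                    ("B", b, helix.b_start, helix.b_end)):
        for p in range(start, end - 1):
            x, y = seq[p], seq[p + 1]
            if x == "U" and y in PURINES:
                sites.append((strand, p))
            elif x in PURINES and y == "U":
                sites.append((strand, p + 1))
    return replace(helix, amt_sites=tuple(sites))


def _helices_compatible(pairs_list: list[tuple[tuple[int, int], ...]]) -> bool:
    seen: set[int] = set()
    allp: list[tuple[int, int]] = []
    for pairs in pairs_list:
        for i, j in pairs:
            if i in seen or j in seen:
                return False
            seen.add(i)
            seen.add(j)
            allp.append((i, j))
    for (a, b), (c, d) in combinations(allp, 2):
        if (a < c < b) != (a < d < b):
            return False
    return True


def select_min_energy_structure(fragments, candidate_helices, evaluator=None,
                                max_combo_helices: int = 5,
                                linker_len: int | None = None) -> DuplexModel:
    """Lowest-energy structure under forced-helix constraints.

    ``fragments`` is one sequence (intramolecular fold) or a pair of
    sequences (dimer, joined by an unpairable linker).  Each candidate helix
    must already carry at least one cross-linking site.  Combinations of
    mutually compatible helices are enumerated as joint constraints (all
    non-empty subsets while the candidate count is at most
    ``max_combo_helices``, single helices beyond that — adding constraints
    can only raise the minimum, so the reported energy is unaffected); the
    globally lowest-energy solution wins, ties resolved toward more
    constrained pairs, then the lexicographically smaller dot-bracket.
    """
    if evaluator is None:
        evaluator = InternalEvaluator()
    if isinstance(fragments, str):
        fragments = (fragments,)
    helices = [h for h in candidate_helices if h.amt_sites]
    if not helices:
        raise NoValidConstraintError("no candidate helix carries a cross-linking site")
    helices.sort(key=lambda h: (-h.length, h.a_start, h.b_start))

    if len(fragments) == 1:
        seq = to_rna(fragments[0])
        b_offset = 0
        unpairable: tuple[int, ...] = ()
    else:
        la = len(fragments[0])
        linker = evaluator.min_loop + 1 if linker_len is None else linker_len
        b_offset = la + linker
        seq = to_rna(fragments[0]) + "N" * linker + to_rna(fragments[1])
        unpairable = tuple(range(la, la + linker))

    per_helix = [h.forced_pairs(b_offset) for h in helices]

    if len(helices) <= max_combo_helices:
        combos = [
            tuple(idx)
            for r in range(1, len(helices) + 1)
            for idx in combinations(range(len(helices)), r)
        ]
    else:
        combos = [(i,) for i in range(len(helices))]

    best: tuple[float, int, str] | None = None
    best_model: DuplexModel | None = None
    for idx in combos:
        pairs_list = [per_helix[i] for i in idx]
        if not _helices_compatible(pairs_list):
            continue
        forced = [p for pairs in pairs_list for p in pairs]
        try:
            result = evaluator.fold(seq, forced_pairs=forced, unpairable=unpairable)
        except ValueError:
            continue  # e.g. a loop-infeasible intramolecular helix
        structure = result.structure
        if len(fragments) == 2:
            la = len(fragments[0])
            structure = structure[:la] + "&" + structure[b_offset:]
        key = (round(result.energy, 9), -len(forced), structure)
        if best is None or key < best:
            best = key
            best_model = DuplexModel(
                helices=tuple(helices[i] for i in idx),
                fold=result, structure=structure, energy=result.energy,
            )
    if best_model is None:
        raise NoValidConstraintError("no helix combination yields a feasible constrained fold")
    return best_model


def normalized_mfe(seq: str, evaluator=None) -> float:
    """Unconstrained minimum folding energy divided by sequence length (kcal/mol/nt)."""
    if not seq:
        raise ValueError("empty sequence")
    if evaluator is None:
        evaluator = InternalEvaluator()
    return evaluator.fold(to_rna(seq)).energy / len(seq)


def random_chimera_sample(genome, n: int = 10000, len_range: tuple[int, int] = (40, 100),
                          frag_count_range: tuple[int, int] = (1, 2),
                          seed: int | np.random.Generator = 0) -> list[str]:
    """Random-ligation null sequences for the folding-energy comparison.

    Each sequence concatenates ``k`` fragments drawn uniformly from the
    genome (``k`` uniform in ``frag_count_range``), with total length
    uniform in ``len_range``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = len_range
    kmin, kmax = frag_count_range
    out: list[str] = []
    for _ in range(n):
        total = int(rng.integers(lo, hi + 1))
        k = int(rng.integers(kmin, kmax + 1))
        k = min(k, total)  # every fragment at least 1 nt
        if k > 1:
            cuts = sorted(rng.choice(np.arange(1, total), size=k - 1, replace=False).tolist())
        else:
            cuts = []
        bounds = [0] + cuts + [total]
        parts = []
        for a, b in zip(bounds, bounds[1:]):
            flen = b - a
            start = int(rng.integers(0, genome.length - flen + 1))
            parts.append(genome.sequence[start : start + flen])
        out.append(to_rna("".join(parts)))
    return out
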