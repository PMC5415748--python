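"""Independent brute-force oracles used to validate the implementation.

These deliberately use naive algorithms (all-substrings scans, exhaustive
enumeration, exact integer arithmetic) and share no code with the package's
own search/DP/statistics routines.
"""

from __future__ import annotations

from functools import lru_cache
from math import comb

_RC = str.maketrans("ACGTN", "TGCAN")

_PAIRS_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_PAIRS_GU = {("G", "U"), ("U", "G")}


def _revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


def brute_force_mems(read: str, genome: str, min_len: int):
    """All maximal exact matches of read vs both genome strands.

    Returns a set of (read_start, read_end, genome_start, genome_end, strand)
    with genome coordinates on the forward strand.
    """
    out = set()
    n = len(read)
    for strand, gseq in (("+", genome), ("-", _revcomp(genome))):
        m = len(gseq)
        for i in range(n):
            for g in range(m):
                if read[i] != gseq[g]:
                    continue
                if i > 0 and g > 0 and read[i - 1] == gseq[g - 1]:
                    continue  # extendable left: not maximal
                t = 0
                while i + t < n and g + t < m and read[i + t] == gseq[g + t]:
                    t += 1
                if t >= min_len:
                    if strand == "+":
                        out.add((i, i + t, g, g + t, "+"))
                    else:
                        out.add((i, i + t, m - g - t, m - g, "-"))
    return out


def _pairs_ok(a: str, b: str, allow_gu: bool) -> bool:
    return (a, b) in _PAIRS_WC or (allow_gu and (a, b) in _PAIRS_GU)


def brute_force_helices(seq_a: str, seq_b: str, min_len: int, allow_gu: bool = True):
    """All maximal antiparallel complementary stretches between two RNAs.

    Checks every (a-start, b-end, length) triple directly.  Returns a set of
    (a_start, a_end, b_start, b_end).
    """
    a = seq_a.upper().replace("T", "U")
    b = seq_b.upper().replace("T", "U")
    la, lb = len(a), len(b)
    out = set()
    for i in range(la):
        for jend in range(lb, 0, -1):
            L = 0
            while i + L < la and jend - 1 - L >= 0 and _pairs_ok(a[i + L], b[jend - 1 - L], allow_gu):
                L += 1
            if L < min_len:
                continue
            # maximality: no outer extension
            if i > 0 and jend < lb and _pairs_ok(a[i - 1], b[jend], allow_gu):
                continue
            out.add((i, i + L, jend - L, jend))
    return out


def fisher_greater_exact(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher exact p by hypergeometric-tail enumeration.

    Exact integer arithmetic; a single float division at the end.
    """
    r1, r2, c1 = a + b, c + d, a + c
    num = sum(comb(r1, k) * comb(r2, c1 - k) for k in range(a, min(r1, c1) + 1))
    return num / comb(r1 + r2, c1)


def enumerate_structures(seq: str, min_loop: int = 3, allow_gu: bool = True):
    """Every valid non-crossing secondary structure (as tuples of pairs)."""
    s = seq.upper().replace("T", "U")
    n = len(s)

    @lru_cache(maxsize=None)
    def rec(i: int, j: int):
        if i > j:
            return ((),)
        out = list(rec(i + 1, j))  # i unpaired
        for k in range(i + min_loop + 1, j + 1):
            if _pairs_ok(s[i], s[k], allow_gu) or _pairs_ok(s[k], s[i], allow_gu):
                for inner in rec(i + 1, k - 1):
                    for outer in rec(k + 1, j):
                        out.append(((i, k),) + inner + outer)
        return tuple(out)

    return rec(0, n - 1)


def structure_energy_simple(seq: str, pairs, gc: float = -3.0, au: float = -2.0,
                            gu: float = -1.0) -> float:
    s = seq.upper().replace("T", "U")
    total = 0.0
    for i, j in pairs:
        key = frozenset((s[i], s[j]))
        if key == frozenset("GC"):
            total += gc
        elif key == frozenset("AU"):
            total += au
        elif key == frozenset("GU"):
            total += gu
    return total


def min_energy_by_enumeration(seq: str, forced=(), min_loop: int = 3) -> float:
    """Minimum energy over all enumerated structures containing the forced pairs."""
    forced = set(tuple(sorted(p)) for p in forced)
    best = 0.0
    found = False
    for st in enumerate_structures(seq, min_loop=min_loop):
        if forced and not forced <= set(st):
            continue
        found = True
        e = structure_energy_simple(seq, st)
        if e < best:
            best = e
    if forced and not found:
        raise ValueError("no structure satisfies the forced pairs")
    return best
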