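"""Window-level over-representation statistics for chimeric reads.

Every single read contributes one occurrence token (at the window of its
genomic midpoint) and every chimera two (one per partner fragment); the
token total T1 is the size of the random-ligation pool.  For a window pair
(X, Y) joined by c_xy chimeras out of C total, the observed ligation
frequency c_xy / C is compared with the expected frequency of random
ligation,

    f_exp = 2 (N_x / T1) (N_y / (T1 - 1))          for X != Y,
    f_exp = N_x (N_x - 1) / (T1 (T1 - 1))          for the self pair X == X,

i.e. the probability of drawing the two windows in an unordered pair of
distinct tokens.  Pairs supported by at least ``min_support`` chimeras and
enriched more than ``min_ratio``-fold are then subjected to a one-sided
Fisher exact test on the read-level 2x2 table (chimeras joining X and Y,
chimeras touching only X, only Y, neither); pairs with p below ``alpha``
are called significant.  No multiple-testing correction is applied by
default; Benjamini-Hochberg can be enabled.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from scipy import stats

from crosslink_chimera.annotation_io import WindowIndex
from crosslink_chimera.chimera_caller import ReadCall


@dataclass
class WindowOccurrenceCounts:
    """Occurrence tokens per window; T1 = sum(N) = singles + 2 * chimeras."""

    N: dict[int, int]
    T1: int
    C: int  # number of chimeric reads


@dataclass
class PairTestResult:
    x: int
    y: int
    c_xy: int
    f_obs: float
    f_exp: float
    ratio: float
    p: float | None
    tested: bool
    significant: bool


@dataclass
class TranscriptPairCall:
    gene_a: str
    gene_b: str
    class_pair: str
    window_pairs: tuple[tuple[int, int], ...]
    n_reads: int


def _midpoint(call: ReadCall) -> int:
    if not call.is_single:
        raise ValueError("midpoint is defined for single-read calls")
    if call.category == "single_continuous" or call.part_b is None:
        a = call.part_a
        return (a.genome_start + a.genome_end) // 2
    a, b = call.part_a, call.part_b
    return (min(a.genome_start, b.genome_start) + max(a.genome_end, b.genome_end)) // 2


def chimera_windows(call: ReadCall, idx: WindowIndex) -> tuple[int, int]:
    """Unordered window pair of a chimera's two partner midpoints."""
    a, b = call.part_a, call.part_b
    wa = idx.window_of(min((a.genome_start + a.genome_end) // 2, idx.genome_length - 1))
    wb = idx.window_of(min((b.genome_start + b.genome_end) // 2, idx.genome_length - 1))
    return (wa, wb) if wa <= wb else (wb, wa)


def count_occurrences(calls: Sequence[ReadCall], idx: WindowIndex) -> WindowOccurrenceCounts:
    """Window tokens from classified reads (singles: 1 token; chimeras: 2)."""
    N: Counter[int] = Counter()
    n_chim = 0
    for call in calls:
        if call.is_single:
            N[idx.window_of(min(_midpoint(call), idx.genome_length - 1))] += 1
        elif call.is_chimera:
            wa, wb = chimera_windows(call, idx)
            N[wa] += 1
            N[wb] += 1
            n_chim += 1
    return WindowOccurrenceCounts(N=dict(N), T1=sum(N.values()), C=n_chim)


def count_pair_support(calls: Sequence[ReadCall], idx: WindowIndex) -> dict[tuple[int, int], int]:
    """Chimera count per unordered window pair."""
    pairs: Counter[tuple[int, int]] = Counter()
    for call in calls:
        if call.is_chimera:
            pairs[chimera_windows(call, idx)] += 1
    return dict(pairs)


def expected_frequency(n_x: int, n_y: int, t1: int, same_window: bool = False) -> float:
    """Random-ligation frequency of the window pair under the token-pool null."""
    if t1 < 2:
        raise ValueError("T1 must be at least 2")
    if same_window:
        return n_x * (n_x - 1) / (t1 * (t1 - 1))
    return 2.0 * n_x * n_y / (t1 * (t1 - 1))


def fisher_pair_test(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher exact p for the read-level 2x2 table.

    a = chimeras joining X and Y; b = chimeras with X but not Y;
    c = with Y but not X; d = the remaining chimeras.
    """
    if min(a, b, c, d) < 0:
        raise ValueError(f"inconsistent 2x2 table ({a}, {b}, {c}, {d})")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])


def pair_table(pair: tuple[int, int], pair_counts: dict[tuple[int, int], int],
               C: int) -> tuple[int, int, int, int]:
    """Build the 2x2 table for a window pair from per-pair chimera counts."""
    x, y = pair
    a = pair_counts.get(pair, 0)
    touch_x = sum(n for (p, q), n in pair_counts.items() if x in (p, q))
    touch_y = sum(n for (p, q), n in pair_counts.items() if y in (p, q))
    if x == y:
        b = c = touch_x - a
    else:
        b = touch_x - a
        c = touch_y - a
    d = C - a - b - c
    return a, b, c, d


def evaluate_pairs(pair_counts: dict[tuple[int, int], int], occ: WindowOccurrenceCounts,
                   min_support: int = 10, min_ratio: float = 2.0, alpha: float = 0.01,
                   bh_correct: bool = False) -> list[PairTestResult]:
    """Apply the support, ratio and Fisher filters (in that order) to all pairs."""
    if occ.T1 < 2 or occ.C == 0:
        raise ValueError("not enough classified reads for the statistics stage")
    results: list[PairTestResult] = []
    for (x, y), cnt in sorted(pair_counts.items()):
        f_obs = cnt / occ.C
        f_exp = expected_frequency(occ.N.get(x, 0), occ.N.get(y, 0), occ.T1, same_window=(x == y))
        ratio = f_obs / f_exp if f_exp > 0 else math.inf
        tested = cnt >= min_support
        p: float | None = None
        if tested and ratio > min_ratio:
            p = fisher_pair_test(*pair_table((x, y), pair_counts, occ.C))
        results.append(PairTestResult(x=x, y=y, c_xy=cnt, f_obs=f_obs, f_exp=f_exp,
                                      ratio=ratio, p=p, tested=tested, significant=False))
    if bh_correct:
        ps = [(i, r.p) for i, r in enumerate(results) if r.p is not None]
        m = len(ps)
        order = sorted(ps, key=lambda t: t[1])
        adj = {}
        running = 1.0
        for rank in range(m, 0, -1):
            i, p = order[rank - 1]
            running = min(running, p * m / rank)
            adj[i] = running
        for i, q in adj.items():
            results[i].p = q
    for r in results:
        r.significant = bool(r.p is not None and r.ratio > min_ratio
                             and r.c_xy >= min_support and r.p < alpha)
    return results


def call_significant_pairs(results: Iterable[PairTestResult]) -> list[PairTestResult]:
    return [r for r in results if r.significant]


def class_pair_label(biotype_a: str, biotype_b: str) -> str:
    return " - ".join(sorted((biotype_a, biotype_b)))


def aggregate_to_transcripts(significant: Sequence[PairTestResult],
                             calls: Sequence[ReadCall],
                             idx: WindowIndex) -> list[TranscriptPairCall]:
    """Group significant window pairs into transcript (gene) pairs.

    Each window pair is labelled with the most common gene pair among its
    supporting chimeras; window pairs sharing a gene pair merge into one
    transcript-pair call with summed read support.
    """
    by_window_pair: dict[tuple[int, int], Counter] = defaultdict(Counter)
    biotypes: dict[str, str] = {}
    for call in calls:
        if not call.is_chimera:
            continue
        wp = chimera_windows(call, idx)
        pair = call.gene_pair
        by_window_pair[wp][pair] += 1
        biotypes[call.gene_a] = call.biotype_a
        biotypes[call.gene_b] = call.biotype_b
    grouped: dict[tuple[str, str], list[tuple[tuple[int, int], int]]] = defaultdict(list)
    for r in significant:
        wp = (r.x, r.y)
        if wp not in by_window_pair:
            continue
        gene_pair = by_window_pair[wp].most_common(1)[0][0]
        grouped[gene_pair].append((wp, r.c_xy))
    out = []
    for (ga, gb), wps in sorted(grouped.items()):
        out.append(TranscriptPairCall(
            gene_a=ga, gene_b=gb,
            class_pair=class_pair_label(biotypes[ga], biotypes[gb]),
            window_pairs=tuple(wp for wp, _ in wps),
            n_reads=sum(n for _, n in wps),
        ))
    return out


def write_pair_results_tsv(results: Sequence[PairTestResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("window_x\twindow_y\tc_xy\tf_obs\tf_exp\tratio\tp\ttested\tsignificant\n")
        for r in results:
            p = "." if r.p is None else f"{r.p:.6g}"
            ratio = "inf" if math.isinf(r.ratio) else f"{r.ratio:.6g}"
            fh.write(f"{r.x}\t{r.y}\t{r.c_xy}\t{r.f_obs:.6g}\t{r.f_exp:.6g}\t"
                     f"{ratio}\t{p}\t{int(r.tested)}\t{int(r.significant)}\n")


def write_transcript_pairs_tsv(pairs: Sequence[TranscriptPairCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tclass_pair\tn_window_pairs\twindow_pairs\tn_reads\n")
        for t in pairs:
            wps = ";".join(f"{x}-{y}" for x, y in t.window_pairs)
            fh.write(f"{t.gene_a}\t{t.gene_b}\t{t.class_pair}\t{len(t.window_pairs)}\t{wps}\t{t.n_reads}\n")
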