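"""Exhaustive exact-match read mapping.

The pipeline only trusts mismatch-free, gap-free alignments, so mapping
reduces to enumerating all maximal exact matches (MEMs) of a read against
both genome strands above a minimum length.  A seed-and-extend index over
fixed-length k-mers (k = the minimum reported hit length) finds every MEM:
a maximal match of length L >= k contributes all of its L - k + 1 seeds on
one diagonal, so merging consecutive seeds per (strand, diagonal)
reconstructs the match boundaries exactly.

Pre-computed hits in BLAST tabular format (outfmt 6) can be imported
instead; only perfect-identity, gap-free rows are retained, matching the
internal mapper's contract.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from crosslink_chimera.annotation_io import Genome, reverse_complement

logger = logging.getLogger(__name__)

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True, order=True)
class ExactHit:
    """One gap-free, mismatch-free alignment of a read interval to the genome.

    Both intervals are 0-based half-open; on the minus strand the read
    substring equals the reverse complement of the genomic substring.
    """

    read_start: int
    read_end: int
    genome_start: int
    genome_end: int
    strand: str

    def __post_init__(self) -> None:
        if self.read_end - self.read_start != self.genome_end - self.genome_start:
            raise ValueError("read and genome intervals differ in length")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.read_end - self.read_start

    @property
    def read_interval(self) -> tuple[int, int]:
        return (self.read_start, self.read_end)

    @property
    def genome_interval(self) -> tuple[int, int]:
        return (self.genome_start, self.genome_end)


@dataclass
class ReadHitSet:
    read_id: str
    hits: list[ExactHit] = field(default_factory=list)
    exhaustive: bool = True


class GenomeIndex:
    """k-mer seed index over both strands of a genome."""

    def __init__(self, genome: Genome, k: int = 15):
        if k < 4:
            raise ValueError("seed length must be >= 4")
        self.genome = genome
        self.k = k
        self._fwd = genome.sequence
        self._rev = reverse_complement(genome.sequence)
        self._seeds: dict[str, list[tuple[int, int]]] = defaultdict(list)
        # strand code 0 = forward, 1 = reverse-complement coordinates
        for code, seq in ((0, self._fwd), (1, self._rev)):
            for i in range(len(seq) - k + 1):
                self._seeds[seq[i : i + k]].append((code, i))
        self._seeds = dict(self._seeds)

    def strand_sequence(self, code: int) -> str:
        return self._rev if code else self._fwd


def build_index(genome: Genome, min_hit_len: int = 15) -> GenomeIndex:
    return GenomeIndex(genome, k=min_hit_len)


def find_exact_hits(read_id: str, read_seq: str, index: GenomeIndex,
                    min_hit_len: int | None = None) -> ReadHitSet:
    """All maximal exact matches of ``read_seq`` >= ``min_hit_len`` on either strand.

    ``min_hit_len`` defaults to the index seed length and cannot be smaller
    than it (shorter matches have no seed).
    """
    k = index.k
    if min_hit_len is None:
        min_hit_len = k
    if min_hit_len < k:
        raise ValueError(f"min_hit_len {min_hit_len} below index seed length {k}")
    read_seq = read_seq.upper().replace("U", "T")
    n = len(read_seq)
    glen = index.genome.length
    # seeds grouped by (strand code, diagonal); values are read offsets
    diagonals: dict[tuple[int, int], list[int]] = defaultdict(list)
    for i in range(n - k + 1):
        for code, g in index._seeds.get(read_seq[i : i + k], ()):
            diagonals[(code, g - i)].append(i)
    hits: list[ExactHit] = []
    for (code, diag), offsets in diagonals.items():
        offsets.sort()
        run_start = prev = offsets[0]
        for i in offsets[1:] + [None]:  # type: ignore[list-item]
            if i is not None and i == prev + 1:
                prev = i
                continue
            length = prev - run_start + k
            if length >= min_hit_len:
                hits.append(_to_hit(code, run_start, diag + run_start, length, glen))
            if i is not None:
                run_start = prev = i
    hits = sorted(set(hits))
    return ReadHitSet(read_id=read_id, hits=hits, exhaustive=True)


def _to_hit(code: int, read_start: int, strand_pos: int, length: int, glen: int) -> ExactHit:
    if code == 0:
        return ExactHit(read_start, read_start + length, strand_pos, strand_pos + length, "+")
    # position on the reverse-complement sequence -> forward coordinates
    g_end = glen - strand_pos
    return ExactHit(read_start, read_start + length, g_end - length, g_end, "-")


def import_blast_tabular(path: str | Path, min_hit_len: int = 15) -> dict[str, ReadHitSet]:
    """Read BLAST outfmt-6 hits, keeping only exact (ungapped, 100% id) rows.

    BLAST coordinates are 1-based inclusive; ``sstart > send`` encodes the
    minus strand.  Malformed rows are skipped with a logged count.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=BLAST6_COLUMNS, comment="#")
    out: dict[str, ReadHitSet] = {}
    skipped = 0
    for row in df.itertuples(index=False):
        try:
            if int(row.mismatch) != 0 or int(row.gapopen) != 0 or float(row.pident) < 100.0:
                continue
            length = int(row.length)
            if length < min_hit_len:
                continue
            qs, qe = int(row.qstart) - 1, int(row.qend)
            ss, se = int(row.sstart), int(row.send)
            if ss <= se:
                hit = ExactHit(qs, qe, ss - 1, se, "+")
            else:
                hit = ExactHit(qs, qe, se - 1, ss, "-")
        except (ValueError, TypeError):
            skipped += 1
            continue
        rid = str(row.qseqid)
        out.setdefault(rid, ReadHitSet(read_id=rid, hits=[])).hits.append(hit)
    if skipped:
        logger.warning("skipped %d malformed BLAST rows in %s", skipped, path)
    for hs in out.values():
        hs.hits = sorted(set(hs.hits))
    return out


def export_blast_tabular(hit_sets: Iterable[ReadHitSet], genome_id: str, path: str | Path) -> None:
    """Write hits in the 12-column BLAST outfmt-6 dialect (exact hits only)."""
    with open(path, "w") as fh:
        for hs in hit_sets:
            for h in hs.hits:
                if h.strand == "+":
                    ss, se = h.genome_start + 1, h.genome_end
                else:
                    ss, se = h.genome_end, h.genome_start + 1
                fh.write(
                    "\t".join(map(str, [
                        hs.read_id, genome_id, "100.000", h.length, 0, 0,
                        h.read_start + 1, h.read_end, ss, se, "0.0", float(2 * h.length),
                    ])) + "\n"
                )
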