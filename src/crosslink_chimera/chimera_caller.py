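"""Read classification: single reads, chimeric reads, and discards.

A mapped read is explained by at most two exact hits that jointly cover it.
A read with a unique full-length hit is a continuous single read
(intramolecular structure); a read needing two parts is a chimera when the
parts come from different genes, a homodimer chimera when the two parts
map to overlapping coordinates of one gene (two copies of one molecule),
and a split single read when the parts are non-overlapping regions of one
gene.  The junction between the two parts may show a small gap or overlap
(default 4 nt either way) left by the ligation and by trimming.  Retained
reads must additionally contain at least one helical region carrying a
classical psoralen cross-linking site (5'-UR or 5'-RU): the duplex between
the two parts for chimeras, an intramolecular stem for single reads.
Ambiguous reads (several gene pairs or several genomic loci) and reads
needing more than two parts are discarded with an explicit reason.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from crosslink_chimera.annotation_io import GenomeAnnotation
from crosslink_chimera.duplex_finder import find_helices, find_self_helices, scan_amt_sites
from crosslink_chimera.mapper import ExactHit, ReadHitSet

CATEGORIES = (
    "single_continuous",
    "single_split",
    "chimera_inter",
    "chimera_homodimer",
    "discard_multipart",
    "discard_multimap",
    "discard_unmapped",
    "discard_no_amt_site",
)

CHIMERA_CATEGORIES = ("chimera_inter", "chimera_homodimer")
SINGLE_CATEGORIES = ("single_continuous", "single_split")


@dataclass(frozen=True)
class Decomposition:
    parts: tuple[ExactHit, ...]
    junction_offset: int | None  # positive = overlap, negative = gap

    @property
    def n_parts(self) -> int:
        return len(self.parts)


@dataclass
class ReadCall:
    read_id: str
    category: str
    part_a: ExactHit | None = None
    part_b: ExactHit | None = None
    junction_offset: int | None = None
    gene_a: str | None = None
    gene_b: str | None = None
    biotype_a: str | None = None
    biotype_b: str | None = None

    @property
    def is_chimera(self) -> bool:
        return self.category in CHIMERA_CATEGORIES

    @property
    def is_single(self) -> bool:
        return self.category in SINGLE_CATEGORIES

    @property
    def gene_pair(self) -> tuple[str, str] | None:
        if self.gene_a is None or self.gene_b is None:
            return None
        return tuple(sorted((self.gene_a, self.gene_b)))  # type: ignore[return-value]


def enumerate_decompositions(hits: ReadHitSet, read_len: int,
                             max_gap: int = 4, max_overlap: int = 4) -> list[Decomposition]:
    """Every 1-part full cover and every ordered 2-part cover of the read.

    A 2-part decomposition starts at read position 0 with part A, ends at
    ``read_len`` with part B, and has a junction offset
    ``part_a.read_end - part_b.read_start`` within ``[-max_gap, +max_overlap]``
    (negative = unmapped gap nucleotides at the junction).
    """
    out: list[Decomposition] = []
    for h in hits.hits:
        if h.read_start == 0 and h.read_end == read_len:
            out.append(Decomposition(parts=(h,), junction_offset=None))
    starts = [h for h in hits.hits if h.read_start == 0 and h.read_end < read_len]
    ends = [h for h in hits.hits if h.read_end == read_len and h.read_start > 0]
    for a in starts:
        for b in ends:
            off = a.read_end - b.read_start
            if -max_gap <= off <= max_overlap:
                out.append(Decomposition(parts=(a, b), junction_offset=off))
    out.sort(key=lambda d: (d.n_parts, d.parts))
    return out


def _genomic_overlap(a: ExactHit, b: ExactHit) -> int:
    return max(0, min(a.genome_end, b.genome_end) - max(a.genome_start, b.genome_start))


def _has_amt_duplex(seq_a: str, seq_b: str, min_helix_len: int) -> bool:
    for h in find_helices(seq_a, seq_b, min_len=min_helix_len):
        if scan_amt_sites(h, seq_a, seq_b).amt_sites:
            return True
    return False


def _has_amt_stem(seq: str, min_helix_len: int) -> bool:
    for h in find_self_helices(seq, min_len=min_helix_len):
        if scan_amt_sites(h, seq, seq).amt_sites:
            return True
    return False


def classify_read(read_id: str, read_seq: str, hits: ReadHitSet,
                  annotation: GenomeAnnotation, max_gap: int = 4, max_overlap: int = 4,
                  min_helix_len: int = 5, require_amt: bool = True) -> ReadCall:
    """Assign exactly one category to a mapped read (see module docstring)."""
    read_len = len(read_seq)
    if not hits.hits:
        return ReadCall(read_id=read_id, category="discard_unmapped")
    decomps = enumerate_decompositions(hits, read_len, max_gap=max_gap, max_overlap=max_overlap)

    ones = [d for d in decomps if d.n_parts == 1]
    if ones:
        loci = {(d.parts[0].genome_start, d.parts[0].genome_end, d.parts[0].strand) for d in ones}
        if len(loci) > 1:
            return ReadCall(read_id=read_id, category="discard_multimap")
        hit = ones[0].parts[0]
        gene = annotation.assign_gene(hit.genome_start, hit.genome_end)
        if require_amt and not _has_amt_stem(read_seq, min_helix_len):
            return ReadCall(read_id=read_id, category="discard_no_amt_site", part_a=hit,
                            gene_a=gene.name, biotype_a=gene.biotype)
        return ReadCall(read_id=read_id, category="single_continuous", part_a=hit,
                        gene_a=gene.name, gene_b=gene.name,
                        biotype_a=gene.biotype, biotype_b=gene.biotype)

    twos = [d for d in decomps if d.n_parts == 2]
    if not twos:
        return ReadCall(read_id=read_id, category="discard_multipart")

    annotated = []
    for d in twos:
        a, b = d.parts
        ga = annotation.assign_gene(a.genome_start, a.genome_end)
        gb = annotation.assign_gene(b.genome_start, b.genome_end)
        if ga.name == gb.name:
            kind = "chimera_homodimer" if _genomic_overlap(a, b) > 0 else "single_split"
        else:
            kind = "chimera_inter"
        annotated.append((d, ga, gb, kind))

    gene_pairs = {tuple(sorted((ga.name, gb.name))) for _, ga, gb, _ in annotated}
    if len(gene_pairs) > 1:
        return ReadCall(read_id=read_id, category="discard_multimap")
    kinds = {kind for *_, kind in annotated}
    if len(kinds) > 1:
        return ReadCall(read_id=read_id, category="discard_multimap")
    kind = kinds.pop()
    if kind == "single_split":
        loci = {(d.parts[0].genome_interval, d.parts[1].genome_interval) for d, *_ in annotated}
        if len(loci) > 1:
            return ReadCall(read_id=read_id, category="discard_multimap")

    # canonical decomposition: longest 5' part, then genomic order
    annotated.sort(key=lambda t: (-t[0].parts[0].length,
                                  t[0].parts[0].genome_start, t[0].parts[1].genome_start))
    d, ga, gb, _ = annotated[0]
    a, b = d.parts
    call = ReadCall(read_id=read_id, category=kind, part_a=a, part_b=b,
                    junction_offset=d.junction_offset,
                    gene_a=ga.name, gene_b=gb.name,
                    biotype_a=ga.biotype, biotype_b=gb.biotype)
    if require_amt:
        seq_a = read_seq[a.read_start:a.read_end]
        seq_b = read_seq[b.read_start:b.read_end]
        if kind == "single_split":
            ok = _has_amt_stem(read_seq, min_helix_len)
        else:
            ok = _has_amt_duplex(seq_a, seq_b, min_helix_len)
        if not ok:
            call.category = "discard_no_amt_site"
    return call


def category_counts(calls: Sequence[ReadCall]) -> dict[str, int]:
    counts = {c: 0 for c in CATEGORIES}
    for call in calls:
        counts[call.category] += 1
    return counts


_CALL_COLUMNS = [
    "read_id", "category",
    "a_read_start", "a_read_end", "a_genome_start", "a_genome_end", "a_strand",
    "b_read_start", "b_read_end", "b_genome_start", "b_genome_end", "b_strand",
    "junction_offset", "gene_a", "gene_b", "biotype_a", "biotype_b",
]


def write_calls_tsv(calls: Sequence[ReadCall], path: str | Path) -> None:
    def fmt(x):
        return "." if x is None else str(x)

    with open(path, "w") as fh:
        fh.write("\t".join(_CALL_COLUMNS) + "\n")
        for c in calls:
            row = [c.read_id, c.category]
            for part in (c.part_a, c.part_b):
                if part is None:
                    row += ["."] * 5
                else:
                    row += [str(part.read_start), str(part.read_end),
                            str(part.genome_start), str(part.genome_end), part.strand]
            row += [fmt(c.junction_offset), fmt(c.gene_a), fmt(c.gene_b),
                    fmt(c.biotype_a), fmt(c.biotype_b)]
            fh.write("\t".join(row) + "\n")


def read_calls_tsv(path: str | Path) -> list[ReadCall]:
    calls: list[ReadCall] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _CALL_COLUMNS:
            raise ValueError(f"unexpected calls header in {path}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            def hit(i):
                if f[i] == ".":
                    return None
                return ExactHit(int(f[i]), int(f[i + 1]), int(f[i + 2]), int(f[i + 3]), f[i + 4])
            calls.append(ReadCall(
                read_id=f[0], category=f[1], part_a=hit(2), part_b=hit(7),
                junction_offset=None if f[12] == "." else int(f[12]),
                gene_a=None if f[13] == "." else f[13],
                gene_b=None if f[14] == "." else f[14],
                biotype_a=None if f[15] == "." else f[15],
                biotype_b=None if f[16] == "." else f[16],
            ))
    return calls
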