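"""Genome, gene-model and window-index handling.

All coordinates inside the package are 0-based half-open on the forward
strand of a single concatenated coordinate system; conversion to/from the
1-based GFF3 dialect happens only at file boundaries.  The fixed-width
window index tiles the genome with non-overlapping windows and is the
coordinate grid of the over-representation statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: closed set of transcript classes used for interaction class labels
BIOTYPES = ("tRNA", "rRNA", "ncRNA", "mRNA", "tmRNA", "pseudo", "IGT", "repeat")

_VALID_CHARS = frozenset("ACGTN")


@dataclass(frozen=True)
class Genome:
    """A (possibly concatenated multi-record) genome sequence."""

    id: str
    sequence: str
    record_offsets: dict[str, int] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int, strand: str = "+") -> str:
        """Return the forward- or reverse-strand sequence of [start, end)."""
        if not (0 <= start <= end <= self.length):
            raise ValueError(f"interval [{start}, {end}) outside genome of length {self.length}")
        seq = self.sequence[start:end]
        return reverse_complement(seq) if strand == "-" else seq


@dataclass(frozen=True)
class GeneModel:
    """A strand-aware gene model on the concatenated genome."""

    name: str
    biotype: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def overlap(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start))


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class WindowIndex:
    """Non-overlapping fixed-width windows tiling the genome.

    ``window_of(pos) = pos // window_size``; the last window may be short.
    The default width of 100 nt is the grid at which interacting regions
    are grouped for the over-representation test.
    """

    window_size: int
    genome_length: int

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")

    @property
    def n_windows(self) -> int:
        return -(-self.genome_length // self.window_size)

    def window_of(self, pos: int) -> int:
        if not (0 <= pos < self.genome_length):
            raise ValueError(f"position {pos} outside genome of length {self.genome_length}")
        return pos // self.window_size


def window_of(pos: int, idx: WindowIndex) -> int:
    """Window id of a genomic position (functional alias)."""
    return idx.window_of(pos)


def load_genome(path: str | Path) -> Genome:
    """Load a FASTA genome, concatenating multiple records with recorded offsets.

    Sequences are uppercased and U is converted to T; characters outside
    {A, C, G, T, N} are rejected.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    parts: list[str] = []
    offsets: dict[str, int] = {}
    pos = 0
    for rec in records:
        seq = str(rec.seq).upper().replace("U", "T")
        bad = set(seq) - _VALID_CHARS
        if bad:
            raise ValueError(f"non-nucleotide characters {sorted(bad)} in record {rec.id}")
        offsets[rec.id] = pos
        parts.append(seq)
        pos += len(seq)
    return Genome(id=records[0].id, sequence="".join(parts), record_offsets=offsets)


def write_genome(genome: Genome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.id}\n")
        seq = genome.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")


def load_annotation(path: str | Path, genome: Genome) -> list[GeneModel]:
    """Load gene models from GFF3 or BED6, normalising to 0-based half-open.

    GFF3 coordinates (1-based inclusive) and BED coordinates (0-based
    half-open) both map onto the concatenated genome using the recorded
    per-record offsets.  Features of unknown biotype are kept as ``ncRNA``
    with a logged warning; out-of-range features are an error.
    """
    path = Path(path)
    if path.suffix.lower() in {".bed", ".bed6"}:
        genes = _load_bed(path, genome)
    else:
        genes = _load_gff3(path, genome)
    for g in genes:
        if g.end > genome.length:
            raise ValueError(f"feature {g.name} ends at {g.end} beyond genome length {genome.length}")
    return genes


def _offset_for(genome: Genome, seqid: str) -> int:
    if seqid in genome.record_offsets:
        return genome.record_offsets[seqid]
    if len(genome.record_offsets) <= 1:
        return 0
    raise ValueError(f"unknown sequence id {seqid!r} in annotation")


def _coerce_biotype(raw: str, name: str) -> str:
    if raw in BIOTYPES:
        return raw
    logger.warning("unknown biotype %r for feature %s; treating as ncRNA", raw, name)
    return "ncRNA"


def _load_gff3(path: Path, genome: Genome) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", sort_attribute_values=True,
    )
    genes: list[GeneModel] = []
    for feat in db.all_features():
        if feat.featuretype in {"region", "chromosome"}:
            continue
        name = feat.attributes.get("Name", feat.attributes.get("ID", [feat.id]))[0]
        raw_type = feat.attributes.get("biotype", [feat.featuretype])[0]
        off = _offset_for(genome, feat.seqid)
        start = off + feat.start - 1  # GFF3 is 1-based inclusive
        end = off + feat.end
        if start < 0 or feat.start < 1:
            raise ValueError(f"feature {name} has invalid GFF3 start {feat.start}")
        genes.append(
            GeneModel(name=name, biotype=_coerce_biotype(raw_type, name),
                      start=start, end=end, strand=feat.strand if feat.strand in "+-" else "+")
        )
    return genes


def _load_bed(path: Path, genome: Genome) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 6:
        raise ValueError("BED6 requires at least 6 columns")
    genes: list[GeneModel] = []
    for row in df.itertuples(index=False):
        off = _offset_for(genome, str(row[0]))
        biotype = _coerce_biotype(str(row[6]) if len(row) > 6 else "ncRNA", str(row[3]))
        genes.append(
            GeneModel(name=str(row[3]), biotype=biotype,
                      start=off + int(row[1]), end=off + int(row[2]), strand=str(row[5]))
        )
    return genes


def write_annotation_gff3(genes: Sequence[GeneModel], genome: Genome, path: str | Path) -> None:
    """Write gene models as GFF3 (1-based inclusive) against the concatenated genome."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {genome.length}\n")
        for g in genes:
            attrs = f"ID={g.name};Name={g.name};biotype={g.biotype}"
            fh.write(
                f"{genome.id}\tcrosslink_chimera\t{g.biotype}\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


class GenomeAnnotation:
    """Genome + gene models + window index, with fragment-to-gene assignment.

    A mapped fragment is assigned to the annotated gene with the largest
    overlap of its genomic interval (ties broken by gene start, then name);
    fragments overlapping no gene are assigned a synthetic intergenic
    transcript (IGT) named by the window span they occupy.
    """

    def __init__(self, genome: Genome, genes: Iterable[GeneModel], window_size: int = 100):
        self.genome = genome
        self.genes = sorted(genes, key=lambda g: (g.start, g.end, g.name))
        self.windows = WindowIndex(window_size=window_size, genome_length=genome.length)

    def assign_gene(self, start: int, end: int) -> GeneModel:
        best: GeneModel | None = None
        best_ov = 0
        for g in self.genes:
            if g.start >= end:
                break
            ov = g.overlap(start, end)
            if ov > best_ov:
                best, best_ov = g, ov
        if best is not None:
            return best
        w0 = self.windows.window_of(start)
        w1 = self.windows.window_of(end - 1)
        label = f"IGT_w{w0}" if w0 == w1 else f"IGT_w{w0}-{w1}"
        return GeneModel(name=label, biotype="IGT",
                         start=w0 * self.windows.window_size,
                         end=min((w1 + 1) * self.windows.window_size, self.genome.length))
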