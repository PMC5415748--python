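"""Paired-end read preparation: 3' quality trimming, filtering, merging.

The library inserts are short (40-100 nt after size selection) so the two
mates of a pair overlap substantially; merging requires an exact
suffix/prefix match of at least ``min_overlap`` nucleotides between mate 1
and the reverse complement of mate 2.  Downstream mapping tolerates no
mismatches, so merging is exact by default as well; a mismatch budget for
real data can be enabled explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

from Bio import SeqIO

from crosslink_chimera.annotation_io import reverse_complement


@dataclass
class Read:
    id: str
    seq: str
    qual: list[int]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class MergedRead:
    id: str
    seq: str
    overlap: int


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> Iterator[tuple[Read, Read]]:
    it1 = SeqIO.parse(str(r1_path), "fastq")
    it2 = SeqIO.parse(str(r2_path), "fastq")
    for rec1, rec2 in zip(it1, it2, strict=True):
        yield (
            Read(rec1.id, str(rec1.seq).upper(), list(rec1.letter_annotations["phred_quality"])),
            Read(rec2.id, str(rec2.seq).upper(), list(rec2.letter_annotations["phred_quality"])),
        )


def quality_trim_3prime(read: Read, q_threshold: int = 30) -> Read:
    """Trim 3' bases until a base of quality >= ``q_threshold`` is exposed."""
    end = len(read.qual)
    while end > 0 and read.qual[end - 1] < q_threshold:
        end -= 1
    if end == len(read.qual):
        return read
    return Read(read.id, read.seq[:end], read.qual[:end])


def filter_read(read: Read, min_len: int = 10, max_n_frac: float = 0.10,
                low_q: int = 5, max_low_q_frac: float = 0.50) -> tuple[bool, str]:
    """Keep-or-drop verdict with reason.

    Drops reads shorter than ``min_len``, with a fraction of undetermined
    bases above ``max_n_frac``, or with a fraction of bases at Phred
    <= ``low_q`` above ``max_low_q_frac`` (all strict comparisons).
    """
    n = len(read)
    if n < min_len:
        return False, "too_short"
    if read.seq.count("N") / n > max_n_frac:
        return False, "too_many_N"
    if sum(1 for q in read.qual if q <= low_q) / n > max_low_q_frac:
        return False, "low_quality"
    return True, "ok"


def merge_pair(r1: Read, r2: Read, min_overlap: int = 10,
               max_mismatch: int = 0) -> MergedRead | None:
    """Merge a pair via the longest suffix(r1)/prefix(revcomp r2) overlap.

    Returns ``None`` when no overlap of at least ``min_overlap`` exists.
    Overlap bases take the higher-quality call; with multiple admissible
    overlaps the longest wins (the longer merged product on ties).
    """
    rc2 = reverse_complement(r2.seq)
    q2 = r2.qual[::-1]
    best = None
    for olen in range(min(len(r1), len(r2)), min_overlap - 1, -1):
        s1 = r1.seq[len(r1) - olen:]
        s2 = rc2[:olen]
        if max_mismatch == 0:
            if s1 == s2:
                best = olen
                break
        else:
            mm = sum(1 for a, b in zip(s1, s2) if a != b)
            if mm <= max_mismatch:
                best = olen
                break
    if best is None:
        return None
    olen = best
    off = len(r1) - olen
    overlap_bases = [
        r1.seq[off + i] if r1.qual[off + i] >= q2[i] else rc2[i] for i in range(olen)
    ]
    merged = r1.seq[:off] + "".join(overlap_bases) + rc2[olen:]
    return MergedRead(id=r1.id, seq=merged, overlap=olen)


def prepare_pairs(pairs, q_threshold: int = 30, min_overlap: int = 10,
                  max_mismatch: int = 0):
    """Trim, filter and merge an iterable of read pairs.

    Returns ``(merged, audit)`` where ``audit`` is a list of
    ``(read id, action, reason)`` rows; unmergeable pairs are discarded
    and logged in the audit trail.
    """
    merged: list[MergedRead] = []
    audit: list[tuple[str, str, str]] = []
    for r1, r2 in pairs:
        t1 = quality_trim_3prime(r1, q_threshold)
        t2 = quality_trim_3prime(r2, q_threshold)
        ok1, why1 = filter_read(t1)
        ok2, why2 = filter_read(t2)
        if not (ok1 and ok2):
            audit.append((r1.id, "filtered", why1 if not ok1 else why2))
            continue
        m = merge_pair(t1, t2, min_overlap=min_overlap, max_mismatch=max_mismatch)
        if m is None:
            audit.append((r1.id, "discarded", "no_overlap"))
            continue
        merged.append(m)
        audit.append((r1.id, "merged", f"overlap={m.overlap}"))
    return merged, audit


def write_merged_fasta(merged: list[MergedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in merged:
            fh.write(f">{m.id}\n{m.seq}\n")


def write_audit_tsv(audit, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\taction\treason\n")
        for row in audit:
            fh.write("\t".join(row) + "\n")
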