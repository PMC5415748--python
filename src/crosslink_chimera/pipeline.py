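"""End-to-end orchestration: prep -> map -> call -> duplex -> stats.

Every stage writes its intermediate as plain text, counts are reconciled
at each boundary (reads in = reads out + reads discarded), and a run with
identical configuration and seed is byte-identical.  All thresholds live
in the configuration, with the analysis defaults: 100 nt windows, >= 10 nt
mate overlap, >= 15 nt exact hits, +-4 nt junction window, >= 5 bp
helices, and the significance filter (support >= 10, ratio > 2, p < 0.01).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from crosslink_chimera import annotation_io, chimera_caller, duplex_finder, fold, interaction_stats, mapper, read_prep


@dataclass
class RunConfig:
    genome: str
    annotation: str
    r1: str | None = None
    r2: str | None = None
    reads_fasta: str | None = None  # pre-merged reads
    blast: str | None = None  # pre-computed hits, outfmt 6
    outdir: str = "run_out"
    window_size: int = 100
    q_threshold: int = 30
    min_overlap: int = 10
    min_hit_len: int = 15
    max_gap: int = 4
    max_overlap_junction: int = 4
    min_helix_len: int = 5
    min_support: int = 10
    min_ratio: float = 2.0
    alpha: float = 0.01
    bh_correct: bool = False
    fold_structures: bool = True
    energy_engine: str = "internal"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("window_size", "min_overlap", "min_hit_len", "min_helix_len", "min_support"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.r1 is None and self.reads_fasta is None:
            raise ValueError("either paired FASTQ (r1/r2) or pre-merged reads are required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class RunReport:
    config: dict
    stage_counts: dict = field(default_factory=dict)
    length_histogram: dict = field(default_factory=dict)
    fraction_longer_than_42: float = 0.0
    category_counts: dict = field(default_factory=dict)
    n_window_pairs: int = 0
    n_significant_pairs: int = 0
    n_transcript_pairs: int = 0
    energy_summary: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def report_length_distribution(reads) -> tuple[dict[int, int], float]:
    """Integer length histogram and the fraction of reads longer than 42 nt."""
    lengths = [len(r.seq) for r in reads]
    if not lengths:
        raise ValueError("no reads")
    hist: dict[int, int] = {}
    for L in lengths:
        hist[L] = hist.get(L, 0) + 1
    frac = sum(1 for L in lengths if L > 42) / len(lengths)
    return hist, frac


def run_pipeline(config: RunConfig) -> RunReport:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    report = RunReport(config=asdict(config))

    genome = annotation_io.load_genome(config.genome)
    genes = annotation_io.load_annotation(config.annotation, genome)
    ann = annotation_io.GenomeAnnotation(genome, genes, window_size=config.window_size)

    # --- prep -------------------------------------------------------------
    if config.r1 is not None:
        pairs = list(read_prep.read_fastq_pairs(config.r1, config.r2))
        merged, audit = read_prep.prepare_pairs(
            pairs, q_threshold=config.q_threshold, min_overlap=config.min_overlap)
        read_prep.write_audit_tsv(audit, outdir / "prep_audit.tsv")
        report.stage_counts["pairs_in"] = len(pairs)
        report.stage_counts["merged"] = len(merged)
        report.stage_counts["prep_discarded"] = len(pairs) - len(merged)
    else:
        from Bio import SeqIO

        merged = [read_prep.MergedRead(id=rec.id, seq=str(rec.seq).upper(), overlap=0)
                  for rec in SeqIO.parse(config.reads_fasta, "fasta")]
        report.stage_counts["pairs_in"] = len(merged)
        report.stage_counts["merged"] = len(merged)
        report.stage_counts["prep_discarded"] = 0
    read_prep.write_merged_fasta(merged, outdir / "merged.fasta")
    hist, frac = report_length_distribution(merged)
    report.length_histogram = {str(k): v for k, v in sorted(hist.items())}
    report.fraction_longer_than_42 = frac

    # --- map --------------------------------------------------------------
    if config.blast is not None:
        hit_sets = mapper.import_blast_tabular(config.blast, min_hit_len=config.min_hit_len)
        for m in merged:
            hit_sets.setdefault(m.id, mapper.ReadHitSet(read_id=m.id, hits=[], exhaustive=False))
    else:
        index = mapper.build_index(genome, min_hit_len=config.min_hit_len)
        hit_sets = {
            m.id: (mapper.find_exact_hits(m.id, m.seq, index)
                   if len(m.seq) >= config.min_hit_len
                   else mapper.ReadHitSet(read_id=m.id, hits=[]))
            for m in merged
        }
    mapper.export_blast_tabular((hit_sets[m.id] for m in merged), genome.id, outdir / "hits.tsv")
    report.stage_counts["reads_with_hits"] = sum(1 for m in merged if hit_sets[m.id].hits)

    # --- call -------------------------------------------------------------
    calls = [
        chimera_caller.classify_read(
            m.id, m.seq, hit_sets[m.id], ann,
            max_gap=config.max_gap, max_overlap=config.max_overlap_junction,
            min_helix_len=config.min_helix_len)
        for m in merged
    ]
    chimera_caller.write_calls_tsv(calls, outdir / "calls.tsv")
    report.category_counts = chimera_caller.category_counts(calls)
    assert sum(report.category_counts.values()) == len(merged)

    # --- duplex -----------------------------------------------------------
    if config.fold_structures:
        evaluator = fold.get_evaluator(config.energy_engine)
        seq_by_id = {m.id: m.seq for m in merged}
        report.energy_summary = _fold_stage(calls, seq_by_id, evaluator,
                                            config.min_helix_len, outdir / "duplexes.tsv")

    # --- stats ------------------------------------------------------------
    occ = interaction_stats.count_occurrences(calls, ann.windows)
    pair_counts = interaction_stats.count_pair_support(calls, ann.windows)
    if occ.C > 0 and occ.T1 >= 2:
        results = interaction_stats.evaluate_pairs(
            pair_counts, occ, min_support=config.min_support,
            min_ratio=config.min_ratio, alpha=config.alpha, bh_correct=config.bh_correct)
    else:
        results = []
    significant = interaction_stats.call_significant_pairs(results)
    transcripts = interaction_stats.aggregate_to_transcripts(significant, calls, ann.windows)
    interaction_stats.write_pair_results_tsv(results, outdir / "window_pairs.tsv")
    interaction_stats.write_transcript_pairs_tsv(transcripts, outdir / "transcript_pairs.tsv")
    report.n_window_pairs = len(results)
    report.n_significant_pairs = len(significant)
    report.n_transcript_pairs = len(transcripts)
    report.stage_counts["T1"] = occ.T1
    report.stage_counts["chimeric_reads"] = occ.C

    report.to_json(outdir / "report.json")
    return report


def _fold_stage(calls, seq_by_id, evaluator, min_helix_len, out_path) -> dict:
    """Constrained duplex/fold models for retained reads; returns an energy summary."""
    n_folded = 0
    energies = []
    with open(out_path, "w") as fh:
        fh.write("read_id\tcategory\tenergy\tnormalized_energy\tn_constraint_helices\tstructure\n")
        for call in calls:
            if not (call.is_chimera or call.is_single):
                continue
            seq = seq_by_id[call.read_id]
            try:
                if call.is_chimera:
                    a, b = call.part_a, call.part_b
                    seq_a = seq[a.read_start:a.read_end]
                    seq_b = seq[b.read_start:b.read_end]
                    helices = [duplex_finder.scan_amt_sites(h, seq_a, seq_b)
                               for h in duplex_finder.find_helices(seq_a, seq_b, min_len=min_helix_len)]
                    model = duplex_finder.select_min_energy_structure(
                        (seq_a, seq_b), helices, evaluator)
                else:
                    helices = [duplex_finder.scan_amt_sites(h, seq, seq)
                               for h in duplex_finder.find_self_helices(seq, min_len=min_helix_len)]
                    model = duplex_finder.select_min_energy_structure(seq, helices, evaluator)
            except duplex_finder.NoValidConstraintError:
                continue
            norm = model.energy / len(seq)
            energies.append(norm)
            n_folded += 1
            fh.write(f"{call.read_id}\t{call.category}\t{model.energy:.3f}\t"
                     f"{norm:.5f}\t{len(model.helices)}\t{model.structure}\n")
    summary = {"n_folded": n_folded}
    if energies:
        summary["mean_normalized_energy"] = round(sum(energies) / len(energies), 5)
        summary["min_normalized_energy"] = round(min(energies), 5)
        summary["max_normalized_energy"] = round(max(energies), 5)
    return summary
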