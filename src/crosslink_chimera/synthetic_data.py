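"""Synthetic genomes, planted RNA-RNA interactions and simulated read sets.

The generator emulates the statistical structure the analysis assumes,
so every downstream stage is testable without sequencing data:

* a random genome tiled with non-overlapping genes, each carrying one
  intramolecular hairpin cassette (stem with a 5'-UR cross-link motif) so
  that single reads fold with a cross-linkable stem;
* planted interacting gene pairs: each pair embeds the two arms of a
  reverse-complementary helix (with a configurable UR/RU motif) in its two
  genes, and chimeric reads ligate fragments containing the two arms with
  a junction gap/overlap drawn from a configurable window;
* a random-ligation background: chimeras joining two fragments drawn
  independently with probability proportional to per-gene abundance
  (log-uniform across genes), so window-pair frequencies follow the
  random-ligation expectation;
* paired-end reads over each ligated molecule with a guaranteed mate
  overlap, high base qualities, and optional degraded tails / substitution
  errors to exercise trimming and filtering.

Junction geometry is engineered at the genome level: fragments of a
planted pair always end (arm side A) and start (arm side B) at fixed
junction points whose flanking 4 nt are identical by construction, so a
positive junction offset (overlap) produces exactly the intended pair of
maximal exact hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from crosslink_chimera.annotation_io import (
    GeneModel,
    Genome,
    reverse_complement,
    write_annotation_gff3,
    write_genome,
)
from crosslink_chimera.read_prep import Read

_BASES = np.array(list("ACGT"))


@dataclass
class PlantedPair:
    gene_a: int
    gene_b: int
    n_chimeras: int = 15
    helix_length: int = 8
    amt_motif: str = "UR"  # U-purine or purine-U on the A arm

    def __post_init__(self) -> None:
        if self.helix_length < 5:
            raise ValueError("planted helices must be at least 5 bp")
        if self.amt_motif not in ("UR", "RU"):
            raise ValueError("amt_motif must be 'UR' or 'RU'")
        if self.n_chimeras < 0:
            raise ValueError("n_chimeras must be >= 0")


@dataclass
class SimConfig:
    seed: int = 0
    genome_length: int = 20000
    n_genes: int = 20
    gene_biotype_mix: dict = field(default_factory=lambda: {
        "mRNA": 0.4, "tRNA": 0.25, "rRNA": 0.15, "ncRNA": 0.2,
    })
    gene_length_range: tuple[int, int] = (150, 260)
    planted_pairs: list[PlantedPair] = field(default_factory=list)
    n_background_chimeras: int = 0
    n_single_reads: int = 0
    junction_gap_overlap_range: tuple[int, int] = (-4, 4)  # negative = gap
    read_length_range: tuple[int, int] = (40, 100)
    pe_overlap_min: int = 10
    pe_read_length: int = 75
    abundance_span: float = 100.0  # log-uniform ratio between most and least abundant gene
    planted_min_enrichment: float = 5.0  # planted pairs are at least this enriched over background
    error_rate: float = 0.0
    degraded_tail_len: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < self.n_genes * 150:
            raise ValueError("genome too short to pack the requested genes")
        lo, hi = self.junction_gap_overlap_range
        if not (-10 <= lo <= hi <= 10):
            raise ValueError("junction gap/overlap range out of bounds")
        rlo, rhi = self.read_length_range
        if rlo < 30 or rhi < rlo:
            raise ValueError("bad read_length_range")
        if 2 * self.pe_read_length - rhi < self.pe_overlap_min:
            raise ValueError("paired-end reads cannot guarantee the minimum mate overlap")
        if any(n < 0 for n in (self.n_background_chimeras, self.n_single_reads)):
            raise ValueError("counts must be >= 0")
        for p in self.planted_pairs:
            if not (0 <= p.gene_a < self.n_genes and 0 <= p.gene_b < self.n_genes):
                raise ValueError("planted pair references a gene outside the genome")


@dataclass
class PlantedLayout:
    pair: PlantedPair
    gene_a_name: str
    gene_b_name: str
    arm_a: tuple[int, int]
    arm_b: tuple[int, int]
    junction_a: int  # fragments from side A always end here
    junction_b: int  # fragments from side B always start here


@dataclass
class SimLayout:
    cassettes: list[tuple[int, int]]  # per-gene hairpin interval
    planted: list[PlantedLayout]
    abundances: np.ndarray


@dataclass
class ReadProvenance:
    read_id: str
    label: str  # planted_chimera | background_chimera | single
    gene_a: str
    gene_b: str


@dataclass
class GroundTruth:
    rows: list[ReadProvenance] = field(default_factory=list)

    def labels(self) -> dict[str, str]:
        return {r.read_id: r.label for r in self.rows}


@dataclass
class SimulatedDataset:
    config: SimConfig
    genome: Genome
    genes: list[GeneModel]
    layout: SimLayout
    molecules: list[tuple[str, str]]  # (read id, ligated molecule sequence)
    pairs: list[tuple[Read, Read]]
    truth: GroundTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "annotation": outdir / "genes.gff3",
            "r1": outdir / "reads_R1.fastq",
            "r2": outdir / "reads_R2.fastq",
            "truth": outdir / "truth.tsv",
        }
        write_genome(self.genome, paths["genome"])
        write_annotation_gff3(self.genes, self.genome, paths["annotation"])
        write_fastq_pairs(self.pairs, paths["r1"], paths["r2"])
        with open(paths["truth"], "w") as fh:
            fh.write("read_id\tlabel\tgene_a\tgene_b\n")
            for r in self.truth.rows:
                fh.write(f"{r.read_id}\t{r.label}\t{r.gene_a}\t{r.gene_b}\n")
        return paths


def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return _BASES[rng.integers(0, 4, n)].tolist()


def _find_free_slot(rng: np.random.Generator, gene: GeneModel,
                    occupied: list[tuple[int, int]], size: int, margin: int = 10) -> int:
    lo, hi = gene.start + margin, gene.end - margin - size
    if hi < lo:
        raise ValueError(f"gene {gene.name} too short to place a {size} nt element")
    for _ in range(200):
        s = int(rng.integers(lo, hi + 1))
        if all(e <= s or b >= s + size for b, e in occupied):
            occupied.append((s, s + size))
            return s
    raise ValueError(f"could not place a {size} nt element in gene {gene.name}")


def make_toy_genome(cfg: SimConfig) -> tuple[Genome, list[GeneModel], SimLayout]:
    """Deterministically build a toy genome with genes, hairpins and planted arms."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    glo, ghi = cfg.gene_length_range
    ghi = min(ghi, (cfg.genome_length - 2 * (n + 1)) // n)
    lengths = rng.integers(glo, max(glo, ghi) + 1, n)
    slack = cfg.genome_length - int(lengths.sum())
    if slack < 0:
        raise ValueError("infeasible gene packing")
    gaps = rng.multinomial(slack, [1.0 / (n + 1)] * (n + 1))

    seq = _random_seq(rng, cfg.genome_length)
    mix_names = sorted(cfg.gene_biotype_mix)
    mix_p = np.array([cfg.gene_biotype_mix[k] for k in mix_names], dtype=float)
    mix_p = mix_p / mix_p.sum()
    biotypes = rng.choice(mix_names, size=n, p=mix_p)

    genes: list[GeneModel] = []
    pos = 0
    counts: dict[str, int] = {}
    for i in range(n):
        pos += int(gaps[i])
        bt = str(biotypes[i])
        counts[bt] = counts.get(bt, 0) + 1
        genes.append(GeneModel(name=f"{bt}{counts[bt]:02d}", biotype=bt,
                               start=pos, end=pos + int(lengths[i]), strand="+"))
        pos += int(lengths[i])

    occupied: list[list[tuple[int, int]]] = [[] for _ in range(n)]
    cassettes: list[tuple[int, int]] = []
    for i, g in enumerate(genes):
        stem = _random_seq(rng, 7)
        stem[2], stem[3] = "T", "A"  # 5'-UR cross-link motif in the stem
        loop = _random_seq(rng, 4)
        cassette = stem + loop + list(reverse_complement("".join(stem)))
        s = _find_free_slot(rng, g, occupied[i], len(cassette))
        seq[s : s + len(cassette)] = cassette
        cassettes.append((s, s + len(cassette)))

    planted: list[PlantedLayout] = []
    for p in cfg.planted_pairs:
        if p.gene_a == p.gene_b:
            planted.append(_plant_homodimer(rng, p, genes, occupied, seq))
        else:
            planted.append(_plant_inter(rng, p, genes, occupied, seq))

    log_span = np.log(cfg.abundance_span)
    abundances = np.exp(rng.uniform(0.0, log_span, n))
    abundances = abundances / abundances.sum()

    genome = Genome(id="toy_genome", sequence="".join(seq), record_offsets={"toy_genome": 0})
    return genome, genes, SimLayout(cassettes=cassettes, planted=planted, abundances=abundances)


def _plant_inter(rng, p: PlantedPair, genes, occupied, seq) -> PlantedLayout:
    """Arm A (with motif) in gene A followed by its fixed junction; the
    reverse-complement arm in gene B preceded by its junction.  The 4 nt
    after junction B equal the 4 nt before junction A so that overlap
    offsets up to +4 produce the intended maximal hits."""
    L = p.helix_length
    arm_a = _random_seq(rng, L)
    arm_a[2:4] = list("TA" if p.amt_motif == "UR" else "AT")
    arm_a[-1] = "A"  # keeps junction hits maximal at +4 overlap
    arm_b = list(reverse_complement("".join(arm_a)))

    ga, gb = genes[p.gene_a], genes[p.gene_b]
    sa = _find_free_slot(rng, ga, occupied[p.gene_a], L + 5)
    seq[sa : sa + L] = arm_a
    ja = sa + L + 4
    seq[sa + L : ja] = list("CCCC")
    seq[ja] = "A"

    sb_region = _find_free_slot(rng, gb, occupied[p.gene_b], L + 5)
    jb = sb_region + 5
    seq[sb_region] = "G"
    seq[sb_region + 1 : jb] = list("CCCC")
    seq[jb : jb + L] = arm_b
    return PlantedLayout(pair=p, gene_a_name=ga.name, gene_b_name=gb.name,
                         arm_a=(sa, sa + L), arm_b=(jb, jb + L),
                         junction_a=ja, junction_b=jb - 4)


def _plant_homodimer(rng, p: PlantedPair, genes, occupied, seq) -> PlantedLayout:
    """A reverse-complement-palindromic arm in one gene; both fragments of a
    homodimer chimera contain it, so their genomic intervals overlap."""
    half = max(3, (p.helix_length + 1) // 2)
    h = _random_seq(rng, half)
    h[0] = "G"
    h[-2:] = list("TA")
    arm = h + list(reverse_complement("".join(h)))
    L = len(arm)

    g = genes[p.gene_a]
    s0 = _find_free_slot(rng, g, occupied[p.gene_a], L + 10)
    jb = s0 + 1  # layout: [G][CCCC][arm][CCCC][A]
    sa = jb + 4
    ja = sa + L + 4
    seq[s0] = "G"
    seq[jb : jb + 4] = list("CCCC")
    seq[sa : sa + L] = arm
    seq[sa + L : ja] = list("CCCC")
    seq[ja] = "A"
    return PlantedLayout(pair=p, gene_a_name=g.name, gene_b_name=g.name,
                         arm_a=(sa, sa + L), arm_b=(sa, sa + L),
                         junction_a=ja, junction_b=jb)


def _draw_planted_molecule(rng, genome_seq: str, layout: PlantedLayout,
                           genes_by_name: dict[str, GeneModel], cfg: SimConfig) -> str:
    ja, jb = layout.junction_a, layout.junction_b
    arm_len_a = layout.arm_a[1] - layout.arm_a[0]
    gene_a = genes_by_name[layout.gene_a_name]
    gene_b = genes_by_name[layout.gene_b_name]
    need_a = (ja - layout.arm_a[0]) + 2  # fragment A must contain the arm
    need_b = (layout.arm_b[1] - jb) + 2
    max_a = min(48, ja - gene_a.start)
    max_b = min(48, gene_b.end - jb)
    lo, hi = cfg.read_length_range
    jlo, jhi = cfg.junction_gap_overlap_range
    for _ in range(100):
        len_a = int(rng.integers(max(16, need_a), max_a + 1))
        len_b = int(rng.integers(max(16, need_b), max_b + 1))
        off = int(rng.integers(jlo, jhi + 1))
        total = len_a + len_b - off if off > 0 else len_a - off + len_b
        if lo <= total <= hi:
            frag_a = genome_seq[ja - len_a : ja]
            if off > 0:
                return frag_a + genome_seq[jb + off : jb + len_b]
            return frag_a + "T" * (-off) + genome_seq[jb : jb + len_b]
    raise RuntimeError("could not draw a planted chimera within the length range")


def _make_pair(molecule: str, read_id: str, cfg: SimConfig, rng) -> tuple[Read, Read]:
    n = len(molecule)
    rl = min(cfg.pe_read_length, n)
    r1_seq = list(molecule[:rl])
    r2_seq = list(reverse_complement(molecule[n - rl:]))
    q1 = [40] * rl
    q2 = [40] * rl
    for s, q in ((r1_seq, q1), (r2_seq, q2)):
        if cfg.error_rate > 0:
            for i in range(rl):
                if rng.random() < cfg.error_rate:
                    s[i] = str(rng.choice([b for b in "ACGT" if b != s[i]]))
        t = min(cfg.degraded_tail_len, rl - 1)
        for i in range(rl - t, rl):
            q[i] = 2
            s[i] = str(_BASES[int(rng.integers(0, 4))])
    return Read(read_id, "".join(r1_seq), q1), Read(read_id, "".join(r2_seq), q2)


def simulate_reads(genome: Genome, genes: list[GeneModel], layout: SimLayout,
                   cfg: SimConfig, rng: np.random.Generator | None = None):
    """Ligated molecules and paired-end reads for planted, background and single classes."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    gseq = genome.sequence
    genes_by_name = {g.name: g for g in genes}
    molecules: list[tuple[str, str]] = []
    truth = GroundTruth()

    gene_index = {g.name: i for i, g in enumerate(genes)}
    for k, pl in enumerate(layout.planted):
        # a planted interaction is an enrichment over random ligation: plant at
        # least planted_min_enrichment times the expected background
        # co-ligation count of its two genes (w^2 for a homodimer pair)
        wa = layout.abundances[gene_index[pl.gene_a_name]]
        wb = layout.abundances[gene_index[pl.gene_b_name]]
        expected_bg = (wa * wb if pl.gene_a_name == pl.gene_b_name else 2 * wa * wb)
        expected_bg *= cfg.n_background_chimeras
        n_chim = max(pl.pair.n_chimeras,
                     int(np.ceil(cfg.planted_min_enrichment * expected_bg)))
        for i in range(n_chim):
            rid = f"P{k}_{i}"
            molecules.append((rid, _draw_planted_molecule(rng, gseq, pl, genes_by_name, cfg)))
            truth.rows.append(ReadProvenance(rid, "planted_chimera", pl.gene_a_name, pl.gene_b_name))

    lo, hi = cfg.read_length_range
    for i in range(cfg.n_background_chimeras):
        gx = genes[int(rng.choice(len(genes), p=layout.abundances))]
        gy = genes[int(rng.choice(len(genes), p=layout.abundances))]
        for _ in range(100):
            l1 = int(rng.integers(18, 49))
            l2 = int(rng.integers(18, 49))
            if lo <= l1 + l2 <= hi:
                break
        s1 = int(rng.integers(gx.start, gx.end - l1 + 1))
        s2 = int(rng.integers(gy.start, gy.end - l2 + 1))
        rid = f"B{i}"
        molecules.append((rid, gseq[s1 : s1 + l1] + gseq[s2 : s2 + l2]))
        truth.rows.append(ReadProvenance(rid, "background_chimera", gx.name, gy.name))

    for i in range(cfg.n_single_reads):
        gi = int(rng.choice(len(genes), p=layout.abundances))
        g = genes[gi]
        cs, ce = layout.cassettes[gi]
        L = int(rng.integers(max(lo, ce - cs), min(hi, g.end - g.start) + 1))
        slo = max(g.start, ce - L)
        shi = min(cs, g.end - L)
        start = int(rng.integers(slo, shi + 1))
        rid = f"S{i}"
        molecules.append((rid, gseq[start : start + L]))
        truth.rows.append(ReadProvenance(rid, "single", g.name, g.name))

    pairs = [_make_pair(m, rid, cfg, rng) for rid, m in molecules]
    return molecules, pairs, truth


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """One-call simulation: genome, annotation, reads and ground truth."""
    genome, genes, layout = make_toy_genome(cfg)
    molecules, pairs, truth = simulate_reads(genome, genes, layout, cfg)
    return SimulatedDataset(config=cfg, genome=genome, genes=genes, layout=layout,
                            molecules=molecules, pairs=pairs, truth=truth)


def write_fastq_pairs(pairs, r1_path: str | Path, r2_path: str | Path) -> None:
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for r1, r2 in pairs:
            for fh, r in ((f1, r1), (f2, r2)):
                qual = "".join(chr(q + 33) for q in r.qual)
                fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")
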