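"""Shared fixtures: a hand-built classification genome exercising every
read category, and small helpers used across the suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from crosslink_chimera.annotation_io import (
    GeneModel,
    Genome,
    GenomeAnnotation,
    reverse_complement,
)

BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


def build_classification_fixture():
    """Hand-built 2 kb genome + 12 reads spanning every read category.

    Layout (all on the + strand):
      geneA (tRNA) [100, 400): hairpin cassette at 120, split-single arms at
        200/300, inter-chimera arm (with engineered junction) at 230, and a
        U-free segment at 350;
      geneB (rRNA) [600, 900): the reverse-complement inter arm at 650 (with
        its junction), a palindromic homodimer arm at 700, and a U-free
        segment at 820;
      intergenic: a duplicated 50-mer at 1200/1400 (multi-mapping locus).
    """
    rng = np.random.default_rng(42)
    g = list(random_dna(rng, 2000))

    genes = [
        GeneModel(name="geneA", biotype="tRNA", start=100, end=400, strand="+"),
        GeneModel(name="geneB", biotype="rRNA", start=600, end=900, strand="+"),
    ]

    # hairpin cassette in geneA: 7 bp stem with a 5'-UR motif, 4 nt loop
    stem = list(random_dna(rng, 7))
    stem[2], stem[3] = "T", "A"
    g[120:138] = stem + list(random_dna(rng, 4)) + list(reverse_complement("".join(stem)))

    # split-single arms inside geneA
    arm_s = list(random_dna(rng, 8))
    arm_s[2], arm_s[3] = "T", "A"
    g[200:208] = arm_s
    g[300:308] = list(reverse_complement("".join(arm_s)))
    # junction safety for the split read (no accidental hit extension)
    g[217], g[218], g[291], g[292] = "G", "A", "T", "C"

    # inter-chimera arm: geneA side [armX][CCCC][A], geneB side [G][CCCC][rc armX];
    # the copied CCCC makes overlap offsets up to +4 yield the intended hits
    arm_x = list(random_dna(rng, 8))
    arm_x[2], arm_x[3] = "T", "A"
    arm_x[-1] = "A"
    g[230:238] = arm_x
    g[238:242] = list("CCCC")
    g[242] = "A"
    g[645] = "G"
    g[646:650] = list("CCCC")
    g[650:658] = list(reverse_complement("".join(arm_x)))

    # palindromic homodimer arm in geneB
    h = list(random_dna(rng, 5))
    h[0] = "G"
    h[3], h[4] = "T", "A"
    g[700:710] = h + list(reverse_complement("".join(h)))
    g[695], g[696], g[713], g[714] = "G", "T", "C", "A"

    # U-free (hence cross-link-site-free) segments in both genes
    acg = np.array(list("ACG"))
    g[350:372] = acg[rng.integers(0, 3, 22)].tolist()
    g[820:842] = acg[rng.integers(0, 3, 22)].tolist()
    g[371], g[372], g[819], g[820] = "C", "T", "G", "A"

    # duplicated intergenic 50-mer (multi-mapping)
    g[1400:1450] = g[1200:1250]

    seq = "".join(g)
    genome = Genome(id="fixture", sequence=seq, record_offsets={"fixture": 0})
    ann = GenomeAnnotation(genome, genes, window_size=100)

    frag_a = seq[214:242]
    frag_b0 = seq[646:674]
    reads = {
        "r01_continuous": seq[110:160],
        "r02_split": seq[190:218] + seq[292:316],
        "r03_inter_adjacent": frag_a + frag_b0,
        "r04_inter_gap4": frag_a + "TTTT" + frag_b0,
        "r05_inter_overlap4": frag_a + seq[650:678],
        "r06_gap5_rejected": frag_a + "TTTTT" + frag_b0,
        "r07_homodimer": seq[690:714] + seq[696:720],
        "r08_multimap": seq[1200:1245],
        "r09_three_parts": seq[150:170] + seq[750:770] + seq[1000:1020],
        "r10_no_amt": seq[350:372] + seq[820:842],
        "r11_unmapped": random_dna(np.random.default_rng(4242), 45),
        "r12_inter_overlap2": frag_a + seq[648:676],
    }
    expected = {
        "r01_continuous": "single_continuous",
        "r02_split": "single_split",
        "r03_inter_adjacent": "chimera_inter",
        "r04_inter_gap4": "chimera_inter",
        "r05_inter_overlap4": "chimera_inter",
        "r06_gap5_rejected": "discard_multipart",
        "r07_homodimer": "chimera_homodimer",
        "r08_multimap": "discard_multimap",
        "r09_three_parts": "discard_multipart",
        "r10_no_amt": "discard_no_amt_site",
        "r11_unmapped": "discard_unmapped",
        "r12_inter_overlap2": "chimera_inter",
    }
    expected_offsets = {
        "r03_inter_adjacent": 0,
        "r04_inter_gap4": -4,
        "r05_inter_overlap4": 4,
        "r12_inter_overlap2": 2,
    }
    return ann, reads, expected, expected_offsets


@pytest.fixture(scope="session")
def classification_fixture():
    return build_classification_fixture()
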