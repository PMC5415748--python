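# Methods

## Overview

`crosslink-chimera` detects RNA–RNA interactions from proximity-ligation
sequencing experiments (CLASH/PARIS-style protocols) on bacterial-scale
genomes. In such experiments a psoralen derivative (AMT) intercalates into
RNA duplexes in vivo and, under 365 nm UV, covalently links juxtaposed
uridines; after nuclease trimming the two strands of a cross-linked duplex
are ligated into one molecule and sequenced. A read therefore either maps
continuously to the genome (an intramolecular structure, "single read") or
decomposes into two fragments from different places (a "chimera",
evidencing a physical interaction between two transcripts). The pipeline
turns paired-end reads into a table of window pairs whose ligation
frequency is significantly above the random-ligation expectation.

The stages are: paired-end merge → exhaustive exact mapping → read
classification → constrained duplex/structure modelling → windowed
over-representation statistics.

## Read preparation

Mates are 3'-quality-trimmed to Phred ≥ 30, then dropped if shorter than
10 nt, if more than 10% of bases are undetermined, or if more than half of
the bases have Phred ≤ 5 (all strict comparisons). Merging requires an
exact suffix/prefix match of at least 10 nt between mate 1 and the reverse
complement of mate 2; the longest admissible overlap wins, and overlap
bases take the higher-quality call. Because the mapper tolerates no
mismatches, merging is exact by default — tolerating merge mismatches
would only create unmappable reads; an explicit mismatch budget exists for
real data. Unmergeable pairs are discarded with a logged reason rather
than analysed as separate mates; this is a deliberate simplification and
every discard is visible in the audit trail.

## Exact mapping

Only gap-free, mismatch-free alignments are trusted, so mapping reduces to
enumerating all maximal exact matches (MEMs) of each read against both
genome strands, down to a minimum hit length (default 15 nt — short enough
to keep two-fragment reads decomposable, long enough that a random 15-mer
is not expected even once on a 5 Mb genome). The index stores every
genomic k-mer (k = the minimum hit length); since a MEM of length L
contributes all of its L−k+1 seeds on one diagonal, merging consecutive
seeds per (strand, diagonal) reconstructs MEM boundaries exactly, and the
result provably equals a brute-force all-substrings scan (tested against
one). Pre-computed BLAST tabular hits can be imported instead; rows with
mismatches, gaps, or identity below 100% are dropped so that both routes
satisfy the same contract.

## Read classification

Each read is explained by at most two hits that jointly cover it:

* a unique full-length hit → `single_continuous`;
* two parts in different genes → `chimera_inter`;
* two parts mapping to overlapping coordinates of one gene →
  `chimera_homodimer` (two copies of one molecule ligated to each other);
* two parts in non-overlapping regions of one gene → `single_split`
  (an intramolecular stem whose loop was nucleased away).

The junction between two parts may carry up to 4 nt of overlap (ligation
near a trimmed end maps ambiguously to both fragments) or up to 4 nt of
gap (bases resolved by neither hit); the signed junction offset
(positive = overlap) is recorded per read. Reads whose decompositions
implicate more than one gene pair, more than one genomic locus, or more
than one geometry are `discard_multimap`; reads that no one- or two-part
decomposition can explain are `discard_multipart`; reads with no hits are
`discard_unmapped`. When both a continuous and a split interpretation
exist, the continuous one wins.

Retained reads must finally contain at least one helical region carrying a
classical psoralen cross-linking context — a 5'-UR or 5'-RU dinucleotide
(uridine adjacent to a purine, read 5'→3') — inside the duplex between the
two parts (chimeras) or inside an intramolecular stem (single reads);
otherwise the read is `discard_no_amt_site`. The motif is searched on
either strand of the helix; since every helix position is base-paired, any
such dinucleotide wholly inside the helix has its uridine paired. Reads
with no candidate helix at all fail the same filter: without a duplex
there is nothing the cross-linker could have frozen.

Fragment-to-gene assignment uses maximal genomic overlap, ties broken by
gene start; the current assignment is strand-agnostic because library
strandedness is not guaranteed. Fragments overlapping no annotated gene
become synthetic intergenic transcripts (IGT) named by their window span,
so novel transcripts participate in the statistics like any gene.

## Helix search and duplex modelling

A helical region is a maximal stretch of antiparallel base pairing
(Watson–Crick plus G·U wobble) of at least 5 bp — the shortest stretch
that plausibly survives single-strand nuclease trimming; shorter minima
explode the candidate count without adding credible duplexes. The search
is exhaustive over substring pairs and is validated against a brute-force
oracle.

Candidate helices carrying a cross-link site become forced-pair
constraints for an energy model, and the lowest-energy constrained
structure is reported as the duplex frozen by the cross-linker. The
default evaluator scores a structure as the sum of its pair energies
(G·C −3.0, A·U −2.0, G·U −1.0 kcal/mol; minimum hairpin loop 3 nt) and
minimises it by Nussinov-style dynamic programming with exact constraint
handling (forced pairs restrict partners and forbid crossing pairs;
unpairable positions are masked). The table is deliberately simple so that
results are bit-stable, fast, and checkable against exhaustive structure
enumeration; a nearest-neighbour engine (ViennaRNA's RNAfold, when the
executable is available) plugs in behind the same interface, changing
energies but not pipeline logic. Pseudoknots and partition-function
quantities are out of scope.

Two numerical details matter. First, dimers are joined through a run of
four unpairable linker positions rather than concatenated, so no spurious
junction-spanning pairs can form and the minimum-loop rule never bridges
the two molecules. Second, constraint combinations: the minimum energy
over all non-empty subsets of mutually compatible forced helices equals
the minimum over single helices, because adding constraints can only
shrink the feasible structure set; subsets are therefore enumerated
exhaustively only while the candidate count is at most 5 and singly
beyond that — the reported energy is unaffected, only the reported
constraint set can differ. Ties are resolved toward more constrained
pairs, then the lexicographically smaller dot-bracket, making every output
deterministic.

Per-read minimum folding energies are reported normalised by read length
(kcal/mol/nt); a random-ligation null set (concatenations of random
genomic fragments with matched length and fragment-count ranges) is
available for comparison, mirroring the observation that genuine ligated
duplexes fold lower than random concatenations.

## Over-representation statistics

The genome is tiled with non-overlapping fixed-width windows (default
100 nt, the resolution at which interacting regions are grouped). Every
single read contributes one occurrence token at the window of its genomic
midpoint, and every chimera two tokens (one per partner fragment); a
fragment spans at most two windows at this width, so the midpoint rule
gives a unique, deterministic token without inflating the total. The
token total T1 is the size of the random-ligation pool.

For a window pair (X, Y) joined by c_xy of the C chimeras, the observed
frequency c_xy / C is compared with the expected frequency of random
ligation — the probability of drawing the two windows as an unordered pair
of distinct tokens from the pool:

    f_exp = 2 (N_x / T1) (N_y / (T1 − 1))      X ≠ Y
    f_exp = N_x (N_x − 1) / (T1 (T1 − 1))      X = Y (homodimers)

The self-pair form drops the factor of two because the two draws are
indistinguishable; with it, expected frequencies over all unordered pairs
sum exactly to one (a tested invariant). Filters apply in order: support
(c_xy ≥ 10 chimeras), enrichment (observed/expected ratio > 2), then a
one-sided Fisher exact test at p < 0.01 on the read-level 2×2 table

    a = chimeras joining X and Y        b = chimeras with X but not Y
    c = chimeras with Y but not X       d = all remaining chimeras

This table was a genuinely open design point; the read-level construction
was chosen because its margins are observable and it asks precisely
whether X and Y are ligated together more often than their overall
ligation activity predicts. No multiple-testing correction is applied by
default (the decision rule is a fixed per-pair threshold);
Benjamini–Hochberg can be enabled. Significant window pairs are grouped
into transcript pairs by the most common gene pair among their supporting
chimeras, with a class-pair label (e.g. "rRNA - tRNA") from the two
biotypes.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes — it
is the test bed, not a model of the chemistry (no cross-linking kinetics,
nuclease bias, or ligation efficiency). A random genome is tiled with
non-overlapping genes (default 20 genes of 150–260 nt on a 20 kb genome,
all on the plus strand; strand handling is exercised separately in unit
tests). Per-gene abundances are log-uniform spanning 100×, mimicking the
dominance of rRNA/tRNA species in real libraries. Each gene carries one
hairpin cassette (7 bp stem containing a 5'-UR motif, 4 nt loop) so single
reads fold with a cross-linkable stem.

Planted interacting pairs embed the two arms of a reverse-complementary
helix (default 8 bp, below the 15 nt mapping threshold so arms never
create multi-mapping; homodimer pairs use a reverse-complement-palindromic
arm) with a configurable UR/RU motif. Planted chimeras ligate fragments
containing the two arms with a junction offset drawn uniformly from
[−4, +4]: gaps insert unmapped bases, and overlaps are made real by
fixing each pair's two junction points at genome construction and copying
the 4 nt flank from one junction to the other, so a +k offset produces
exactly the intended pair of maximal hits. A planted pair represents an
interaction *enriched over random ligation*: the generator plants at least
`planted_min_enrichment` (default 5) times the expected background
co-ligation count of its two genes, so highly abundant gene pairs receive
proportionally more planted reads — without this the "interaction" of two
abundant genes can be weaker than their own random-ligation background,
which is not what a planted positive means.

Background chimeras join two fragments drawn independently with
probability proportional to gene abundance, so pair frequencies follow the
random-ligation expectation (a tested convergence property). Molecule
lengths are 40–100 nt (the size-selection range); paired-end reads of up
to 75 nt are synthesised over each molecule with a guaranteed mate overlap
of at least 10 nt, Phred-40 bases, and optional degraded tails or
substitution errors to exercise trimming and filtering. Sequencing error
defaults to zero because the mapper tolerates none; with errors enabled,
affected reads fail the exact merge or mapping and are discarded, never
misclassified (tested).

Everything is driven by one seed through a single generator, so identical
configurations produce byte-identical outputs.

What passing tests on this generator do **not** show about real data:
adapter contamination, quality-dependent error structure, strandedness,
transcription-unit structure (operons, processing sites), copy-number
variation between rRNA operons (a major source of real multi-mapping), or
any chemistry-driven bias in where cross-links and ligations occur.

## Problem sizes and calibration checks

The suite validates each non-trivial computation against an independent
oracle at sizes where the oracle is exact: the mapper against an
all-substrings scan (200 reads, 2.5 kb genome), the helix search against
an all-substring-pairs check (100 random 60-mer pairs), the Fisher test
against exact hypergeometric-tail enumeration (every 2×2 table with total
≤ 30 plus 500 random tables to total 500, agreement to 1e-12), and the
constrained folder against exhaustive structure enumeration (50 random
sequences up to 25 nt). Statistical calibration uses 20-seed batches:
background-only runs of 10,000 chimeras keep the fraction of tested window
pairs passing the full filter at or below 2%, and planted runs (5 pairs,
≥ 20 chimeras each, 2000 background chimeras on a 20 kb / 20-gene genome)
achieve ≥ 95% transcript-pair sensitivity with at most one false call per
run. Calibration batches run with structure folding disabled — folding
annotates structures but does not feed the statistics — which keeps the
whole suite fast; determinism and energy checks run with folding on.

## Known limitations

* Reads requiring more than two parts (multiple ligations) are counted but
  never resolved.
* The internal energy model ranks duplexes by pair content only; absolute
  energies are not nearest-neighbour free energies (plug in the ViennaRNA
  engine for those).
* The Fisher table and the token-counting rule (midpoint assignment) are
  reasonable choices among several defensible ones; both are isolated
  behind small functions and pinned by tests.
* Gene assignment is strand-agnostic; stranded libraries would justify a
  strand-aware assignment.
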