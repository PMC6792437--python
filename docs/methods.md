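# Methods

This note records the quantitative model behind each component, the
default parameters and why they were chosen, what the synthetic data
generator does and does not emulate, and the numerical conventions the
tests pin down.

## 1. Synthetic communities and ground truth

The generator (`synth.py`) produces communities whose every property
is known, so estimator output can be compared to truth rather than to
another tool.

- **Genomes** are i.i.d. base draws with a specified GC fraction
  (default 0.5), GC split equally between G and C. Real genomes have
  k-mer structure, repeats and skew; i.i.d. backbones are deliberately
  the *hardest* case for false-positive ANI (unrelated genomes share
  essentially no 15-mers) and the cleanest case for truth bookkeeping.
- **Variants** apply independent per-site substitutions; the shift is
  drawn from {1,2,3} in code space so a mutated site is guaranteed to
  change. `mutate_genome` returns the *realized* divergence, which is
  what ANI is calibrated against (±0.2 percentage points), not the
  nominal rate.
- **Abundance profiles** are log-normal (σ = 1) per genome per
  sample. A planted redundant pair shares one base profile, the second
  member multiplied by log-normal noise with σ = 0.05 — the structure
  the abundance-correlation criterion of dereplication assumes.
  Columns are normalized to sum to 1.
- **Reads**: per sample, read origins are multinomial over genomes
  with probability proportional to abundance × genome length, so the
  expected recruited-read fraction *is* the truth abundance. Starts
  and strands are uniform; sequencing error is substitution-only at a
  fixed per-base rate (default 0.005, a short-read-like figure).
  Qualities are constant placeholders. No indels, no quality model, no
  chimeras, no coverage bias — the generator emulates the recruitment
  statistics, not an instrument.
- **Marker proteins** are random amino-acid strings (length 290,
  roughly nitrogenase-reductase-sized) with one instance of the
  bundled [4Fe-4S]-motif pattern embedded, labelled so the annotation
  rule can fire. Genes are produced by uniform-codon back-translation
  (bacterial code, table 11). Decoys are composition-preserving
  shuffles.

Defaults are study conditions: they were chosen from the model, not
tuned to outcomes. Problem sizes in tests and the acceptance script
(20–30 kb genomes, 10⁵ reads per sample) are the package's own choice
of a desk-scale regime in which every statistical signal the methods
rely on is comfortably above sampling noise.

## 2. Read recruitment and profiling

`map_reads` is a competitive ungapped mapper: exact 21-mer seeds at
the read's start, middle and end (both strands) propose
(reference, diagonal) candidates; each candidate is scored by full-read
ungapped comparison. A read maps when identity ≥ 0.95 over ≥ 0.9 of
its length; among tied best identities one placement is chosen
uniformly with a seeded generator, so shared reads between
near-identical genomes split evenly in expectation. Ungapped scoring
is adequate because the simulator is substitution-only; with indel
reads a gapped mapper should be substituted.

Coverage is accumulated with a difference array. The **Q2Q3 mean**
computes the 1st/3rd quartiles with linear interpolation (numpy
default, type 7) and averages the positions whose coverage lies in
[Q1, Q3] inclusive; a constant vector returns the plain mean. The
inclusive-band-by-value convention (rather than discarding a fixed 25%
of positions) is pinned by a brute-force oracle in the tests.

Relative abundance is recruited reads / total sample reads;
`cells_per_litre` multiplies by 5×10⁸ (≈ bacterial cells per litre of
surface seawater), e.g. 0.0014 → 700 000. Square-root transformation
is provided for display only; statistics run on raw abundances.

## 3. MAG statistics

N50 is the largest length L such that contigs ≥ L sum to at least half
the assembly. Completion = 100 × families present / collection size;
redundancy = 100 × Σ max(0, copies − 1) / collection size. A bin is a
MAG when completion > 70% **or** length > 2 Mbp (both strict). The
representative score is completion − redundancy.

## 4. Dereplication

Fragment ANI cuts the smaller genome (ties broken by id) into
consecutive 1000 bp fragments. Each fragment is anchored on the larger
genome by exact 15-mer seeds (majority-vote diagonal, both
orientations) and aligned with edlib's banded infix edit distance over
a ±50 bp padded window, capped at edit distance ⌈0.2 × len⌉. Fragments
with identity ≥ 0.8 are retained; ANI is their mean identity and
aligned fraction is retained bases / smaller-genome length. Seed-based
anchoring makes the computation near-linear; at the ≥ 99% identity
regime that matters for dereplication, 15-mer anchors are effectively
always found, and calibration against realized divergence is within
±0.2 percentage points at substitution rates up to 5%.

Two MAGs are redundant iff ANI ≥ 99.0 (inclusive: "reached 99%") AND
aligned fraction > 0.75 (strict) AND Pearson r of abundance profiles
> 0.9 (strict). An undefined correlation (constant profile) fails the
criterion. Redundancy groups are connected components of that
relation; note the relation is not transitive, so a component may
contain pairs that fail pairwise — the component convention is pinned
against a transitive-closure oracle. Representatives maximize
completion − redundancy (bacteria/archaea) or total length (eukarya),
ties broken by length then id.

## 5. nifH screen

Candidate genes are translated in six frames (partial codons
trimmed). Each frame is aligned to every reference protein with local
Smith–Waterman, BLOSUM62, gap open 11 / extend 1 under the convention
that a gap of length L costs 11 + (L−1)×1. Significance uses the
Karlin–Altschul formula E = K·m·n·exp(−λS) with the standard ungapped
BLOSUM62 parameters λ = 0.3176, K = 0.134, m the frame length and n
the summed database length. The verdict requires E < 10⁻⁵⁰, the best
hit's description to contain "nitrogenase" (case-insensitive), and the
best frame to contain the [4Fe-4S] PROSITE signature.

The PROSITE engine parses the standard syntax (x, literals, [sets],
{negated sets}, (n) and (n,m) repeats, `<`/`>` anchors) and scans with
backtracking, trying fewer repeats first; it is verified against a
regex translation on randomized patterns. The bundled pattern
`C-x(2)-C-x(4)-[LIVMF]-x(2)-[ST]-x(3)-C` is a synthetic stand-in with
the documented cysteine spacing character, not the curated signature;
real screens should supply the curated pattern file.

`recruited_read_identity` reports per-read best local nucleotide
identity (match +1 / mismatch −1 / gap −2; identity = matches /
alignment columns), excluding alignments shorter than 100 columns —
the minimum-alignment-length convention of blastn-style read checks.
Mean identity recovers 100 × (1 − error rate) within ±0.5 points.

## 6. Primer audit

Primers and genes are encoded as 4-bit IUPAC base sets; a position
mismatches when the sets are disjoint (so a degenerate primer base
matching any gene possibility is not a mismatch). All windows on both
strands are scanned via a sliding-window minimum; positions are
reported in plus-strand coordinates, ties resolved to the smallest
position with the plus strand first. Compatibility defaults to zero
tolerated mismatches — the conservative reading of whether a PCR
survey would recover the gene. The scanner equals a
minimum-over-expansion Hamming oracle on random degenerate primers.

## 7. Enrichment

Welch's unequal-variance t-test (scipy) with Welch–Satterthwaite
degrees of freedom compares raw abundances between sample groups;
identical constant groups return p = 1, and two different constant
groups raise an error rather than fabricate significance.
Benjamini–Hochberg adjustment uses statsmodels. Empirical type-I error
under the null sits in [0.03, 0.07] at α = 0.05 (2000 simulations),
and a 10× mean shift at realistic group sizes is detected at
p < 0.005 in ≥ 95% of replicates.

## 8. Pipeline and determinism

Stages communicate only through files in the output directory. Each
stage derives its seed as
`(global_seed × 1_000_003 + crc32(stage_name)) mod 2³¹`, so stages are
decorrelated but individually re-runnable. The resolved configuration
is written first; the report stage emits a manifest with the size and
SHA-256 of every artifact. Identical configuration + seed produces
byte-identical outputs, which the tests verify by hashing whole
directories.

## 9. Limitations

- Substitution-only error and mutation models; no indels in reads, so
  the ungapped mapper is matched to the generator.
- i.i.d. genome backbones: no repeats, operons, or compositional
  structure; ANI false-positive behaviour on repeat-rich genomes is
  untested.
- SCG counts are simulated tables, not called from sequence; gene
  calling and HMM family assignment are out of scope.
- Karlin–Altschul parameters are the standard ungapped BLOSUM62
  values applied to gapped scores — the usual pragmatic approximation,
  conservative at the 10⁻⁵⁰ threshold used here.
- The bundled motif and primers are synthetic stand-ins; conclusions
  about real primer coverage require the published primer sets as
  inputs.
- Desk-scale only: data structures are in-memory and the mapper is
  pure numpy/Python; the design favours auditability over throughput.
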