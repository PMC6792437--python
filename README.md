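# diazoscan

Discovery and quantification of heterotrophic bacterial diazotrophs
(nitrogen-fixing bacteria outside the cyanobacteria) in shotgun
metagenomes. The package implements the full desk-scale workflow —
simulate or ingest a community, recruit reads, profile abundance,
quality-score and dereplicate genome bins, screen for the nitrogenase
marker gene *nifH*, audit PCR primers, and test for between-region
enrichment — with a reproducible pipeline and a synthetic data
generator that carries its own ground truth.

## The scientific problem

Marine nitrogen fixation has traditionally been credited to
cyanobacteria, and surveys of it lean on PCR amplification of the
nitrogenase reductase gene *nifH*. Genome-resolved metagenomics offers
a PCR-free alternative: assemble and bin genomes directly from reads
(metagenome-assembled genomes, MAGs), then ask which populations carry
the nitrogen-fixation machinery and how abundant they are across
samples. That workflow needs several pieces of careful numerics:

- **Read recruitment.** Reads are mapped competitively against the
  genome collection; the fraction of a sample's reads recruited by a
  genome proxies the population's relative abundance, and
  `cells_per_litre = relative_abundance × 5×10⁸` converts it to a
  cell-density scale (assuming ~0.5 billion bacterial cells per litre
  of surface seawater).
- **Q2Q3 mean coverage.** Per-position coverage is trimmed to the
  interquartile band (positions with coverage below the 1st or above
  the 3rd quartile are excluded) before averaging, which suppresses
  non-specific recruitment to conserved regions.
- **Completion / redundancy.** Single-copy core gene (SCG) families
  give bin quality: completion = % of families present, redundancy =
  % of extra copies. A bin qualifies as a MAG when completion > 70%
  or length > 2 Mbp.
- **Dereplication.** Near-identical bins recovered from independent
  co-assemblies are merged when fragment-based average nucleotide
  identity (ANI) reaches 99% over more than 75% of the smaller genome
  *and* the Pearson correlation of their abundance profiles across
  samples exceeds 0.9. Connected components of that relation are
  redundancy groups; the representative is the member with the largest
  completion − redundancy (longest genome for eukaryotes).
- ***nifH* screen.** A candidate gene passes when (1) the best
  six-frame Smith–Waterman hit against a nitrogenase reference set has
  Karlin–Altschul E-value below 10⁻⁵⁰, (2) that hit's annotation
  contains "nitrogenase", and (3) the translation contains the
  nitrogenase-reductase [4Fe-4S]-binding PROSITE signature.
- **Primer audit.** Degenerate *nifH* primers are scanned against
  recovered genes with IUPAC-aware mismatch counting (a primer base
  matches when its base set intersects the gene's), flagging
  populations that standard PCR surveys would miss.
- **Enrichment.** Welch's unequal-variance t-test with
  Benjamini–Hochberg correction compares abundance between sample
  groups (e.g. ocean regions).

## Quick start

End-to-end demo on a synthetic community (8 genomes of which 3 are
planted near-identical variant pairs, 4 samples, 50 000 reads each;
~20 s on one CPU):

```bash
diazoscan all --seed 1 --outdir demo/
```

This writes, among others:

- `abundance.tsv` — recruited-read relative abundance per MAG per sample
- `cells_per_litre.tsv` — the same on the cell-density scale
- `mag_table.tsv` — length, N50, GC, completion, redundancy, MAG status
- `derep_groups.tsv` — redundancy groups with Reference/Redundant status
- `nifh_verdicts.tsv` — the three-part *nifH* screen per candidate gene
- `primer_compatibility.tsv` — primer-by-gene mismatch counts
- `enrichment.tsv` — Welch's test with BH-adjusted p-values
- `manifest.tsv` — sizes and SHA-256 checksums of every output

With seed 1 the dereplication stage recovers exactly the planted
structure — five groups, e.g.:

```
group_id   mag_id  status
group000   MAG00   Reference
group000   MAG05   Redundant
group001   MAG01   Redundant
group001   MAG06   Reference
...
```

and the screen separates the planted marker from a
composition-matched decoy:

```
gene_id    frame  best_ref        score  evalue        label_ok  motif_ok  verdict
gene_nifH  1      synth_nifh_000  1598   8.66385e-216  True      True      True
gene_decoy 3      synth_nifh_013  44     0.191613      True      False     False
```

Individual stages run separately (`diazoscan synth`, `recruit`,
`profile`, `mag_stats`, `derep`, `screen`, `primer_check`, `enrich`,
`report`) and accept a YAML config; `resolved_config.yaml` in the
output directory records every parameter actually used. Identical
config + seed gives byte-identical outputs.

## Library example

```python
from diazoscan import synth
from diazoscan.dereplication import fragment_ani

base = synth.generate_genome(30_000, 0.5, seed=31, genome_id="popA")
variant, divergence = synth.mutate_genome(base, 0.01, seed=32)
res = fragment_ani(base, variant)
print(f"realized divergence: {100*divergence:.3f}%")
print(f"ANI: {res.ani:.2f}%  aligned fraction: {res.aligned_fraction:.3f}")
```

```
realized divergence: 0.973%
ANI: 99.03%  aligned fraction: 1.000
```

## Testing

```bash
python -m pytest -q tests/
```

The suite (≈190 tests, ~3 min) checks every component against an
independent oracle or planted truth: the Q2Q3 trim against a
brute-force quartile oracle, Smith–Waterman against a plain O(nm)
dynamic program, the PROSITE scanner against a regex translation, the
dereplication partition against transitive closure, primer mismatches
against min-over-expansion Hamming distance, and Welch's test against
the closed-form formulas plus direct numerical integration of the
t density. `tests/test_acceptance.py` holds one end-to-end test per
headline guarantee.

## Layout

```
src/diazoscan/
  io.py            FASTA/FASTQ/SAM parsing and writing, config, logging
  synth.py         community simulator with ground truth; protein tools
  recruitment.py   competitive read mapper, coverage, Q2Q3, abundance
  mag_stats.py     N50, GC, completion/redundancy, MAG criteria
  dereplication.py fragment ANI, correlation, redundancy groups
  markers.py       six-frame SW screen, E-values, PROSITE scanner
  primers.py       IUPAC primer expansion and mismatch scanning
  enrichment.py    Welch's t-test, Benjamini–Hochberg
  pipeline.py      staged, seeded, manifest-producing pipeline
  cli.py           click command-line interface
  data/            synthetic stand-in motif and example primers
```

The bundled PROSITE motif and example primers are **synthetic
stand-ins** with known truth, not database or published sequences;
real screens should supply the curated pattern and primer set as
configuration inputs. See `docs/methods.md` for the full model,
parameter rationale, and limitations.
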