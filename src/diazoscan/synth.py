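"""Synthetic communities with known truth.

Every downstream stage of the pipeline (recruitment, dereplication,
marker screening, primer auditing, enrichment) is exercised against
communities built here: genomes of controlled length and GC, planted
single-copy and marker genes, near-identical genome variants at set
substitution rates, per-sample abundance profiles (correlated across
samples for redundant variants), and error-bearing short reads with
truth alignments.

The model is deliberately simple where the analysis does not depend on
realism: bases are i.i.d. given GC, mutations and sequencing errors are
substitution-only (keeping pairwise identity truths exact), and read
qualities are constant. All generators are deterministic under a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

from .io import AlignmentRecord, ReadRecord, SequenceRecord, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_DECODE = {65: 0, 67: 1, 71: 2, 84: 3}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode an ACGT string as uint8 codes 0..3."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = np.empty(arr.size, dtype=np.uint8)
    for byte, code in _DECODE.items():
        codes[arr == byte] = code
    return codes


def codes_to_seq(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


# ---------------------------------------------------------------------------
# genomes


def generate_genome(length: int, gc: float, seed, genome_id: str = "genome") -> SequenceRecord:
    """Draw an i.i.d. genome with P(G)+P(C)=gc, split equally within pairs."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc must be in [0,1], got {gc}")
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = _rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    codes = rng.choice(4, size=length, p=p).astype(np.uint8)
    return SequenceRecord(id=genome_id, residues=codes_to_seq(codes))


def mutate_genome(genome: SequenceRecord, sub_rate: float, seed) -> tuple[SequenceRecord, float]:
    """Substitute each position independently; return variant and realized divergence."""
    if not 0.0 <= sub_rate < 1.0:
        raise ValueError(f"sub_rate must be in [0,1), got {sub_rate}")
    rng = _rng(seed)
    codes = seq_to_codes(genome.residues)
    mask = rng.random(codes.size) < sub_rate
    # shift by 1..3 guarantees a *different* base
    shifts = rng.integers(1, 4, size=int(mask.sum()))
    codes = codes.copy()
    codes[mask] = (codes[mask] + shifts) % 4
    divergence = mask.sum() / codes.size
    return (
        SequenceRecord(id=f"{genome.id}_variant", residues=codes_to_seq(codes)),
        float(divergence),
    )


@dataclass
class FragmentedGenome:
    """Contigs retained from a genome, with their source intervals and truth."""

    contigs: list[SequenceRecord]
    intervals: list[tuple[int, int]]  # 0-based half-open on the source genome
    true_completeness: float


def fragment_genome(
    genome: SequenceRecord,
    target_completeness: float,
    contig_len_range: tuple[int, int],
    seed,
) -> FragmentedGenome:
    """Cut a genome into contigs and drop random ones down to a target fraction.

    The retained fraction lands within one contig length of the target
    (exactly 1.0 when target is 1.0).
    """
    if not 0.0 < target_completeness <= 1.0:
        raise ValueError("target_completeness must be in (0,1]")
    lo, hi = contig_len_range
    if hi > len(genome):
        raise ValueError("contig length range exceeds genome length")
    rng = _rng(seed)
    cuts: list[tuple[int, int]] = []
    pos = 0
    n = len(genome)
    while pos < n:
        step = int(rng.integers(lo, hi + 1))
        cuts.append((pos, min(pos + step, n)))
        pos += step
    keep = list(range(len(cuts)))
    retained = n
    order = rng.permutation(len(cuts)).tolist()
    for i in order:
        if retained / n <= target_completeness:
            break
        s, e = cuts[i]
        keep.remove(i)
        retained -= e - s
    keep.sort()
    contigs = [
        SequenceRecord(id=f"{genome.id}_c{i:04d}", residues=genome.residues[cuts[i][0]:cuts[i][1]])
        for i in keep
    ]
    return FragmentedGenome(
        contigs=contigs,
        intervals=[cuts[i] for i in keep],
        true_completeness=retained / n,
    )


@dataclass
class GenomeSpec:
    """Blueprint for one synthetic genome with planted genes."""

    id: str
    length: int
    gc: float = 0.5
    domain: str = "bacteria"
    planted_genes: list[tuple[str, str, int]] = field(default_factory=list)  # (gene_id, seq, offset)

    def __post_init__(self) -> None:
        for gid, seq, off in self.planted_genes:
            if off < 0 or off + len(seq) > self.length:
                raise ValueError(f"gene {gid} does not fit in genome {self.id}")


def build_genome(spec: GenomeSpec, seed) -> SequenceRecord:
    """Realize a GenomeSpec: random backbone with planted genes spliced in."""
    genome = generate_genome(spec.length, spec.gc, seed, genome_id=spec.id)
    residues = list(genome.residues)
    for gid, seq, off in spec.planted_genes:
        residues[off : off + len(seq)] = seq
    return SequenceRecord(id=spec.id, residues="".join(residues))


# ---------------------------------------------------------------------------
# abundances


def simulate_abundances(
    n_genomes: int,
    n_samples: int,
    redundant_pairs: list[tuple[int, int]] | None = None,
    correlated_noise_sd: float = 0.05,
    seed=0,
    lognormal_sigma: float = 1.0,
) -> np.ndarray:
    """Per-sample relative abundances (genomes x samples; columns sum to 1).

    Base profiles are log-normal per genome per sample. Each genome pair
    declared redundant shares one base profile, the second member seeing
    multiplicative log-normal noise of the stated sd — the structure the
    distribution-correlation dereplication criterion assumes.
    """
    rng = _rng(seed)
    base = rng.lognormal(mean=0.0, sigma=lognormal_sigma, size=(n_genomes, n_samples))
    for i, j in redundant_pairs or []:
        noise = rng.lognormal(mean=0.0, sigma=correlated_noise_sd, size=n_samples)
        base[j] = base[i] * noise
    return base / base.sum(axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# reads


@dataclass
class CommunitySpec:
    """A community to sequence: genomes, per-sample depth and composition."""

    genomes: list[SequenceRecord]
    samples: list[tuple[str, int, np.ndarray]]  # (sample_id, total_reads, abundance vector)
    read_length: int = 120
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for sid, total, ab in self.samples:
            ab = np.asarray(ab, dtype=float)
            if total < 1:
                raise ValueError(f"sample {sid}: total_reads must be >= 1")
            if np.any(ab < 0) or not np.isclose(ab.sum(), 1.0):
                raise ValueError(f"sample {sid}: abundance vector must be non-negative, sum 1")
        if any(self.read_length > len(g) for g in self.genomes):
            raise ValueError("read_length exceeds a genome length")


@dataclass
class TruthSet:
    """Ground truth for one simulated community."""

    read_origins: dict[str, list[tuple[str, str, int, str]]]  # sample -> (read_id, genome, pos, strand)
    sample_abundance: dict[str, np.ndarray]  # expected read fraction per genome
    pair_divergence: dict[tuple[str, str], float] = field(default_factory=dict)
    completeness: dict[str, float] = field(default_factory=dict)


def simulate_reads(
    community: CommunitySpec,
) -> tuple[dict[str, list[ReadRecord]], dict[str, list[AlignmentRecord]], TruthSet]:
    """Draw error-bearing reads per sample plus truth alignments.

    Read origins are multinomial over genomes with probability
    abundance x genome length (renormalized), so the expected recruited
    read fraction *is* the truth abundance; starts and strands uniform;
    substitution errors at ``error_rate``.
    """
    rng = _rng(community.seed)
    rl = community.read_length
    lengths = np.array([len(g) for g in community.genomes], dtype=float)
    codes = [seq_to_codes(g.residues) for g in community.genomes]
    reads_by_sample: dict[str, list[ReadRecord]] = {}
    truth_by_sample: dict[str, list[AlignmentRecord]] = {}
    truth_abund: dict[str, np.ndarray] = {}
    origins: dict[str, list[tuple[str, str, int, str]]] = {}
    qual = "I" * rl
    for sid, total, ab in community.samples:
        ab = np.asarray(ab, dtype=float)
        probs = ab * lengths
        probs = probs / probs.sum()
        truth_abund[sid] = probs
        counts = rng.multinomial(total, probs)
        reads: list[ReadRecord] = []
        truth: list[AlignmentRecord] = []
        orig: list[tuple[str, str, int, str]] = []
        serial = 0
        for gi, n_reads in enumerate(counts):
            if n_reads == 0:
                continue
            g = community.genomes[gi]
            starts = rng.integers(0, len(g) - rl + 1, size=n_reads)
            strands = rng.integers(0, 2, size=n_reads)
            mat = codes[gi][starts[:, None] + np.arange(rl)[None, :]].copy()
            rev = strands == 1
            if rev.any():
                mat[rev] = (3 - mat[rev])[:, ::-1]  # reverse complement in code space
            if community.error_rate > 0:
                mask = rng.random(mat.shape) < community.error_rate
                shifts = rng.integers(1, 4, size=int(mask.sum()))
                mat[mask] = (mat[mask] + shifts) % 4
            for k in range(n_reads):
                rid = f"{sid}_r{serial:07d}"
                serial += 1
                strand = "-" if strands[k] else "+"
                reads.append(ReadRecord(id=rid, residues=codes_to_seq(mat[k]), qualities=qual))
                truth.append(
                    AlignmentRecord(
                        read_id=rid,
                        ref_id=g.id,
                        ref_start=int(starts[k]),
                        strand=strand,
                        aligned_length=rl,
                        edit_distance=None,
                        is_mapped=True,
                    )
                )
                orig.append((rid, g.id, int(starts[k]), strand))
        # restore a shuffled sample-wide order so genomes are interleaved
        order = rng.permutation(len(reads))
        reads_by_sample[sid] = [reads[i] for i in order]
        truth_by_sample[sid] = [truth[i] for i in order]
        origins[sid] = [orig[i] for i in order]
    return reads_by_sample, truth_by_sample, TruthSet(read_origins=origins, sample_abundance=truth_abund)


# ---------------------------------------------------------------------------
# marker proteins and genes

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]


def _codons_by_aa() -> dict[str, list[str]]:
    by_aa: dict[str, list[str]] = {}
    for codon, aa in _TABLE11.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    by_aa["*"] = list(_TABLE11.stop_codons)
    return {aa: sorted(cods) for aa, cods in by_aa.items()}


_CODONS = _codons_by_aa()


def reverse_translate(protein: str, seed) -> str:
    """Back-translate with uniform codon choice (bacterial code, table 11)."""
    rng = _rng(seed)
    parts = []
    for aa in protein:
        cods = _CODONS[aa]
        parts.append(cods[int(rng.integers(len(cods)))])
    return "".join(parts)


def motif_instance(pattern, seed) -> str:
    """A concrete amino-acid string matching a parsed PROSITE pattern."""
    rng = _rng(seed)
    out = []
    for elem in pattern.elements:
        count = elem.min_count
        for _ in range(count):
            if elem.kind == "any":
                out.append(AMINO_ACIDS[int(rng.integers(20))])
            elif elem.kind == "set":
                choices = sorted(elem.residues)
                out.append(choices[int(rng.integers(len(choices)))])
            else:  # negated set
                choices = sorted(set(AMINO_ACIDS) - elem.residues)
                out.append(choices[int(rng.integers(len(choices)))])
    return "".join(out)


def make_reference_proteins(
    n: int,
    pattern,
    length: int = 290,
    seed=0,
    label: str = "nitrogenase reductase NifH-like protein (synthetic)",
    id_prefix: str = "synth_nifh",
) -> list[SequenceRecord]:
    """SYNTHETIC nitrogenase-reductase-like reference proteins.

    Each protein is a random amino-acid string with one instance of the
    supplied [4Fe-4S]-motif pattern embedded at a random internal
    position, described with a label containing 'nitrogenase'. These are
    synthetic stand-ins with known truth, not database sequences.
    """
    rng = _rng(seed)
    records = []
    for i in range(n):
        core = motif_instance(pattern, rng)
        flank = length - len(core)
        pos = int(rng.integers(20, max(21, flank - 20)))
        aas = [AMINO_ACIDS[int(k)] for k in rng.integers(20, size=flank)]
        prot = "".join(aas[:pos]) + core + "".join(aas[pos:])
        records.append(SequenceRecord(id=f"{id_prefix}_{i:03d}", residues=prot, description=label))
    return records


def mutate_protein(protein: str, rate: float, seed, keep: tuple[int, int] | None = None) -> str:
    """Substitute residues at the given rate, optionally preserving a span.

    ``keep`` protects a half-open interval (e.g. the planted motif) so
    divergence does not destroy the property under test.
    """
    rng = _rng(seed)
    out = list(protein)
    for i in range(len(out)):
        if keep and keep[0] <= i < keep[1]:
            continue
        if rng.random() < rate:
            choices = AMINO_ACIDS.replace(out[i], "") if out[i] in AMINO_ACIDS else AMINO_ACIDS
            out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def shuffle_sequence(seq: str, seed) -> str:
    """Composition-preserving shuffle (decoy generator)."""
    rng = _rng(seed)
    chars = list(seq)
    rng.shuffle(chars)
    return "".join(chars)
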