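"""Competitive read recruitment and its summary statistics.

Reads are assigned to at most one reference each — the one maximizing
full-read identity after exact k-mer seeding and ungapped extension on
both strands — emulating competitive mapping against a concatenated
reference collection. Coverage summaries include the quartile-trimmed
(Q2Q3) mean, which suppresses the effect of non-specific recruitment
spikes, detection (breadth of coverage), recruited-read relative
abundance and its conversion to cells per litre.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AlignmentRecord, SequenceRecord

# assumed prokaryotic cell density of surface seawater, cells per litre
DEFAULT_CELL_DENSITY = 5e8


# ---------------------------------------------------------------------------
# mapping


class ReferenceIndex:
    """Exact k-mer index over a reference collection."""

    def __init__(self, references: list[SequenceRecord], k: int = 21):
        if not references:
            raise ValueError("empty reference set")
        self.k = k
        self.names = [r.id for r in references]
        self.lengths = {r.id: len(r) for r in references}
        self.arrays = [np.frombuffer(r.residues.encode(), dtype=np.uint8) for r in references]
        self.index: dict[bytes, list[tuple[int, int]]] = {}
        for ri, r in enumerate(references):
            enc = r.residues.encode()
            for pos in range(0, len(enc) - k + 1):
                self.index.setdefault(enc[pos : pos + k], []).append((ri, pos))


_RC_TABLE = bytes.maketrans(b"ACGTN", b"TGCAN")


def _revcomp_bytes(seq: bytes) -> bytes:
    return seq.translate(_RC_TABLE)[::-1]


def map_reads(
    reads,
    references: list[SequenceRecord] | ReferenceIndex,
    k: int = 21,
    min_identity: float = 0.95,
    min_aligned_fraction: float = 0.9,
    seed: int = 0,
) -> list[AlignmentRecord]:
    """Competitively assign each read to its best reference, if any.

    Candidate placements come from exact k-mer seeds (read start, middle
    and end, both strands); each candidate is scored by ungapped
    extension over the full read. Reads failing ``min_identity`` or
    ``min_aligned_fraction`` are unmapped; identity ties are broken
    uniformly at random with the seeded generator.
    """
    idx = references if isinstance(references, ReferenceIndex) else ReferenceIndex(references, k=k)
    k = idx.k
    rng = np.random.default_rng(seed)
    out: list[AlignmentRecord] = []
    for read in reads:
        seq = (read.residues if hasattr(read, "residues") else str(read)).encode()
        rl = len(seq)
        if rl < k:
            out.append(AlignmentRecord(read_id=read.id, is_mapped=False))
            continue
        offsets = sorted({0, (rl - k) // 2, rl - k})
        best_ident = -1.0
        best: list[tuple[int, int, int, int, str]] = []  # ref, start, overlap, mismatches, strand
        for strand, oriented in (("+", seq), ("-", _revcomp_bytes(seq))):
            rarr = np.frombuffer(oriented, dtype=np.uint8)
            candidates: set[tuple[int, int]] = set()
            for off in offsets:
                for ri, pos in idx.index.get(oriented[off : off + k], ()):
                    candidates.add((ri, pos - off))
            for ri, diag in candidates:
                ref = idx.arrays[ri]
                s = max(0, diag)
                e = min(len(ref), diag + rl)
                overlap = e - s
                if overlap < min_aligned_fraction * rl:
                    continue
                mism = int(np.count_nonzero(ref[s:e] != rarr[s - diag : e - diag]))
                ident = 1.0 - mism / overlap
                if ident < min_identity:
                    continue
                key = (ri, s, overlap, mism, strand)
                if ident > best_ident + 1e-12:
                    best_ident = ident
                    best = [key]
                elif abs(ident - best_ident) <= 1e-12:
                    best.append(key)
        if not best:
            out.append(AlignmentRecord(read_id=read.id, is_mapped=False))
            continue
        # competitive tie-break: uniform over distinct (reference, placement)
        ri, s, overlap, mism, strand = best[int(rng.integers(len(best)))] if len(best) > 1 else best[0]
        out.append(
            AlignmentRecord(
                read_id=read.id,
                ref_id=idx.names[ri],
                ref_start=s,
                strand=strand,
                aligned_length=overlap,
                edit_distance=mism,
                is_mapped=True,
            )
        )
    return out


# ---------------------------------------------------------------------------
# coverage statistics


@dataclass
class CoverageVector:
    """Per-position read coverage of one reference in one sample."""

    ref_id: str
    sample_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if np.any(self.values < 0):
            raise ValueError("negative coverage")


@dataclass
class RecruitmentSummary:
    ref_id: str
    sample_id: str
    mean_coverage: float
    q2q3_mean_coverage: float
    detection: float
    reads_recruited: int


def coverage_from_alignments(alignments, ref_id: str, ref_length: int, sample_id: str = "") -> CoverageVector:
    """Stack mapped alignment intervals into a per-position depth vector."""
    delta = np.zeros(ref_length + 1, dtype=np.int64)
    for aln in alignments:
        if not aln.is_mapped or aln.ref_id != ref_id:
            continue
        end = aln.ref_start + aln.aligned_length
        if aln.ref_start < 0 or end > ref_length:
            raise ValueError(f"alignment {aln.read_id} extends past reference end")
        delta[aln.ref_start] += 1
        delta[end] -= 1
    return CoverageVector(ref_id=ref_id, sample_id=sample_id, values=np.cumsum(delta[:-1]))


def q2q3_mean_coverage(cov: CoverageVector | np.ndarray) -> float:
    """Mean coverage after trimming positions in the 1st and 4th quartiles.

    Quartiles use the linear-interpolation ("type 7") convention;
    positions with value strictly below Q1 or strictly above Q3 are
    excluded. Constant vectors return the plain mean.
    """
    values = cov.values if isinstance(cov, CoverageVector) else np.asarray(cov)
    if values.size == 0:
        raise ValueError("empty coverage vector")
    q1, q3 = np.percentile(values, [25, 75], method="linear")
    mask = (values >= q1) & (values <= q3)
    if not mask.any():
        return float(values.mean())
    return float(values[mask].mean())


def detection(cov: CoverageVector | np.ndarray, min_cov: int = 1) -> float:
    """Fraction of reference positions covered at least ``min_cov``-fold."""
    values = cov.values if isinstance(cov, CoverageVector) else np.asarray(cov)
    if values.size == 0:
        raise ValueError("empty coverage vector")
    return float(np.mean(values >= min_cov))


def relative_abundance(reads_recruited: int, total_sample_reads: int) -> float:
    """Recruited-read fraction, the abundance proxy for a population."""
    if total_sample_reads < 1:
        raise ValueError("total_sample_reads must be >= 1")
    if reads_recruited < 0 or reads_recruited > total_sample_reads:
        raise ValueError("reads_recruited outside [0, total]")
    return reads_recruited / total_sample_reads


def cells_per_litre(rel_abundance: float, cell_density: float = DEFAULT_CELL_DENSITY) -> float:
    """Scale a read fraction by the assumed per-litre prokaryotic cell count."""
    if not 0.0 <= rel_abundance <= 1.0:
        raise ValueError("rel_abundance must be in [0,1]")
    return rel_abundance * cell_density


def sqrt_normalize(x):
    """Element-wise square root, the display transform for abundance tables."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("negative input")
    out = np.sqrt(arr)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def summarize_sample(
    alignments,
    references: list[SequenceRecord],
    sample_id: str,
    total_sample_reads: int,
    min_cov: int = 1,
) -> list[RecruitmentSummary]:
    """Per-reference recruitment summary for one sample."""
    by_ref: dict[str, list] = {r.id: [] for r in references}
    for aln in alignments:
        if aln.is_mapped and aln.ref_id in by_ref:
            by_ref[aln.ref_id].append(aln)
    out = []
    for ref in references:
        cov = coverage_from_alignments(by_ref[ref.id], ref.id, len(ref), sample_id=sample_id)
        out.append(
            RecruitmentSummary(
                ref_id=ref.id,
                sample_id=sample_id,
                mean_coverage=float(cov.values.mean()),
                q2q3_mean_coverage=q2q3_mean_coverage(cov),
                detection=detection(cov, min_cov=min_cov),
                reads_recruited=len(by_ref[ref.id]),
            )
        )
    return out
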