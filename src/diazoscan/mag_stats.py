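"""Per-MAG assembly and quality statistics.

Length, N50, GC, single-copy-gene (SCG) completion and redundancy, the
MAG definition rule (>70% completeness OR >2 Mbp, both strict), and the
representative score (completion minus redundancy) used when choosing
one genome out of a redundant group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import SequenceRecord

_UNAMBIGUOUS = frozenset("ACGT")

MAG_COMPLETENESS_MIN = 70.0  # percent, strict
MAG_LENGTH_MIN = 2_000_000  # bp, strict


def contig_n50(lengths) -> int:
    """Smallest contig length whose descending cumulative sum reaches half the assembly."""
    lengths = list(lengths)
    if not lengths:
        raise ValueError("empty length list")
    if any(l < 1 for l in lengths):
        raise ValueError("contig lengths must be >= 1")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for l in ordered:
        acc += l
        if acc >= half:
            return l
    raise AssertionError("unreachable")


def gc_content(records) -> float:
    """Percent G+C over all contigs pooled; ambiguous IUPAC bases excluded."""
    gc = 0
    total = 0
    for rec in records:
        seq = rec.residues if isinstance(rec, SequenceRecord) else str(rec)
        for base in seq.upper():
            if base in _UNAMBIGUOUS:
                total += 1
                if base in "GC":
                    gc += 1
    if total == 0:
        raise ValueError("no unambiguous bases")
    return 100.0 * gc / total


@dataclass
class ScgProfile:
    """Single-copy-gene family occurrence counts for one MAG."""

    mag_id: str
    counts: dict[str, int]
    collection_size: int

    def __post_init__(self) -> None:
        if self.collection_size < 1:
            raise ValueError("collection_size must be >= 1")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative SCG count")


def completion_redundancy(profile: ScgProfile) -> tuple[float, float]:
    """Completion = % families present; redundancy = % extra copies.

    completion = 100 x |{families with count >= 1}| / D
    redundancy = 100 x sum(max(0, count - 1)) / D
    """
    d = profile.collection_size
    present = sum(1 for c in profile.counts.values() if c >= 1)
    extra = sum(max(0, c - 1) for c in profile.counts.values())
    return 100.0 * present / d, 100.0 * extra / d


def is_mag(completion: float, total_length: int) -> bool:
    """A bin qualifies as a MAG when completion > 70% or length > 2 Mbp (strict)."""
    return completion > MAG_COMPLETENESS_MIN or total_length > MAG_LENGTH_MIN


def representative_score(completion: float, redundancy: float) -> float:
    """'Completion minus redundancy', the representative-choice score."""
    return completion - redundancy


@dataclass
class MagRecord:
    """Table-shaped per-MAG summary."""

    mag_id: str
    total_length: int
    n_contigs: int
    n50: int
    gc: float
    completion: float
    redundancy: float
    domain: str = "bacteria"
    contigs: list[SequenceRecord] = field(default_factory=list, repr=False)


def mag_record(
    mag_id: str,
    contigs: list[SequenceRecord],
    scg: ScgProfile | None = None,
    domain: str = "bacteria",
) -> MagRecord:
    """Assemble the per-MAG statistics row from contigs and SCG counts."""
    lengths = [len(c) for c in contigs]
    completion, redundancy = completion_redundancy(scg) if scg else (float("nan"), float("nan"))
    return MagRecord(
        mag_id=mag_id,
        total_length=int(sum(lengths)),
        n_contigs=len(contigs),
        n50=contig_n50(lengths),
        gc=gc_content(contigs),
        completion=completion,
        redundancy=redundancy,
        domain=domain,
        contigs=contigs,
    )
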