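"""Readers and writers for the plain-text formats the pipeline consumes.

Sequence collections travel as FASTA/FASTQ, read placements as SAM.
Internally every coordinate is 0-based, half-open; 1-based coordinates
exist only at the SAM boundary. Nucleotide sequences accept the full
IUPAC code set (lowercase is normalized to uppercase at parse time).
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam
import yaml
from Bio import SeqIO

log = logging.getLogger("diazoscan")

NUCLEOTIDE_ALPHABET = frozenset("ACGTUNRYSWKMBDHV")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYBXZJUO*")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class SequenceRecord:
    """A named sequence (genome, contig, gene, or reference protein)."""

    id: str
    residues: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ReadRecord:
    """A sequencing read with per-base Sanger-encoded qualities."""

    id: str
    residues: str
    qualities: str
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.residues):
            raise ParseError(
                f"read {self.id!r}: qualities length {len(self.qualities)} "
                f"!= sequence length {len(self.residues)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class AlignmentRecord:
    """Placement of one read on one reference (0-based, half-open)."""

    read_id: str
    ref_id: str | None = None
    ref_start: int = 0
    strand: str = "+"
    aligned_length: int = 0
    edit_distance: int | None = None
    is_mapped: bool = False

    def __post_init__(self) -> None:
        if self.is_mapped:
            if self.ref_start < 0:
                raise ValueError(f"{self.read_id}: negative ref_start")
            if self.aligned_length < 1:
                raise ValueError(f"{self.read_id}: mapped with aligned_length < 1")
            if self.edit_distance is not None and self.edit_distance > self.aligned_length:
                raise ValueError(f"{self.read_id}: edit_distance exceeds aligned_length")


def _check_alphabet(record_id: str, residues: str, alphabet: frozenset, ordinal: int) -> None:
    bad = set(residues) - alphabet
    if bad:
        raise ParseError(
            f"record #{ordinal} ({record_id!r}): illegal characters {sorted(bad)}"
        )


def read_fasta(path, alphabet: str | None = "nucleotide") -> list[SequenceRecord]:
    """Parse a FASTA file into SequenceRecords.

    ``alphabet`` is one of ``"nucleotide"``, ``"protein"`` or ``None``
    (no residue validation). Duplicate ids and alphabet violations are
    rejected.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise ParseError(f"{path}: empty file")
    with open(path) as fh:
        first = fh.read(1)
        if first != ">":
            raise ParseError(f"{path}: line 1: FASTA must begin with '>'")
    allowed = {"nucleotide": NUCLEOTIDE_ALPHABET, "protein": PROTEIN_ALPHABET, None: None}[alphabet]
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        residues = str(rec.seq).upper()
        if not residues:
            raise ParseError(f"record #{i} ({rec.id!r}): empty sequence")
        if rec.id in seen:
            raise ParseError(f"record #{i}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        if allowed is not None:
            _check_alphabet(rec.id, residues, allowed, i)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(SequenceRecord(id=rec.id, residues=residues, description=desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_fastq(path) -> list[ReadRecord]:
    """Parse 4-line FASTQ (Sanger qualities) into ReadRecords."""
    path = Path(path)
    reads: list[ReadRecord] = []
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                break
            lineno += 1
            if not header.startswith("@"):
                raise ParseError(f"{path}: line {lineno}: expected '@' header")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not plus.startswith("+") or not qual:
                raise ParseError(f"{path}: line {lineno}: truncated FASTQ record")
            lineno += 3
            name = header[1:].rstrip("\n").split(None, 1)
            rid = name[0]
            desc = name[1] if len(name) > 1 else ""
            if len(seq) != len(qual):
                raise ParseError(
                    f"{path}: line {lineno}: read {rid!r} sequence/quality length mismatch"
                )
            reads.append(ReadRecord(id=rid, residues=seq.upper(), qualities=qual, description=desc))
    return reads


def write_fastq(reads: Iterable[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            header = f"@{r.id} {r.description}".rstrip()
            fh.write(f"{header}\n{r.residues}\n+\n{r.qualities}\n")


# ---------------------------------------------------------------------------
# SAM


def _edit_distance_from_md(aln: pysam.AlignedSegment) -> int | None:
    if aln.has_tag("NM"):
        return int(aln.get_tag("NM"))
    if aln.has_tag("MD"):
        # substitutions + deletions from MD, insertions from CIGAR
        import re

        md = str(aln.get_tag("MD"))
        subs = len(re.findall(r"[ACGTN]", re.sub(r"\^[ACGTN]+", lambda m: "", md)))
        dels = sum(len(m) - 1 for m in re.findall(r"\^[ACGTN]+", md))
        ins = sum(l for op, l in aln.cigartuples if op == 1)
        return subs + dels + ins
    return None


def _validate_sam_refs(path) -> None:
    # pysam downgrades unknown RNAMEs to unmapped; reject them instead
    known: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("@"):
                if line.startswith("@SQ"):
                    for field in line.rstrip("\n").split("\t")[1:]:
                        if field.startswith("SN:"):
                            known.add(field[3:])
                continue
            fields = line.split("\t")
            if len(fields) > 2 and fields[2] not in ("*",) and fields[2] not in known:
                raise ParseError(f"{path}: line {lineno}: reference {fields[2]!r} absent from @SQ")


def read_alignments(path) -> list[AlignmentRecord]:
    """Parse a SAM text file into AlignmentRecords (0-based internally)."""
    _validate_sam_refs(path)
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=True) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped:
                records.append(AlignmentRecord(read_id=aln.query_name, is_mapped=False))
                continue
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    ref_id=aln.reference_name,
                    ref_start=aln.reference_start,
                    strand="-" if aln.is_reverse else "+",
                    aligned_length=aln.reference_length,
                    edit_distance=_edit_distance_from_md(aln),
                    is_mapped=True,
                )
            )
    return records


def write_alignments(
    alignments: Iterable[AlignmentRecord],
    ref_lengths: dict[str, int],
    path,
    sequences: dict[str, str] | None = None,
) -> None:
    """Write AlignmentRecords as SAM text (1-based at the boundary).

    Ungapped placements are encoded as a single M run. ``sequences``
    optionally maps read_id to the read sequence to embed in SEQ.
    """
    names = list(ref_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": ref_lengths[n]} for n in names],
    }
    idx = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in alignments:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.read_id
            if not rec.is_mapped:
                a.flag = 4
                a.reference_id = -1
                a.reference_start = -1
            else:
                a.flag = 16 if rec.strand == "-" else 0
                a.reference_id = idx[rec.ref_id]
                a.reference_start = rec.ref_start
                a.mapping_quality = 255
                a.cigarstring = f"{rec.aligned_length}M"
                if rec.edit_distance is not None:
                    a.set_tag("NM", rec.edit_distance)
            if sequences and rec.read_id in sequences:
                seq = sequences[rec.read_id]
                a.query_sequence = seq
                a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            out.write(a)


# ---------------------------------------------------------------------------
# configuration & logging


def load_config(path) -> dict:
    """Load a YAML config into a flat dict of named parameters."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return cfg


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


_RC = str.maketrans(
    "ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
    "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb",
)
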