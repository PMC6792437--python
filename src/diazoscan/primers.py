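"""Degenerate-primer expansion and in-silico matching against genes.

A degenerate primer written in IUPAC codes denotes a mixture of
concrete oligos. For each primer x gene pair the scanner slides the
primer over both strands and reports the window with the fewest
IUPAC-aware mismatches: a position mismatches when the base sets of
the primer code and the gene base do not intersect. A primer is
"compatible" with a gene when its best window has at most a configured
number of mismatches (default 0 — any mismatch disqualifies).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .io import SequenceRecord, reverse_complement

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_MASK = {code: sum(1 << "ACGT".index(b) for b in bases) for code, bases in IUPAC.items()}


@dataclass
class PrimerSpec:
    name: str
    sequence: str  # IUPAC nucleotide string
    orientation: str = "forward"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"primer {self.name}: empty sequence")
        bad = set(self.sequence) - set(IUPAC)
        if bad:
            raise ValueError(f"primer {self.name}: invalid IUPAC codes {sorted(bad)}")

    def degeneracy(self) -> int:
        n = 1
        for c in self.sequence:
            n *= len(IUPAC[c])
        return n


@dataclass
class PrimerMatch:
    primer: str
    gene_id: str
    strand: str | None  # None when the primer is longer than the gene
    position: int | None  # 0-based start in + strand gene coordinates
    mismatches: int | None
    compatible: bool


def iupac_expand(primer: PrimerSpec | str) -> set[str]:
    """All concrete sequences a degenerate primer denotes."""
    seq = primer.sequence if isinstance(primer, PrimerSpec) else str(primer).upper()
    bad = set(seq) - set(IUPAC)
    if bad:
        raise ValueError(f"invalid IUPAC codes {sorted(bad)}")
    return {"".join(combo) for combo in product(*(IUPAC[c] for c in seq))}


def _mask_array(seq: str) -> np.ndarray:
    return np.array([_MASK[c] for c in seq], dtype=np.uint8)


def _best_window(primer_mask: np.ndarray, gene_mask: np.ndarray) -> tuple[int, int] | None:
    """(mismatches, position) of the best window, smallest position on ties."""
    p = primer_mask.size
    if p > gene_mask.size:
        return None
    windows = np.lib.stride_tricks.sliding_window_view(gene_mask, p)
    mism = ((windows & primer_mask[None, :]) == 0).sum(axis=1)
    pos = int(np.argmin(mism))
    return int(mism[pos]), pos


def scan_primer(
    primer: PrimerSpec, gene: SequenceRecord, max_mismatch: int = 0
) -> PrimerMatch:
    """Best IUPAC-aware placement of a primer on either strand of a gene.

    A window position counts as a mismatch when the primer code's base
    set and the gene base's set are disjoint (gene ambiguity codes use
    the set-intersection rule). Ties prefer the smallest position, +
    strand first. Positions are reported in + strand coordinates.
    """
    pmask = _mask_array(primer.sequence)
    gene_seq = gene.residues.upper()
    bad = set(gene_seq) - set(IUPAC)
    if bad:
        raise ValueError(f"gene {gene.id}: invalid bases {sorted(bad)}")
    gmask = _mask_array(gene_seq)
    fwd = _best_window(pmask, gmask)
    if fwd is None:
        return PrimerMatch(primer.name, gene.id, None, None, None, False)
    rmask = _mask_array(reverse_complement(gene_seq))
    rev = _best_window(pmask, rmask)
    g, p = len(gene_seq), len(primer.sequence)
    candidates = [(fwd[0], 0, fwd[1], "+", fwd[1])]
    if rev is not None:
        candidates.append((rev[0], 1, rev[1], "-", g - p - rev[1]))
    mism, _, _, strand, plus_pos = min(candidates)
    return PrimerMatch(
        primer=primer.name,
        gene_id=gene.id,
        strand=strand,
        position=plus_pos,
        mismatches=mism,
        compatible=mism <= max_mismatch,
    )


def compatibility_report(
    primers: list[PrimerSpec], genes: list[SequenceRecord], max_mismatch: int = 0
) -> list[PrimerMatch]:
    """One best-match row per primer x gene."""
    if not primers or not genes:
        raise ValueError("primers and genes must be non-empty")
    return [scan_primer(p, gene, max_mismatch=max_mismatch) for p in primers for gene in genes]


def read_primer_tsv(path) -> list[PrimerSpec]:
    """Load primers from a TSV with columns: name, sequence[, orientation]."""
    primers = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].lower() == "name":
                continue
            orientation = fields[2] if len(fields) > 2 else "forward"
            primers.append(PrimerSpec(name=fields[0], sequence=fields[1], orientation=orientation))
    return primers
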