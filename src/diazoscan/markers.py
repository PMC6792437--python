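"""nifH-like marker screening.

A candidate nucleotide gene is accepted as a nitrogenase-reductase
(nifH) gene only when three conditions hold simultaneously:

1. its best translated local alignment against the reference protein
   set reaches an E-value below a threshold (default 1e-50),
2. the best-scoring reference's annotation contains a label keyword
   (default ``nitrogenase``), emulating a top-hit identity check, and
3. the characteristic [4Fe-4S]-binding site motif (PROSITE syntax) is
   present in the best reading frame's translation.

Translated search is exhaustive: all six frames are aligned with
Smith-Waterman (BLOSUM62, affine gaps) against every reference, which
is feasible at the gene-collection scales this package targets.
E-values use the Karlin-Altschul form E = K*m*n*exp(-lambda*S) with
config-pinned constants.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .io import SequenceRecord, reverse_complement

# ---------------------------------------------------------------------------
# six-frame translation


def six_frame_translate(seq: str) -> dict[int, str]:
    """Translate all six frames with the bacterial code (table 11).

    Keys are +1,+2,+3,-1,-2,-3; stops render as '*'; trailing partial
    codons are dropped.
    """
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    frames: dict[int, str] = {}
    rc = reverse_complement(seq)
    for off in range(3):
        fwd = seq[off : off + 3 * ((len(seq) - off) // 3)]
        rev = rc[off : off + 3 * ((len(rc) - off) // 3)]
        frames[off + 1] = str(Seq(fwd).translate(table=11))
        frames[-(off + 1)] = str(Seq(rev).translate(table=11))
    return frames


# ---------------------------------------------------------------------------
# Smith-Waterman (library-backed) and Karlin-Altschul E-value

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _aligner(matrix=_BLOSUM62, gap_open: int = 11, gap_extend: int = 1) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    # first gapped residue costs gap_open, each further one gap_extend
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def smith_waterman(
    protein_a: str,
    protein_b: str,
    gap_open: int = 11,
    gap_extend: int = 1,
    score_only: bool = False,
):
    """Optimal local alignment score under BLOSUM62 with affine gaps.

    A gap of length L costs ``gap_open + (L-1)*gap_extend``. Returns
    ``(score, (a_start, a_end), (b_start, b_end))`` with 0-based
    half-open coordinates, or just the score when ``score_only``.
    """
    if not protein_a or not protein_b:
        raise ValueError("empty sequence")
    alphabet = set(_BLOSUM62.alphabet)
    bad = (set(protein_a) | set(protein_b)) - alphabet
    if bad:
        raise ValueError(f"residues outside BLOSUM62 alphabet: {sorted(bad)}")
    aligner = _aligner(gap_open=gap_open, gap_extend=gap_extend)
    score = aligner.score(protein_a, protein_b)
    score = max(0.0, float(score))
    if score_only:
        return score
    if score == 0.0:
        return 0.0, (0, 0), (0, 0)
    aln = aligner.align(protein_a, protein_b)[0]
    a_span = (int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1]))
    b_span = (int(aln.aligned[1][0][0]), int(aln.aligned[1][-1][1]))
    return score, a_span, b_span


def karlin_altschul_evalue(
    score: float, query_len: int, db_len: int, lam: float = 0.3176, k: float = 0.134
) -> float:
    """E = K * m * n * exp(-lambda * S)."""
    if score < 0 or query_len < 1 or db_len < 1 or lam <= 0 or k <= 0:
        raise ValueError("invalid Karlin-Altschul inputs")
    return k * query_len * db_len * math.exp(-lam * score)


# ---------------------------------------------------------------------------
# PROSITE patterns


class PrositeSyntaxError(ValueError):
    pass


@dataclass(frozen=True)
class PrositeElement:
    kind: str  # "any" | "set" | "neg" | "literal" (literal stored as 1-residue set)
    residues: frozenset
    min_count: int = 1
    max_count: int = 1

    def allows(self, aa: str) -> bool:
        if self.kind == "any":
            return True
        if self.kind == "neg":
            return aa not in self.residues
        return aa in self.residues


@dataclass(frozen=True)
class PrositePattern:
    elements: tuple[PrositeElement, ...]
    n_anchored: bool = False
    c_anchored: bool = False
    source: str = ""

    def to_text(self) -> str:
        parts = []
        for e in self.elements:
            if e.kind == "any":
                tok = "x"
            elif e.kind == "neg":
                tok = "{" + "".join(sorted(e.residues)) + "}"
            elif len(e.residues) == 1:
                tok = next(iter(e.residues))
            else:
                tok = "[" + "".join(sorted(e.residues)) + "]"
            if (e.min_count, e.max_count) != (1, 1):
                if e.min_count == e.max_count:
                    tok += f"({e.min_count})"
                else:
                    tok += f"({e.min_count},{e.max_count})"
            parts.append(tok)
        body = "-".join(parts)
        return ("<" if self.n_anchored else "") + body + (">" if self.c_anchored else "")


_TOKEN_RE = re.compile(
    r"^(?P<body>x|[A-Za-z]|\[[A-Za-z]+\]|\{[A-Za-z]+\})(?:\((?P<n>\d+)(?:,(?P<m>\d+))?\))?$"
)


def prosite_parse(text: str) -> PrositePattern:
    """Parse PROSITE pattern syntax into a structured pattern.

    Supports residues, ``x``, ``[ABC]``, ``{ABC}``, repeat counts
    ``(n)`` / ``(n,m)``, hyphen separators, optional anchors ``<`` /
    ``>`` and an optional trailing period.
    """
    src = text.strip()
    body = src.rstrip(".")
    n_anchor = body.startswith("<")
    if n_anchor:
        body = body[1:]
    c_anchor = body.endswith(">")
    if c_anchor:
        body = body[:-1]
    if not body:
        raise PrositeSyntaxError("empty pattern")
    elements: list[PrositeElement] = []
    for pos, token in enumerate(body.split("-")):
        m = _TOKEN_RE.match(token.strip())
        if not m:
            raise PrositeSyntaxError(f"malformed token {token!r} at element {pos}")
        base = m.group("body")
        lo = int(m.group("n")) if m.group("n") else 1
        hi = int(m.group("m")) if m.group("m") else lo
        if lo < 1 or hi < lo:
            raise PrositeSyntaxError(f"bad repeat count in token {token!r} at element {pos}")
        if base == "x":
            elem = PrositeElement("any", frozenset(), lo, hi)
        elif base.startswith("["):
            elem = PrositeElement("set", frozenset(base[1:-1].upper()), lo, hi)
        elif base.startswith("{"):
            elem = PrositeElement("neg", frozenset(base[1:-1].upper()), lo, hi)
        else:
            elem = PrositeElement("set", frozenset(base.upper()), lo, hi)
        elements.append(elem)
    return PrositePattern(tuple(elements), n_anchor, c_anchor, source=src)


def _match_here(protein: str, elements, ei: int, pos: int, c_anchored: bool) -> int | None:
    """Backtracking matcher; tries fewer repeats first (regex non-greedy order).

    Returns the end position of the first successful match, else None.
    """
    if ei == len(elements):
        if c_anchored and pos != len(protein):
            return None
        return pos
    elem = elements[ei]
    for count in range(elem.min_count, elem.max_count + 1):
        end = pos + count
        if end > len(protein):
            break
        ok = all(elem.allows(protein[p]) for p in range(pos, end))
        if not ok:
            # a longer repeat only adds more positions; once one fails, longer fail too
            break
        result = _match_here(protein, elements, ei + 1, end, c_anchored)
        if result is not None:
            return result
    return None


def prosite_scan(protein: str, pattern: PrositePattern) -> list[tuple[int, int]]:
    """All 0-based start positions where the pattern matches.

    Returns (start, end) spans, one per matching start; for variable
    repeats the span is the first match in fewest-repeats-first order
    (equivalent to a non-greedy regex).
    """
    starts = [0] if pattern.n_anchored else range(len(protein) + 1)
    spans: list[tuple[int, int]] = []
    for s in starts:
        end = _match_here(protein, pattern.elements, 0, s, pattern.c_anchored)
        if end is not None:
            spans.append((s, end))
    return spans


# ---------------------------------------------------------------------------
# screening


@dataclass
class MarkerHit:
    """Screening verdict for one candidate gene."""

    gene_id: str
    best_ref_id: str | None
    score: float
    evalue: float
    frame: int
    top_hit_label_ok: bool
    motif_ok: bool

    @property
    def verdict(self) -> bool:
        return self.evalue < self.evalue_max and self.top_hit_label_ok and self.motif_ok

    evalue_max: float = 1e-50


def screen_gene(
    gene: SequenceRecord,
    refdb: list[SequenceRecord],
    motif: PrositePattern,
    evalue_max: float = 1e-50,
    label_keyword: str = "nitrogenase",
    lam: float = 0.3176,
    k: float = 0.134,
) -> MarkerHit:
    """Apply the three-part nifH rule to one candidate gene."""
    if not refdb:
        raise ValueError("empty reference database")
    if len(gene.residues) < 3:
        raise ValueError(f"gene {gene.id}: shorter than one codon")
    frames = six_frame_translate(gene.residues)
    db_len = sum(len(r) for r in refdb)
    best = (-1.0, None, None)  # score, frame, ref
    for frame, prot in frames.items():
        if not prot:
            continue
        for ref in refdb:
            s = smith_waterman(prot, ref.residues, score_only=True)
            if s > best[0]:
                best = (s, frame, ref)
    score, frame, ref = best
    prot = frames[frame]
    evalue = karlin_altschul_evalue(score, len(prot), db_len, lam=lam, k=k)
    label_ok = label_keyword.lower() in ref.description.lower()
    motif_ok = len(prosite_scan(prot, motif)) > 0
    return MarkerHit(
        gene_id=gene.id,
        best_ref_id=ref.id,
        score=score,
        evalue=evalue,
        frame=frame,
        top_hit_label_ok=label_ok,
        motif_ok=motif_ok,
        evalue_max=evalue_max,
    )


# ---------------------------------------------------------------------------
# recruited-read identity


@dataclass
class ReadIdentitySummary:
    gene_id: str
    n_reads: int
    mean_identity: float | None
    min_identity: float | None
    max_identity: float | None


def _nt_aligner(match: int = 1, mismatch: int = -1, gap: int = -2) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def recruited_read_identity(
    gene: SequenceRecord,
    reads,
    min_align_len: int = 100,
) -> ReadIdentitySummary:
    """Per-read best local nucleotide identity to the gene, summarized.

    Identity is 100 x matches / alignment columns of the best local
    alignment (match +1 / mismatch -1 / gap -2); alignments shorter than
    ``min_align_len`` columns are excluded, mirroring a blastn
    minimum-alignment-length rule.
    """
    aligner = _nt_aligner()
    identities = []
    for read in reads:
        seq = read.residues if hasattr(read, "residues") else str(read)
        best = None
        for candidate in (seq, reverse_complement(seq)):
            if aligner.score(gene.residues, candidate) <= 0:
                continue
            aln = aligner.align(gene.residues, candidate)[0]
            counts = aln.counts()
            columns = counts.identities + counts.mismatches + counts.gaps
            if columns < min_align_len:
                continue
            ident = 100.0 * counts.identities / columns
            if best is None or ident > best:
                best = ident
        if best is not None:
            identities.append(best)
    if not identities:
        return ReadIdentitySummary(gene.id, 0, None, None, None)
    return ReadIdentitySummary(
        gene.id,
        len(identities),
        float(sum(identities) / len(identities)),
        float(min(identities)),
        float(max(identities)),
    )
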