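import numpy as np
import pytest

from diazoscan import markers, pipeline, synth
from diazoscan.io import SequenceRecord


@pytest.fixture(scope="session")
def motif():
    return pipeline.bundled_motif()


@pytest.fixture(scope="session")
def refdb(motif):
    """Twenty synthetic nitrogenase-reductase-like reference proteins."""
    return synth.make_reference_proteins(20, motif, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


# ---------------------------------------------------------------------------
# independent oracles shared across test modules


def quartile_trim_oracle(values):
    """Brute-force Q2Q3-trimmed mean: type-7 quartiles computed by hand,
    then position-by-position membership marking."""
    v = sorted(float(x) for x in values)
    n = len(v)

    def quantile(p):
        h = (n - 1) * p
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return v[lo] + (h - lo) * (v[hi] - v[lo])

    q1, q3 = quantile(0.25), quantile(0.75)
    kept = [x for x in values if q1 <= x <= q3]
    if not kept:
        return float(np.mean(values))
    return sum(kept) / len(kept)


def sw_oracle(a, b, gap_open=11, gap_extend=1):
    """Plain O(n*m) affine-gap local alignment DP (Gotoh), no optimizations.

    Gap of length L costs gap_open + (L-1)*gap_extend, matching the
    implementation's convention.
    """
    mat = markers._BLOSUM62
    n, m = len(a), len(b)
    NEG = -1e9
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            s = mat[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def prosite_regex_oracle(protein, pattern_text):
    """Translate PROSITE syntax to a regex and find all overlapping matches.

    Non-greedy repeats reproduce fewest-repeats-first semantics.
    """
    import re

    body = pattern_text.strip().rstrip(".")
    n_anchor = body.startswith("<")
    if n_anchor:
        body = body[1:]
    c_anchor = body.endswith(">")
    if c_anchor:
        body = body[:-1]
    parts = []
    for token in body.split("-"):
        m = re.match(r"^(x|[A-Za-z]|\[[A-Za-z]+\]|\{[A-Za-z]+\})(?:\((\d+)(?:,(\d+))?\))?$", token)
        base, lo, hi = m.group(1), m.group(2), m.group(3)
        if base == "x":
            rx = "."
        elif base.startswith("["):
            rx = "[" + base[1:-1].upper() + "]"
        elif base.startswith("{"):
            rx = "[^" + base[1:-1].upper() + "]"
        else:
            rx = base.upper()
        if lo and hi:
            rx += "{" + lo + "," + hi + "}?"
        elif lo and int(lo) != 1:
            rx += "{" + lo + "}"
        parts.append(rx)
    rx = "".join(parts) + ("$" if c_anchor else "")
    compiled = re.compile("(?=(" + rx + "))")
    spans = []
    starts = [0] if n_anchor else range(len(protein) + 1)
    for s in starts:
        m = compiled.match(protein, s)
        if m:
            spans.append((s, s + len(m.group(1))))
    return spans


def random_prosite_pattern(rng):
    """A random small PROSITE pattern over the 20 amino acids."""
    aas = synth.AMINO_ACIDS
    n = int(rng.integers(2, 6))
    tokens = []
    for _ in range(n):
        kind = rng.integers(4)
        if kind == 0:
            tok = "x"
        elif kind == 1:
            tok = aas[int(rng.integers(20))]
        elif kind == 2:
            k = int(rng.integers(2, 5))
            tok = "[" + "".join(sorted(set(aas[int(i)] for i in rng.integers(20, size=k)))) + "]"
        else:
            k = int(rng.integers(1, 4))
            tok = "{" + "".join(sorted(set(aas[int(i)] for i in rng.integers(20, size=k)))) + "}"
        if rng.random() < 0.3:
            lo = int(rng.integers(1, 4))
            if rng.random() < 0.5:
                tok += f"({lo},{lo + int(rng.integers(0, 3))})"
            else:
                tok += f"({lo})"
        tokens.append(tok)
    body = "-".join(tokens)
    if rng.random() < 0.15:
        body = "<" + body
    if rng.random() < 0.15:
        body = body + ">"
    return body


def partition_closure_oracle(mag_ids, edge_predicate):
    """Brute-force transitive closure over a pairwise predicate."""
    n = len(mag_ids)
    adj = np.eye(n, dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if edge_predicate(mag_ids[i], mag_ids[j]):
                adj[i, j] = adj[j, i] = True
    closure = adj.copy()
    for _ in range(n):
        closure = closure | (closure @ closure)
    groups = set()
    for i in range(n):
        groups.add(frozenset(mag_ids[j] for j in range(n) if closure[i, j]))
    return groups


def make_read(genome: SequenceRecord, start: int, length: int, read_id="r0"):
    from diazoscan.io import ReadRecord

    seq = genome.residues[start : start + length]
    return ReadRecord(id=read_id, residues=seq, qualities="I" * length)
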