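"""Pairwise local protein alignment with substitution-matrix scoring and
Karlin-Altschul E/P-value estimation.

The aligner is an exact affine-gap Smith-Waterman.  Gap penalties follow the
NCBI convention for protein search defaults (open 11, extend 1: a gap of
length k costs 11 + k).  Statistics use the published gapped BLOSUM62/11/1
Karlin-Altschul constants (lambda = 0.267, K = 0.041) so that scores convert
to E-values comparable with practitioner expectations:

    E = K * m * n * exp(-lambda * S),     P = 1 - exp(-E)

The all-vs-all driver aligns every unordered pair once and emits one
undirected hit per pair passing the P-value cut; this feeds the cluster map.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigError
from .io import SimilarityHit

_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_CODE = {c: i for i, c in enumerate(_ALPHABET)}

DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1


def load_matrix(name_or_path: str = "BLOSUM62") -> np.ndarray:
    """Load a substitution matrix (by name or NCBI flat-format path) as a
    dense int array over the package alphabet (20 amino acids + X)."""
    from Bio.Align import substitution_matrices

    try:
        m = substitution_matrices.load(name_or_path)
    except (FileNotFoundError, ValueError):
        m = substitution_matrices.read(name_or_path)
    n = len(_ALPHABET)
    out = np.zeros((n, n), dtype=np.int64)
    for i, a in enumerate(_ALPHABET):
        for j, b in enumerate(_ALPHABET):
            try:
                out[i, j] = int(m[a, b])
            except (KeyError, IndexError):
                out[i, j] = -1
    return out


_BLOSUM62: np.ndarray | None = None


def blosum62() -> np.ndarray:
    global _BLOSUM62
    if _BLOSUM62 is None:
        _BLOSUM62 = load_matrix("BLOSUM62")
    return _BLOSUM62


def encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODE.get(c, _CODE["X"]) for c in seq), dtype=np.int64, count=len(seq))


@dataclass(frozen=True)
class KarlinAltschul:
    """Gapped Karlin-Altschul parameters (defaults: BLOSUM62, gaps 11/1)."""

    lam: float = 0.267
    K: float = 0.041

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.K <= 0:
            raise ConfigError(f"lambda and K must be positive, got {self.lam}, {self.K}")


@dataclass
class AlignmentResult:
    """Optimal local alignment of one pair."""

    score: int
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    identity_fraction: float  # identical columns / aligned columns
    n_identical: int
    alignment_length: int
    mismatches: int
    gap_opens: int
    evalue: float = float("nan")


# DP cell traceback codes: 0 stop, 1 diagonal, 2 up (gap in b), 3 left (gap in a)
def _sw_python(a, b, sub, gap_open, gap_extend):
    la, lb = len(a), len(b)
    NEG = -(10**9)
    H = np.zeros((la + 1, lb + 1), dtype=np.int64)
    E = np.full((la + 1, lb + 1), NEG, dtype=np.int64)  # gap in a (left)
    F = np.full((la + 1, lb + 1), NEG, dtype=np.int64)  # gap in b (up)
    best, bi, bj = 0, 0, 0
    go = gap_open + gap_extend
    for i in range(1, la + 1):
        Hi, Hm = H[i], H[i - 1]
        Ei, Fi, Fm = E[i], F[i], F[i - 1]
        ai = a[i - 1]
        for j in range(1, lb + 1):
            e = max(Hi[j - 1] - go, Ei[j - 1] - gap_extend)
            f = max(Hm[j] - go, Fm[j] - gap_extend)
            h = Hm[j - 1] + sub[ai, b[j - 1]]
            v = max(0, h, e, f)
            Ei[j] = e
            Fi[j] = f
            Hi[j] = v
            if v > best:
                best, bi, bj = v, i, j
    return H, E, F, best, bi, bj


try:  # optional acceleration; identical semantics
    from numba import njit

    _sw_numba = njit(cache=False)(_sw_python)
except Exception:  # pragma: no cover - numba present in supported envs
    _sw_numba = None


def _traceback(a, b, sub, gap_open, gap_extend, H, E, F, bi, bj):
    """Recover one optimal path ending at (bi, bj), preferring diagonal moves,
    then gaps in the subject, then gaps in the query (deterministic)."""
    go = gap_open + gap_extend
    i, j = bi, bj
    n_id = 0
    length = 0
    mismatches = 0
    gap_opens = 0
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            v = H[i, j]
            if v == 0:
                break
            if v == H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]:
                length += 1
                if a[i - 1] == b[j - 1]:
                    n_id += 1
                else:
                    mismatches += 1
                i -= 1
                j -= 1
            elif v == F[i, j]:
                state = "F"
            elif v == E[i, j]:
                state = "E"
            else:  # pragma: no cover - unreachable for consistent matrices
                break
        elif state == "F":  # gap in b, consume a
            length += 1
            if F[i, j] == H[i - 1, j] - go:
                gap_opens += 1
                state = "H"
            i -= 1
        else:  # "E": gap in a, consume b
            length += 1
            if E[i, j] == H[i, j - 1] - go:
                gap_opens += 1
                state = "H"
            j -= 1
    return i, j, n_id, length, mismatches, gap_opens


def sw_align(
    a: str,
    b: str,
    matrix: np.ndarray | None = None,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Optimal affine-gap Smith-Waterman alignment of two protein sequences.

    Ties between equally scoring end cells are broken toward the smaller query
    start (equivalently the first maximal cell in row-major order), making the
    result deterministic.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    sub = blosum62() if matrix is None else matrix
    ea, eb = encode(a), encode(b)
    engine = _sw_numba or _sw_python
    H, E, F, best, bi, bj = engine(ea, eb, sub, gap_open, gap_extend)
    if best <= 0:
        return AlignmentResult(0, (0, 0), (0, 0), 0.0, 0, 0, 0, 0)
    i0, j0, n_id, length, mism, gaps = _traceback(
        ea, eb, sub, gap_open, gap_extend, H, E, F, bi, bj
    )
    ident = n_id / length if length else 0.0
    return AlignmentResult(
        score=int(best),
        query_span=(i0, bi),
        subject_span=(j0, bj),
        identity_fraction=ident,
        n_identical=n_id,
        alignment_length=length,
        mismatches=mism,
        gap_opens=gaps,
    )


def estimate_evalue(
    score: int,
    query_len: int,
    db_len: int,
    params: KarlinAltschul = KarlinAltschul(),
) -> float:
    """Karlin-Altschul E-value for a raw local-alignment score."""
    if score < 0:
        raise ValueError("score must be non-negative")
    if query_len < 1 or db_len < 1:
        raise ValueError("lengths must be >= 1")
    return params.K * query_len * db_len * math.exp(-params.lam * score)


def pvalue_from_evalue(evalue: float) -> float:
    """P = 1 - exp(-E)."""
    return -math.expm1(-evalue)


def hit_from_alignment(
    query_id: str,
    subject_id: str,
    res: AlignmentResult,
    query_len: int,
    subject_len: int,
    params: KarlinAltschul = KarlinAltschul(),
) -> SimilarityHit:
    """Package an alignment as a BLAST-tabular-style hit (bitscore = raw
    score converted with the same lambda/K)."""
    evalue = estimate_evalue(res.score, query_len, subject_len, params)
    bitscore = (params.lam * res.score - math.log(params.K)) / math.log(2)
    return SimilarityHit(
        query_id=query_id,
        subject_id=subject_id,
        percent_identity=100.0 * res.identity_fraction,
        alignment_length=max(1, res.alignment_length),
        mismatches=res.mismatches,
        gap_opens=res.gap_opens,
        query_start=res.query_span[0],
        query_end=res.query_span[1],
        subject_start=res.subject_span[0],
        subject_end=res.subject_span[1],
        evalue=evalue,
        bitscore=bitscore,
    )


def all_vs_all(
    seqs: Sequence[tuple[str, str]],
    max_p: float = 1e-06,
    matrix: np.ndarray | None = None,
    params: KarlinAltschul = KarlinAltschul(),
) -> list[SimilarityHit]:
    """Align every unordered pair of (id, sequence) once; emit one undirected
    hit per pair with P <= max_p.  Self-pairs are excluded.  The hit set is
    independent of input order (pairs are aligned with the lexicographically
    ordered orientation)."""
    if len(seqs) < 2:
        return []
    hits: list[SimilarityHit] = []
    indexed = sorted(range(len(seqs)), key=lambda i: seqs[i][0])
    for ii, jj in itertools.combinations(indexed, 2):
        qid, qseq = seqs[ii]
        sid, sseq = seqs[jj]
        res = sw_align(qseq, sseq, matrix)
        if res.score <= 0:
            continue
        evalue = estimate_evalue(res.score, len(qseq), len(sseq), params)
        if pvalue_from_evalue(evalue) <= max_p:
            hits.append(hit_from_alignment(qid, sid, res, len(qseq), len(sseq), params))
    return hits
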