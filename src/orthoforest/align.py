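"""Optimal local alignment with affine gap penalties.

This is the scoring primitive behind the forest/population analysis: a
full dynamic-programming Smith–Waterman (Gotoh three-state recurrence) over
a named substitution matrix. A gap of length k costs
``gap_open + (k-1) * gap_extend`` — the opening penalty is charged on the
first gap position and the extension penalty on each subsequent one.

The DP is written as plain nested loops and jitted with numba; the same
function runs un-jitted if numba is unavailable. This reference
implementation is authoritative; heuristic or SIMD aligners are
deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

NEG_INF = np.iinfo(np.int64).min // 4


@lru_cache(maxsize=None)
def load_matrix(name: str) -> tuple[str, np.ndarray]:
    """A named substitution matrix as (alphabet, square int array)."""
    m = substitution_matrices.load(name)
    alphabet = str(m.alphabet)
    arr = np.asarray(m, dtype=np.int64)
    return alphabet, arr


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring parameters for pairwise local alignment.

    ``gap_open`` is the cost of the first position of a gap, ``gap_extend``
    of each further position; both are non-negative with extend ≤ open.
    ``num_aln``/``min_score`` bound the number and quality of reported
    suboptimal alignments when enumeration is requested (off by default:
    only the single optimal alignment feeds the forest).
    """

    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    num_aln: int = 1
    min_score: int = 0

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must be <= gap_open")
        if self.num_aln < 1:
            raise ValueError("num_aln must be >= 1")

    def encode(self, seq: str) -> np.ndarray:
        alphabet, _ = load_matrix(self.matrix)
        idx = np.empty(len(seq), dtype=np.int64)
        for i, ch in enumerate(seq):
            pos = alphabet.find(ch)
            if pos < 0:
                raise ValueError(
                    f"character {ch!r} absent from matrix {self.matrix}"
                )
            idx[i] = pos
        return idx

    @property
    def score_matrix(self) -> np.ndarray:
        return load_matrix(self.matrix)[1]


@dataclass
class LocalAlignmentResult:
    """One local alignment: score, spans and gapped aligned strings.

    Spans are 0-based half-open intervals into the original sequences; the
    empty alignment (score 0, empty spans) is returned when no
    positive-scoring cell exists.
    """

    score: int
    query_span: tuple[int, int] = (0, 0)
    ref_span: tuple[int, int] = (0, 0)
    aligned_query: str = ""
    aligned_ref: str = ""

    def __post_init__(self) -> None:
        assert self.score >= 0
        assert len(self.aligned_query) == len(self.aligned_ref)


@njit(cache=True)
def _sw_fill(q, r, sub, gap_open, gap_extend):  # pragma: no cover - jitted
    n, m = len(q), len(r)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG_INF, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG_INF, dtype=np.int64)
    best = 0
    bi, bj = 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_extend)
            f = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_extend)
            h = H[i - 1, j - 1] + sub[q[i - 1], r[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            E[i, j] = e
            F[i, j] = f
            H[i, j] = h
            if h > best:
                best = h
                bi, bj = i, j
    return H, E, F, best, bi, bj


@njit(cache=True)
def _sw_score_matrix(pop, pop_len, refs, ref_len, sub, gap_open, gap_extend):
    """Score-only SW for all population × reference pairs (jitted batch)."""
    nq = pop.shape[0]
    nr = refs.shape[0]
    out = np.zeros((nq, nr), dtype=np.int64)
    maxm = refs.shape[1]
    Hrow = np.zeros(maxm + 1, dtype=np.int64)
    Frow = np.full(maxm + 1, NEG_INF, dtype=np.int64)
    for a in range(nq):
        n = pop_len[a]
        for b in range(nr):
            m = ref_len[b]
            best = 0
            for j in range(m + 1):
                Hrow[j] = 0
                Frow[j] = NEG_INF
            for i in range(1, n + 1):
                diag = 0  # H[i-1, j-1]
                e = NEG_INF
                hprev = 0  # H[i, j-1]
                qi = pop[a, i - 1]
                for j in range(1, m + 1):
                    e = max(hprev - gap_open, e - gap_extend)
                    f = max(Hrow[j] - gap_open, Frow[j] - gap_extend)
                    h = diag + sub[qi, refs[b, j - 1]]
                    if e > h:
                        h = e
                    if f > h:
                        h = f
                    if h < 0:
                        h = 0
                    diag = Hrow[j]
                    Hrow[j] = h
                    Frow[j] = f
                    hprev = h
                    if h > best:
                        best = h
            out[a, b] = best
    return out


def _traceback(q, r, qidx, ridx, H, E, F, p, bi, bj):
    """Recover one optimal path from the filled DP matrices."""
    sub = p.score_matrix
    i, j = bi, bj
    aq, ar = [], []
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            if H[i, j] == 0:
                break
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + sub[qidx[i - 1], ridx[j - 1]]:
                aq.append(q[i - 1])
                ar.append(r[j - 1])
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = "E"
            elif H[i, j] == F[i, j]:
                state = "F"
            else:  # pragma: no cover - DP consistency
                raise AssertionError("traceback inconsistency")
        elif state == "E":  # gap in query (consume reference)
            aq.append("-")
            ar.append(r[j - 1])
            if E[i, j] == E[i, j - 1] - p.gap_extend:
                j -= 1
            else:
                j -= 1
                state = "H"
        else:  # state F: gap in reference (consume query)
            aq.append(q[i - 1])
            ar.append("-")
            if F[i, j] == F[i - 1, j] - p.gap_extend:
                i -= 1
            else:
                i -= 1
                state = "H"
    return i, j, "".join(reversed(aq)), "".join(reversed(ar))


def smith_waterman(
    query: str, ref: str, params: AlignmentParams | None = None
) -> LocalAlignmentResult:
    """Optimal local alignment of ``query`` against ``ref``.

    Returns the DP-maximal alignment; ties are broken toward the first
    (row-major smallest) end cell and toward diagonal moves in traceback,
    so results are deterministic.
    """
    p = params or AlignmentParams()
    qidx = p.encode(query)
    ridx = p.encode(ref)
    H, E, F, best, bi, bj = _sw_fill(
        qidx, ridx, p.score_matrix, p.gap_open, p.gap_extend
    )
    if best <= 0:
        return LocalAlignmentResult(score=0)
    i0, j0, aq, ar = _traceback(query, ref, qidx, ridx, H, E, F, p, bi, bj)
    return LocalAlignmentResult(
        score=int(best),
        query_span=(i0, bi),
        ref_span=(j0, bj),
        aligned_query=aq,
        aligned_ref=ar,
    )


def sw_score(query: str, ref: str, params: AlignmentParams | None = None) -> int:
    """Local alignment score only (no traceback)."""
    p = params or AlignmentParams()
    qidx = p.encode(query)
    ridx = p.encode(ref)
    _, _, _, best, _, _ = _sw_fill(
        qidx, ridx, p.score_matrix, p.gap_open, p.gap_extend
    )
    return int(best)


def batch_scores(
    queries: list[str], refs: list[str], params: AlignmentParams | None = None
) -> np.ndarray:
    """All-vs-all local alignment scores, shape (len(queries), len(refs))."""
    p = params or AlignmentParams()
    maxq = max(len(s) for s in queries)
    maxr = max(len(s) for s in refs)
    qarr = np.zeros((len(queries), maxq), dtype=np.int64)
    rarr = np.zeros((len(refs), maxr), dtype=np.int64)
    qlen = np.array([len(s) for s in queries], dtype=np.int64)
    rlen = np.array([len(s) for s in refs], dtype=np.int64)
    for i, s in enumerate(queries):
        qarr[i, : len(s)] = p.encode(s)
    for i, s in enumerate(refs):
        rarr[i, : len(s)] = p.encode(s)
    return _sw_score_matrix(
        qarr, qlen, rarr, rlen, p.score_matrix, p.gap_open, p.gap_extend
    )
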