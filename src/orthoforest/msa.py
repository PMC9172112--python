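"""Progressive multiple sequence alignment over a UPGMA guide tree.

Pairwise k-mer distances give a quick hierarchical (UPGMA, average-linkage)
guide tree; profiles are then merged bottom-up by global affine-gap
profile–profile alignment, where a column pair is scored by the expected
substitution score between the two columns' residue frequency profiles.
This is the classic progressive scheme; an externally computed alignment
(aligned FASTA) can be loaded instead via :func:`read_alignment` and used
everywhere an :class:`MSA` is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .align import AlignmentParams, load_matrix, njit
from .io import Dataset

GAP = "-"
NEG = -1e30


@dataclass
class MSA:
    """An alignment: equal-length gapped rows with per-row identity."""

    ids: list[str]
    species: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        assert len(self.ids) == len(self.rows) == len(self.species)
        if self.rows:
            ncol = len(self.rows[0])
            assert all(len(r) == ncol for r in self.rows), "ragged alignment"

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)


def _kmer_sets(seqs: list[str], k: int) -> list[set[str]]:
    return [
        {s[i : i + k] for i in range(max(1, len(s) - k + 1))} for s in seqs
    ]


def kmer_distance_matrix(seqs: list[str], k: int = 3) -> np.ndarray:
    """1 − shared-k-mer fraction (normalized by the smaller set)."""
    kk = min(k, min(len(s) for s in seqs))
    sets = _kmer_sets(seqs, kk)
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = min(len(sets[i]), len(sets[j]))
            frac = len(sets[i] & sets[j]) / denom if denom else 0.0
            d[i, j] = d[j, i] = 1.0 - frac
    return d


@njit(cache=True)
def _nw_profile_fill(S, gap_open, gap_extend):  # pragma: no cover - jitted
    n, m = S.shape
    H = np.full((n + 1, m + 1), NEG)
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    H[0, 0] = 0.0
    for j in range(1, m + 1):
        E[0, j] = -(gap_open + (j - 1) * gap_extend)
        H[0, j] = E[0, j]
    for i in range(1, n + 1):
        F[i, 0] = -(gap_open + (i - 1) * gap_extend)
        H[i, 0] = F[i, 0]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_extend)
            f = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_extend)
            h = H[i - 1, j - 1] + S[i - 1, j - 1]
            if e > h:
                h = e
            if f > h:
                h = f
            E[i, j] = e
            F[i, j] = f
            H[i, j] = h
    return H, E, F


def _profile_freqs(rows: list[str], alphabet: str) -> np.ndarray:
    """Per-column residue frequencies (gaps excluded from the denominator)."""
    idx = {c: i for i, c in enumerate(alphabet)}
    ncol = len(rows[0])
    freqs = np.zeros((ncol, len(alphabet)))
    for row in rows:
        for j, ch in enumerate(row):
            if ch != GAP:
                freqs[j, idx[ch]] += 1.0
    sums = freqs.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return freqs / sums


def _align_profiles(
    rows_a: list[str], rows_b: list[str], params: AlignmentParams
) -> tuple[list[str], list[str]]:
    """Globally align two profiles; return both with gap columns inserted."""
    alphabet, mat = load_matrix(params.matrix)
    fa = _profile_freqs(rows_a, alphabet)
    fb = _profile_freqs(rows_b, alphabet)
    S = fa @ mat.astype(float) @ fb.T
    H, E, F = _nw_profile_fill(S, float(params.gap_open), float(params.gap_extend))
    i, j = len(rows_a[0]), len(rows_b[0])
    ops: list[str] = []  # 'M', 'A' (gap in b), 'B' (gap in a)
    state = "H"
    tol = 1e-9
    while i > 0 or j > 0:
        if state == "H":
            if i > 0 and j > 0 and abs(H[i, j] - (H[i - 1, j - 1] + S[i - 1, j - 1])) < tol:
                ops.append("M")
                i -= 1
                j -= 1
            elif j > 0 and abs(H[i, j] - E[i, j]) < tol:
                state = "E"
            elif i > 0 and abs(H[i, j] - F[i, j]) < tol:
                state = "F"
            else:  # pragma: no cover
                raise AssertionError("profile traceback inconsistency")
        elif state == "E":  # consume a column of b, gap in a
            ops.append("B")
            if j > 1 and abs(E[i, j] - (E[i, j - 1] - params.gap_extend)) < tol:
                j -= 1
            else:
                j -= 1
                state = "H"
        else:  # consume a column of a, gap in b
            ops.append("A")
            if i > 1 and abs(F[i, j] - (F[i - 1, j] - params.gap_extend)) < tol:
                i -= 1
            else:
                i -= 1
                state = "H"
    ops.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = jb = 0
    for op in ops:
        if op in ("M", "A"):
            for k, row in enumerate(rows_a):
                out_a[k] += row[ia]
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += GAP
        if op in ("M", "B"):
            for k, row in enumerate(rows_b):
                out_b[k] += row[jb]
            jb += 1
        else:
            for k in range(len(rows_b)):
                out_b[k] += GAP
    return out_a, out_b


def progressive_align(d: Dataset, params: AlignmentParams | None = None) -> MSA:
    """Align a dataset progressively along a UPGMA guide tree.

    Deterministic for a fixed input order; output rows follow input order.
    """
    params = params or AlignmentParams()
    records = d.records
    if len(records) < 2:
        raise ValueError("progressive alignment needs at least 2 sequences")
    seqs = [r.sequence for r in records]
    n = len(seqs)
    if n == 2:
        a, b = _align_profiles([seqs[0]], [seqs[1]], params)
        rows = [a[0], b[0]]
    else:
        dmat = kmer_distance_matrix(seqs)
        Z = linkage(squareform(dmat, checks=False), method="average")
        # cluster id -> (row indices, aligned rows)
        profiles: dict[int, tuple[list[int], list[str]]] = {
            i: ([i], [seqs[i]]) for i in range(n)
        }
        for step, (ca, cb, _, _) in enumerate(Z):
            ia, rows_a = profiles.pop(int(ca))
            ib, rows_b = profiles.pop(int(cb))
            out_a, out_b = _align_profiles(rows_a, rows_b, params)
            profiles[n + step] = (ia + ib, out_a + out_b)
        order, aligned = profiles.popitem()[1]
        rows = [None] * n  # type: ignore[list-item]
        for pos, row in zip(order, aligned):
            rows[pos] = row
    return MSA(
        ids=[r.accession for r in records],
        species=[r.species for r in records],
        rows=rows,  # type: ignore[arg-type]
    )


def read_alignment(path: str | Path, species_map: dict[str, str] | None = None) -> MSA:
    """Load an externally computed alignment from aligned FASTA.

    Species are taken from ``species_map`` (accession → tag) or, failing
    that, from an ``_<TAG>`` accession suffix; unknown otherwise.
    """
    from Bio import SeqIO

    ids, species, rows = [], [], []
    for entry in SeqIO.parse(str(path), "fasta"):
        acc = entry.id
        ids.append(acc)
        if species_map and acc in species_map:
            sp = species_map[acc]
        elif "_" in acc:
            sp = acc.rsplit("_", 1)[1]
        else:
            sp = "NA"
        species.append(sp)
        rows.append(str(entry.seq).upper())
    return MSA(ids=ids, species=species, rows=rows)


def write_alignment(msa: MSA, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for acc, row in zip(msa.ids, msa.rows):
            fh.write(f">{acc}\n{row}\n")
    return path
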