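"""Shared Smith–Waterman machinery (Gotoh affine gaps) on encoded sequences.

A gap of length L costs ``gap_open + L * gap_extend``. The stop symbol '*' in
conceptual translations is retained and scores the matrix minimum against
everything, so in-frame stops stay alignable rather than truncating a frame.

The DP kernel is numba-compiled; sizes here are test/desk scale (O(m*n) per
call), which the CLI guards against for large inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

NEG_INF = np.int32(-(10 ** 8))

# Gapped Karlin–Altschul parameters (lambda, K) per matrix at the default gap
# penalties; approximate, used only so e-value filtering code paths run.
KARLIN_ALTSCHUL = {
    "BLOSUM62": (0.267, 0.041),
    "BLOSUM45": (0.195, 0.032),
    "BLOSUM80": (0.300, 0.071),
}


@lru_cache(maxsize=None)
def load_matrix(name: str = "BLOSUM62") -> tuple[str, np.ndarray]:
    """Return (alphabet, square int32 score matrix) with the '*' row/column
    forced to the matrix minimum (stop sentinel scoring)."""
    mat = substitution_matrices.load(name)
    alphabet = str(mat.alphabet)
    arr = np.asarray(mat, dtype=np.int32)
    lowest = np.int32(arr[arr > -100].min()) if (arr <= -100).any() else np.int32(arr.min())
    if "*" in alphabet:
        idx = alphabet.index("*")
        arr = arr.copy()
        arr[idx, :] = lowest
        arr[:, idx] = lowest
    return alphabet, arr


@lru_cache(maxsize=None)
def _encode_table(alphabet: str) -> np.ndarray:
    table = np.full(128, alphabet.index("X") if "X" in alphabet else 0, dtype=np.int8)
    for i, ch in enumerate(alphabet):
        table[ord(ch)] = i
    return table


def encode(seq: str, alphabet: str) -> np.ndarray:
    """Encode an amino-acid string to matrix indices (unknowns map to 'X')."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _encode_table(alphabet)[raw]


@njit(cache=True)
def _sw_fill(a, b, matrix, gap_open, gap_extend):  # pragma: no cover - numba
    m, n = a.shape[0], b.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG_INF, dtype=np.int32)
    F = np.full((m + 1, n + 1), NEG_INF, dtype=np.int32)
    open_cost = gap_open + gap_extend
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            e = E[i, j - 1] - gap_extend
            eo = H[i, j - 1] - open_cost
            if eo > e:
                e = eo
            E[i, j] = e
            f = F[i - 1, j] - gap_extend
            fo = H[i - 1, j] - open_cost
            if fo > f:
                f = fo
            F[i, j] = f
            h = H[i - 1, j - 1] + matrix[ai, b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
    return H, E, F


@dataclass(frozen=True)
class LocalAlignment:
    """A local alignment of a (query) vs b (subject), 0-based half-open."""

    score: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    n_match: int
    n_mismatch: int
    n_gapopen: int
    n_cols: int

    @property
    def pident(self) -> float:
        return 100.0 * self.n_match / self.n_cols if self.n_cols else 0.0


def smith_waterman(a_seq: str, b_seq: str, matrix_name: str = "BLOSUM62",
                   gap_open: int = 11, gap_extend: int = 1) -> LocalAlignment | None:
    """Best local alignment of two amino-acid strings, or None if the best
    score is 0 (no positive-scoring pair)."""
    alphabet, matrix = load_matrix(matrix_name)
    a = encode(a_seq, alphabet)
    b = encode(b_seq, alphabet)
    if a.size == 0 or b.size == 0:
        return None
    H, E, F = _sw_fill(a, b, matrix, np.int32(gap_open), np.int32(gap_extend))
    best = int(H.max())
    if best <= 0:
        return None
    # deterministic end cell: smallest (i, j) among maxima
    flat = int(np.argmax(H))
    i, j = divmod(flat, H.shape[1])
    a_end, b_end = i, j

    open_cost = gap_open + gap_extend
    n_match = n_mismatch = n_gapopen = n_cols = 0
    state = "H"
    while True:
        if state == "H":
            if H[i, j] == 0:
                break
            diag = H[i - 1, j - 1] + matrix[a[i - 1], b[j - 1]]
            if i > 0 and j > 0 and H[i, j] == diag:
                n_cols += 1
                if a[i - 1] == b[j - 1]:
                    n_match += 1
                else:
                    n_mismatch += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = "E"
            elif H[i, j] == F[i, j]:
                state = "F"
            else:  # pragma: no cover - defensive
                raise AssertionError("traceback inconsistency")
        elif state == "E":  # gap in a: consume b[j-1]
            n_cols += 1
            opened = H[i, j - 1] - open_cost
            extended = E[i, j - 1] - gap_extend
            if E[i, j] == opened:
                n_gapopen += 1
                state = "H"
            elif E[i, j] != extended:  # pragma: no cover - defensive
                raise AssertionError("traceback inconsistency")
            j -= 1
        else:  # state == "F": gap in b: consume a[i-1]
            n_cols += 1
            opened = H[i - 1, j] - open_cost
            extended = F[i - 1, j] - gap_extend
            if F[i, j] == opened:
                n_gapopen += 1
                state = "H"
            elif F[i, j] != extended:  # pragma: no cover - defensive
                raise AssertionError("traceback inconsistency")
            i -= 1

    return LocalAlignment(best, i, a_end, j, b_end,
                          n_match, n_mismatch, n_gapopen, n_cols)


def bitscore_from_raw(raw: float, matrix_name: str = "BLOSUM62") -> float:
    lam, k = KARLIN_ALTSCHUL[matrix_name]
    return (lam * raw - np.log(k)) / np.log(2.0)


def evalue_from_bitscore(bitscore: float, m: int, n: int) -> float:
    return float(m) * float(n) * 2.0 ** (-bitscore)
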