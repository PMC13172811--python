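"""Helpers for exhaustive scorer-vs-oracle comparison.

The exhaustive corpus (every probe up to 6 bp over {A,C,G} against every
read up to 10 bp) is too large to score with the naive per-window oracle
in reasonable time, so this module provides an *enumeration oracle*: for
a given probe it tabulates LCS(probe, s) for every string s up to the
maximum read length by walking the prefix tree (each string's DP row is
one append-character update away from its parent's), then scores a read
as the max over its windows via table lookups. It shares no code with
the production scorer — no window pruning, no incremental per-start
reuse — and is itself cross-checked against the naive per-window oracle
on a smaller corpus inside the tests.
"""

from __future__ import annotations

import numpy as np
from numba import njit


def enumerate_strings(alphabet: str, length: int) -> np.ndarray:
    """All strings of the given length, as an ASCII uint8 matrix.

    Row index is the base-k value of the string, most significant digit
    first.
    """
    k = len(alphabet)
    idx = np.arange(k**length)
    cols = [(idx // k**p) % k for p in range(length - 1, -1, -1)]
    codes = np.array([ord(c) for c in alphabet], dtype=np.uint8)
    return codes[np.stack(cols, axis=1)]


@njit(cache=True)
def _lcs_table(probe_digits: np.ndarray, k: int, max_len: int,
               offsets: np.ndarray) -> np.ndarray:
    """LCS(probe, s) for every string s of length 1..max_len over k letters.

    Strings are indexed by offsets[L] + base-k value. Level L+1 rows are
    derived from level L rows by the append-one-character LCS update.
    """
    m = probe_digits.size
    total = offsets[max_len] + k**max_len
    table = np.zeros(total, dtype=np.int8)
    rows = np.zeros((1, m + 1), dtype=np.int8)  # level 0: empty string
    for level in range(max_len):
        n_child = rows.shape[0] * k
        child = np.empty((n_child, m + 1), dtype=np.int8)
        for parent in range(rows.shape[0]):
            for c in range(k):
                ci = parent * k + c
                child[ci, 0] = 0
                diag = np.int8(0)
                for pos in range(1, m + 1):
                    if probe_digits[pos - 1] == c:
                        v = diag + 1
                    else:
                        v = rows[parent, pos]
                        if child[ci, pos - 1] > v:
                            v = child[ci, pos - 1]
                    child[ci, pos] = v
                    diag = rows[parent, pos]
                table[offsets[level + 1] + ci] = child[ci, m]
        rows = child
    return table


@njit(cache=True)
def _window_max_scores(table: np.ndarray, offsets: np.ndarray, m: int,
                       k: int, n: int) -> np.ndarray:
    """Best window score for every read of length n, from the LCS table."""
    count = k**n
    out = np.empty(count, dtype=np.float64)
    digits = np.empty(n, dtype=np.int64)
    for r in range(count):
        tmp = r
        for pos in range(n - 1, -1, -1):
            digits[pos] = tmp % k
            tmp //= k
        best = 0.0
        for i in range(n):
            v = 0
            for j in range(i, n):
                v = v * k + digits[j]
                w = j - i + 1
                lcs = table[offsets[w] + v]
                score = 200.0 * lcs / (m + w)
                if score > best:
                    best = score
        out[r] = best
    return out


def enumeration_oracle_scores(probe: str, alphabet: str, read_len: int) -> np.ndarray:
    """Oracle partial-ratio scores of one probe vs every read of read_len.

    Returned in the row order of :func:`enumerate_strings`.
    """
    k = len(alphabet)
    lookup = {c: i for i, c in enumerate(alphabet)}
    probe_digits = np.array([lookup[c] for c in probe], dtype=np.int64)
    offsets = np.zeros(read_len + 1, dtype=np.int64)
    acc = 0
    for length in range(1, read_len + 1):
        offsets[length] = acc
        acc += k**length
    table = _lcs_table(probe_digits, k, read_len, offsets)
    return _window_max_scores(table, offsets, len(probe), k, read_len)
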