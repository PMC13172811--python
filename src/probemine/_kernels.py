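"""Compiled scoring kernels.

Two independent routes to the same quantity:

* :func:`partial_ratio_kernel` — the production scorer. Incremental
  LCS dynamic programming over every window start, with a sound
  upper-bound prune on window length.
* :func:`oracle_kernel` — the reference scorer. Literally enumerates
  every contiguous window of the read and recomputes the LCS from
  scratch for each. Slow, but obviously correct; the production kernel
  is validated against it.

Sequences are passed as uint8 arrays of ASCII codes; any byte that is
not equal to a probe byte simply never matches (so ``N`` in a read
contributes nothing against A/C/G/T expansions).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "lcs_kernel",
    "indel_ratio_kernel",
    "partial_ratio_kernel",
    "oracle_kernel",
    "partial_ratio_batch",
    "oracle_batch",
]


@njit(cache=True)
def lcs_kernel(a: np.ndarray, b: np.ndarray) -> int:
    """Longest-common-subsequence length, one-row DP."""
    m = a.size
    row = np.zeros(m + 1, dtype=np.int64)
    for j in range(b.size):
        c = b[j]
        diag = 0
        for k in range(1, m + 1):
            tmp = row[k]
            if a[k - 1] == c:
                v = diag + 1
            else:
                v = row[k] if row[k] >= row[k - 1] else row[k - 1]
            row[k] = v
            diag = tmp
    return row[m]


@njit(cache=True)
def indel_ratio_kernel(a: np.ndarray, b: np.ndarray) -> float:
    """Similarity 100 * 2 * LCS(a, b) / (|a| + |b|)."""
    return 200.0 * lcs_kernel(a, b) / (a.size + b.size)


@njit(cache=True)
def partial_ratio_kernel(probe: np.ndarray, read: np.ndarray) -> float:
    """Max indel ratio between the probe and any contiguous read window.

    For each window start i the LCS row is extended one read character at
    a time, so every end j is scored from a single DP pass. Windows of
    length w starting at i cannot beat 200*m/(m+w) (LCS <= m); once that
    bound falls to the running best, longer windows from this start are
    skipped. The prune only discards provably non-improving windows, so
    the result equals the exhaustive enumeration exactly.
    """
    m = probe.size
    n = read.size
    best = 0.0
    row = np.zeros(m + 1, dtype=np.int64)
    for i in range(n):
        row[:] = 0
        for j in range(i, n):
            w = j - i + 1
            if 200.0 * m / (m + w) <= best:
                break
            c = read[j]
            diag = 0
            for k in range(1, m + 1):
                tmp = row[k]
                if probe[k - 1] == c:
                    v = diag + 1
                else:
                    v = row[k] if row[k] >= row[k - 1] else row[k - 1]
                row[k] = v
                diag = tmp
            score = 200.0 * row[m] / (m + w)
            if score > best:
                best = score
                if best == 100.0:
                    return best
    return best


@njit(cache=True)
def oracle_kernel(probe: np.ndarray, read: np.ndarray) -> float:
    """Exhaustive-window reference: recompute LCS for every substring."""
    m = probe.size
    n = read.size
    best = 0.0
    for i in range(n):
        for j in range(i, n):
            lcs = lcs_kernel(probe, read[i:j + 1])
            score = 200.0 * lcs / (m + (j - i + 1))
            if score > best:
                best = score
    return best


@njit(cache=True)
def partial_ratio_batch(probe: np.ndarray, reads: np.ndarray) -> np.ndarray:
    """Production scores of one probe against each row of a read matrix."""
    out = np.empty(reads.shape[0], dtype=np.float64)
    for r in range(reads.shape[0]):
        out[r] = partial_ratio_kernel(probe, reads[r])
    return out


@njit(cache=True)
def oracle_batch(probe: np.ndarray, reads: np.ndarray) -> np.ndarray:
    """Reference scores of one probe against each row of a read matrix."""
    out = np.empty(reads.shape[0], dtype=np.float64)
    for r in range(reads.shape[0]):
        out[r] = oracle_kernel(probe, reads[r])
    return out
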