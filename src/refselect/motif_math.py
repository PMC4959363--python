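"""Exact candidate-motif combinatorics and fast all-pairs l-mer distances.

A *candidate motif* for a pair of l-mers ``(x, x')`` is any l-length string
``y`` with ``d_H(y, x) <= d`` and ``d_H(y, x') <= d``.  The number of such
strings depends on ``(l, d, |alphabet|)`` and on ``d_H(x, x')`` only, so it
can be tabulated once per parameter set and looked up in O(1).

The distance machinery computes the Hamming distance between every pair of
l-length windows of two equal-length sequences in O(n^2) total time using a
match-count matrix ``M`` with the recurrence ``M[a+1, b+1] = M[a, b] + 1`` if
the incoming characters match (else unchanged), from which the window
distance is ``l - (M[a, b] - M[a-l, b-l])``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb, factorial

import numpy as np

__all__ = [
    "PMSParams",
    "CandidateCountTable",
    "common_candidate_count",
    "build_count_table",
    "pair_probability",
    "expected_pair_count",
    "match_count_matrix",
    "all_lmer_distances",
    "lmer_distance_histogram",
]


@dataclass(frozen=True)
class PMSParams:
    """Parameters of a planted (l, d) motif-search instance.

    Parameters
    ----------
    l : motif length.
    d : maximum number of mismatches allowed per motif instance.
    sigma : alphabet size (4 for DNA, 20 for protein; any >= 2 accepted).
    n : sequence length; optional context used only for validation and
        expectation formulas.
    """

    l: int
    d: int
    sigma: int = 4
    n: int | None = None

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError(f"d must be >= 0, got {self.d}")
        if self.l <= self.d:
            raise ValueError(f"require d < l, got l={self.l}, d={self.d}")
        if self.sigma < 2:
            raise ValueError(f"alphabet size must be >= 2, got {self.sigma}")
        if self.n is not None and self.n <= self.l:
            raise ValueError(f"require l < n, got l={self.l}, n={self.n}")


def common_candidate_count(params: PMSParams, dist: int) -> int:
    """Exact number of l-length strings within distance d of both of two
    l-mers at Hamming distance ``dist``.

    Computed as a constrained multinomial sum: at each of the ``dist``
    positions where the two l-mers differ, a common neighbor ``y`` matches
    the first (``a`` positions), matches the second (``b``), or matches
    neither (``c``, ``sigma - 2`` character choices); at ``m`` of the
    ``l - dist`` agreeing positions, ``y`` differs from both (``sigma - 1``
    choices).  Then ``d_H(y, x) = b + c + m`` and ``d_H(y, x') = a + c + m``
    must both be at most ``d``.  Exact integer arithmetic throughout.
    """
    l, d, sigma = params.l, params.d, params.sigma
    if dist < 0 or dist > l:
        raise ValueError(f"distance must be in [0, {l}], got {dist}")
    if dist > 2 * d:
        return 0
    agree = l - dist
    total = 0
    for a in range(dist + 1):
        for b in range(dist + 1 - a):
            c = dist - a - b
            if c > 0 and sigma == 2:
                continue
            # mismatch budget left for the agreeing positions
            m_max = min(d - (b + c), d - (a + c), agree)
            if m_max < 0:
                continue
            ways_diff = (
                factorial(dist) // (factorial(a) * factorial(b) * factorial(c))
            ) * (sigma - 2) ** c
            ways_agree = sum(
                comb(agree, m) * (sigma - 1) ** m for m in range(m_max + 1)
            )
            total += ways_diff * ways_agree
    return total


@dataclass(frozen=True)
class CandidateCountTable:
    """Lookup table of common-candidate-motif counts by pairwise distance.

    ``counts[i]`` holds the exact count for l-mer pairs at Hamming distance
    ``i`` for ``0 <= i <= 2d``; any distance beyond ``2d`` yields 0 (radius-d
    neighborhoods cannot intersect there).
    """

    params: PMSParams
    counts: tuple[int, ...] = field(repr=False)

    def __getitem__(self, dist: int) -> int:
        if dist < 0:
            raise IndexError(f"negative distance {dist}")
        return self.counts[dist] if dist < len(self.counts) else 0

    def as_array(self, length: int) -> np.ndarray:
        """Counts for distances 0..length-1 as a float array (for weighting)."""
        out = np.zeros(length, dtype=np.float64)
        upto = min(length, len(self.counts))
        out[:upto] = self.counts[:upto]
        return out

    def as_object_array(self, length: int) -> np.ndarray:
        """Counts as Python ints (exact, arbitrary precision) of given length."""
        out = np.empty(length, dtype=object)
        for i in range(length):
            out[i] = self.counts[i] if i < len(self.counts) else 0
        return out


def build_count_table(params: PMSParams) -> CandidateCountTable:
    """Tabulate :func:`common_candidate_count` for distances 0 .. 2d."""
    top = min(2 * params.d, params.l)
    counts = tuple(common_candidate_count(params, i) for i in range(top + 1))
    return CandidateCountTable(params=params, counts=counts)


def pair_probability(l: int, i: int, sigma: int) -> float:
    """Probability that two uniform random l-mers are at Hamming distance i.

    ``C(l, i) * (sigma - 1)^i / sigma^l``, evaluated exactly then converted
    to double precision.
    """
    if sigma < 2:
        raise ValueError(f"alphabet size must be >= 2, got {sigma}")
    if i < 0 or i > l:
        raise ValueError(f"distance must be in [0, {l}], got {i}")
    return comb(l, i) * (sigma - 1) ** i / sigma**l


def expected_pair_count(n: int, l: int, i: int, sigma: int) -> float:
    """Expected number of window pairs at distance i between two n-length
    sequences: ``(n - l + 1)^2 * pair_probability(l, i, sigma)``."""
    if l > n:
        raise ValueError(f"require l <= n, got l={l}, n={n}")
    return (n - l + 1) ** 2 * pair_probability(l, i, sigma)


def _as_codes(seq) -> np.ndarray:
    """Coerce a string or integer array to a 1-D uint8/int code array."""
    if isinstance(seq, str):
        return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    arr = np.asarray(seq)
    if arr.ndim != 1:
        raise ValueError("sequence must be one-dimensional")
    return arr


def match_count_matrix(s_i, s_j) -> np.ndarray:
    """Full (n+1) x (n+1) match-count matrix M with zero border.

    ``M[a, b]`` (1-based ends) is the number of matching positions in the
    alignment of the two suffix windows of length ``min(a, b)`` ending at
    ``a`` and ``b``.  Exposed mainly for testing; the histogram path below
    retains only two rows at a time.
    """
    a = _as_codes(s_i)
    b = _as_codes(s_j)
    if a.shape[0] != b.shape[0]:
        raise ValueError(
            f"sequences must have equal length, got {a.shape[0]} and {b.shape[0]}"
        )
    n = a.shape[0]
    eq = (a[:, None] == b[None, :]).astype(np.int32)
    m = np.zeros((n + 1, n + 1), dtype=np.int32)
    for r in range(n):
        m[r + 1, 1:] = m[r, :-1] + eq[r]
    return m

def all_lmer_distances(s_i, s_j, l: int) -> np.ndarray:
    """Hamming distance between every pair of l-length windows.

    Entry ``(u, v)`` for ``0 <= u, v <= n - l`` is the distance between the
    windows starting at ``u`` of ``s_i`` and ``v`` of ``s_j``.  Total work is
    O(n^2) independent of l.
    """
    a = _as_codes(s_i)
    n = a.shape[0]
    if l > n:
        raise ValueError(f"window length {l} exceeds sequence length {n}")
    if l < 1:
        raise ValueError(f"window length must be >= 1, got {l}")
    m = match_count_matrix(s_i, s_j)
    return (l - (m[l:, l:] - m[:-l, :-l])).astype(np.int64)


def lmer_distance_histogram(s_i, s_j, l: int) -> np.ndarray:
    """Histogram of window-pair Hamming distances (length l + 1).

    Streams the match-count recurrence two rows at a time plus a ring buffer
    of the last l rows' window columns, so working storage is O(n) rather
    than O(n^2); the histogram is all that downstream aggregation needs.
    """
    a = _as_codes(s_i)
    b = _as_codes(s_j)
    if a.shape[0] != b.shape[0]:
        raise ValueError(
            f"sequences must have equal length, got {a.shape[0]} and {b.shape[0]}"
        )
    n = a.shape[0]
    if l > n:
        raise ValueError(f"window length {l} exceeds sequence length {n}")
    w = n - l + 1
    hist = np.zeros(l + 1, dtype=np.int64)
    prev = np.zeros(n + 1, dtype=np.int32)
    ring = np.zeros((l, w), dtype=np.int32)  # ring[r % l] = M[r, :w] at col grid
    cur = np.empty(n + 1, dtype=np.int32)
    for r in range(n):
        cur[0] = 0
        np.add(prev[:-1], (a[r] == b).view(np.uint8), out=cur[1:])
        if r + 1 >= l:
            # windows ending at row r+1: distances l - (cur[l:] - M[r+1-l, :w])
            d_row = l - (cur[l:] - ring[(r + 1 - l) % l])
            hist += np.bincount(d_row, minlength=l + 1)
        ring[(r + 1) % l] = cur[:w]
        prev, cur = cur, prev
    return hist
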