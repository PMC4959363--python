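"""Shared fixtures and independent naive oracles for the test suite.

The oracles here deliberately avoid the package's optimized code paths:
window distances by direct character comparison, candidate counts by
exhaustive string enumeration, pair totals by a double loop.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
import pytest

from refselect.motif_math import CandidateCountTable, PMSParams
from refselect.pairwise import SequenceSet, resolve_alphabet

DNA = "ACGT"


def hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


def naive_window_distances(s_i: str, s_j: str, l: int) -> np.ndarray:
    """O(l n^2) oracle: compare every window pair character by character."""
    n = len(s_i)
    w = n - l + 1
    out = np.zeros((w, w), dtype=np.int64)
    for u in range(w):
        for v in range(w):
            out[u, v] = hamming(s_i[u : u + l], s_j[v : v + l])
    return out


@lru_cache(maxsize=None)
def all_strings(sigma: int, l: int) -> tuple[np.ndarray, ...]:
    """All sigma^l strings as one (sigma^l, l) code array (cached)."""
    return (np.array(list(itertools.product(range(sigma), repeat=l)), dtype=np.int8),)


def enumerate_common_count(l: int, d: int, sigma: int, dist: int) -> int:
    """Exhaustive oracle for the common-candidate count at a given pairwise
    distance: count strings within distance d of two canonical l-mers."""
    assert 0 <= dist <= l
    x = np.zeros(l, dtype=np.int8)
    xp = np.zeros(l, dtype=np.int8)
    xp[:dist] = 1
    (grid,) = all_strings(sigma, l)
    near_x = (grid != x).sum(axis=1) <= d
    near_xp = (grid != xp).sum(axis=1) <= d
    return int((near_x & near_xp).sum())


def naive_pair_total(
    s_i: str, s_j: str, table: CandidateCountTable, weighted: bool = False
):
    """Double-loop oracle for the per-pair candidate totals."""
    l = table.params.l
    n = len(s_i)
    total = 0 if not weighted else 0.0
    for u in range(n - l + 1):
        for v in range(n - l + 1):
            dist = hamming(s_i[u : u + l], s_j[v : v + l])
            c = table[dist]
            total += c / (dist + 1) if weighted else c
    return total


def random_sequences(rng: np.random.Generator, t: int, n: int, alphabet: str = "dna") -> SequenceSet:
    chars = resolve_alphabet(alphabet)
    seqs = [
        "".join(chars[c] for c in rng.integers(0, len(chars), size=n))
        for _ in range(t)
    ]
    return SequenceSet(
        sequences=seqs,
        identifiers=[f"seq{i + 1}" for i in range(t)],
        alphabet=alphabet,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160719)


@pytest.fixture
def toy_params() -> PMSParams:
    return PMSParams(l=5, d=1, sigma=4)


@pytest.fixture
def toy_set(rng) -> SequenceSet:
    return random_sequences(rng, t=6, n=20)
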