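"""Pairwise candidate-count aggregation and the sequence-similarity matrix.

For every pair of input sequences the number of candidate motifs they jointly
generate is the sum, over all window pairs, of the tabulated common-candidate
count at that pair's Hamming distance.  A distance-weighted variant divides
each term by ``d_H + 1`` to amplify close window pairs, and similarities are
the weighted counts inverted and rescaled so the maximum-count pair has
similarity exactly 1.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from .motif_math import CandidateCountTable, PMSParams, lmer_distance_histogram

__all__ = [
    "DNA_ALPHABET",
    "PROTEIN_ALPHABET",
    "SequenceSet",
    "SimilarityMatrix",
    "pair_candidate_count",
    "weighted_pair_count",
    "similarity_matrix",
    "total_candidate_count",
]

DNA_ALPHABET = "ACGT"
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_ALPHABETS = {"dna": DNA_ALPHABET, "protein": PROTEIN_ALPHABET}


def resolve_alphabet(alphabet: str) -> str:
    """Map 'dna'/'protein' (or an explicit character set) to its characters."""
    if alphabet in _ALPHABETS:
        return _ALPHABETS[alphabet]
    if len(set(alphabet)) == len(alphabet) and len(alphabet) >= 2:
        return alphabet
    raise ValueError(f"unknown alphabet {alphabet!r}")


@dataclass
class SequenceSet:
    """A set of t equal-length sequences over a declared alphabet."""

    sequences: list[str]
    identifiers: list[str]
    alphabet: str = "dna"

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError("need at least 2 sequences")
        if len(self.identifiers) != len(self.sequences):
            raise ValueError("one identifier per sequence required")
        n = len(self.sequences[0])
        chars = set(resolve_alphabet(self.alphabet))
        for ident, seq in zip(self.identifiers, self.sequences):
            if len(seq) != n:
                raise ValueError(
                    f"record {ident!r} has length {len(seq)}, expected {n}"
                )
            bad = set(seq) - chars
            if bad:
                raise ValueError(
                    f"record {ident!r} contains characters outside the "
                    f"{self.alphabet} alphabet: {sorted(bad)}"
                )

    @property
    def t(self) -> int:
        return len(self.sequences)

    @property
    def n(self) -> int:
        return len(self.sequences[0])

    @property
    def sigma(self) -> int:
        return len(resolve_alphabet(self.alphabet))


@dataclass
class SimilarityMatrix:
    """Raw counts, weighted counts and similarities for all sequence pairs.

    Diagonals are structural zeros; self-pairs are never evaluated.
    ``raw_counts`` is an object array of exact Python ints (protein counts
    overflow int64); ``weighted`` and ``sim`` are double precision.
    """

    raw_counts: np.ndarray
    weighted: np.ndarray
    sim: np.ndarray
    max_weighted: float = field(default=0.0)

    @property
    def t(self) -> int:
        return self.sim.shape[0]


def _pair_histogram(data: SequenceSet, i: int, j: int, l: int) -> np.ndarray:
    return lmer_distance_histogram(data.sequences[i], data.sequences[j], l)


def pair_candidate_count(s_i: str, s_j: str, table: CandidateCountTable) -> int:
    """Exact total candidate motifs generated by one sequence pair:
    sum over all window pairs of the tabulated count at their distance."""
    l = table.params.l
    hist = lmer_distance_histogram(s_i, s_j, l)
    counts = table.as_object_array(l + 1)
    return int(sum(int(h) * c for h, c in zip(hist, counts)))


def weighted_pair_count(s_i: str, s_j: str, table: CandidateCountTable) -> float:
    """Distance-weighted variant: each window pair contributes its tabulated
    count divided by (distance + 1), amplifying close pairs."""
    l = table.params.l
    hist = lmer_distance_histogram(s_i, s_j, l)
    weights = table.as_array(l + 1) / (np.arange(l + 1, dtype=np.float64) + 1.0)
    return float(hist @ weights)


def _histogram_stage(
    data: SequenceSet, l: int, workers: int
) -> list[np.ndarray]:
    """Distance histograms for all C(t, 2) pairs, in fixed pair order.

    Pairs are flattened into one task list and dispatched in chunks; each
    result lands in a preassigned slot, so the output is identical for any
    worker count.
    """
    t = data.t
    pairs = [(i, j) for i in range(t) for j in range(i + 1, t)]
    results: list[np.ndarray | None] = [None] * len(pairs)

    def run(idx: int) -> None:
        i, j = pairs[idx]
        results[idx] = _pair_histogram(data, i, j, l)

    if workers <= 1 or len(pairs) < 2:
        for idx in range(len(pairs)):
            run(idx)
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            list(pool.map(run, range(len(pairs))))
    return results  # type: ignore[return-value]


def similarity_matrix(
    data: SequenceSet, params: PMSParams, workers: int = 1, *,
    table: CandidateCountTable | None = None,
) -> SimilarityMatrix:
    """Compute raw/weighted counts for all pairs and the similarity matrix.

    Similarity of a pair is the maximum weighted count over all pairs divided
    by the pair's own weighted count, so the most count-heavy (least
    desirable) pair has similarity exactly 1 and all others are >= 1.  Pairs
    with weighted count 0 are capped at the highest finite similarity (max
    over the smallest positive weighted count); if every pair is 0 all
    similarities are set to 1.
    """
    if data.t < 2:
        raise ValueError("need at least 2 sequences")
    if workers < 1:
        raise ValueError("workers must be >= 1")
    from .motif_math import build_count_table

    if table is None:
        table = build_count_table(params)
    t, l = data.t, params.l
    hists = _histogram_stage(data, l, workers)

    exact_counts = table.as_object_array(l + 1)
    inv_weights = table.as_array(l + 1) / (np.arange(l + 1) + 1.0)

    raw = np.zeros((t, t), dtype=object)
    raw[:] = 0
    weighted = np.zeros((t, t), dtype=np.float64)
    idx = 0
    for i in range(t):
        for j in range(i + 1, t):
            hist = hists[idx]
            idx += 1
            r = int(sum(int(h) * c for h, c in zip(hist, exact_counts)))
            w = float(hist @ inv_weights)
            raw[i, j] = raw[j, i] = r
            weighted[i, j] = weighted[j, i] = w

    iu = np.triu_indices(t, k=1)
    upper = weighted[iu]
    max_w = float(upper.max()) if upper.size else 0.0
    sim = np.zeros((t, t), dtype=np.float64)
    positive = upper > 0
    if max_w > 0:
        min_pos = float(upper[positive].min())
        sim_vals = max_w / np.where(positive, upper, min_pos)
    else:
        sim_vals = np.ones_like(upper)
    sim[iu] = sim_vals
    sim.T[iu] = sim_vals
    return SimilarityMatrix(
        raw_counts=raw, weighted=weighted, sim=sim, max_weighted=max_w
    )


def total_candidate_count(indices, matrix: SimilarityMatrix) -> int:
    """Total candidate motifs for a reference set: sum of raw counts over all
    unordered pairs within ``indices``."""
    idx = list(indices)
    if len(idx) != len(set(idx)):
        raise ValueError("indices must be distinct")
    if len(idx) < 2:
        raise ValueError("need at least 2 indices")
    t = matrix.t
    if any(i < 0 or i >= t for i in idx):
        raise ValueError("index out of range")
    return int(
        sum(matrix.raw_counts[a, b] for p, a in enumerate(idx) for b in idx[p + 1:])
    )
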