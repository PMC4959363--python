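"""Planted (l, d) benchmark generator, evaluation ratio, and brute-force
neighborhood oracles.

Datasets are built by drawing i.i.d. uniform background sequences, one
uniform l-length motif, and implanting into q of the t sequences a motif
instance that differs from the motif in at most d (or exactly d) positions,
overwriting a uniformly chosen window so sequence length stays fixed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .motif_math import PMSParams, build_count_table
from .pairwise import (
    SequenceSet,
    SimilarityMatrix,
    resolve_alphabet,
    similarity_matrix,
    total_candidate_count,
)

__all__ = [
    "Implant",
    "PlantedDataset",
    "generate_planted_dataset",
    "evaluate_ratio",
    "brute_force_common_neighbors",
]

_BRUTE_FORCE_GUARD = 10**7


@dataclass(frozen=True)
class Implant:
    sequence_index: int
    start: int
    instance: str
    distance: int


@dataclass
class PlantedDataset:
    data: SequenceSet
    motif: str
    implants: list[Implant]
    settings: dict


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def generate_planted_dataset(
    t: int,
    n: int,
    l: int,
    d: int,
    q: int | None = None,
    alphabet: str = "dna",
    seed: int | None = None,
    mode: str = "at_most_d",
) -> PlantedDataset:
    """Generate a planted (l, d) motif-search benchmark.

    The number of mismatches per instance is uniform on {0..d} in
    ``at_most_d`` mode and exactly d in ``exact_d`` mode; mismatch positions
    are uniform without replacement and substituted characters uniform over
    the remaining alphabet.  Fully reproducible from ``seed``.
    """
    chars = resolve_alphabet(alphabet)
    sigma = len(chars)
    if q is None:
        q = t
    if not 0 < q <= t:
        raise ValueError(f"require 0 < q <= t, got q={q}, t={t}")
    if not 0 <= d < l < n:
        raise ValueError(f"require 0 <= d < l < n, got d={d}, l={l}, n={n}")
    if mode not in ("at_most_d", "exact_d"):
        raise ValueError(f"mode must be 'at_most_d' or 'exact_d', got {mode!r}")

    rng = np.random.default_rng(seed)
    background = rng.integers(0, sigma, size=(t, n))
    motif_codes = rng.integers(0, sigma, size=l)
    chosen = np.sort(rng.choice(t, size=q, replace=False))

    implants: list[Implant] = []
    seqs = background.copy()
    for si in chosen:
        n_mm = int(d) if mode == "exact_d" else int(rng.integers(0, d + 1))
        instance = motif_codes.copy()
        if n_mm:
            positions = rng.choice(l, size=n_mm, replace=False)
            for p in positions:
                # uniform over the sigma - 1 alternatives
                shift = int(rng.integers(1, sigma))
                instance[p] = (instance[p] + shift) % sigma
        start = int(rng.integers(0, n - l + 1))
        seqs[si, start : start + l] = instance
        implants.append(
            Implant(
                sequence_index=int(si),
                start=start,
                instance="".join(chars[c] for c in instance),
                distance=int((instance != motif_codes).sum()),
            )
        )

    sequences = ["".join(chars[c] for c in row) for row in seqs]
    data = SequenceSet(
        sequences=sequences,
        identifiers=[f"seq{i + 1}" for i in range(t)],
        alphabet=alphabet,
    )
    return PlantedDataset(
        data=data,
        motif="".join(chars[c] for c in motif_codes),
        implants=implants,
        settings=dict(
            t=t, n=n, l=l, d=d, q=q, sigma=sigma, seed=seed, mode=mode
        ),
    )


def evaluate_ratio(
    data: SequenceSet,
    selected,
    k: int,
    params: PMSParams,
    *,
    matrix: SimilarityMatrix | None = None,
    workers: int = 1,
) -> dict:
    """Candidate-count ratio of the first-k set to the selected k-set.

    Returns a dict with ``n_original`` (total count over the first k input
    sequences), ``n_improved`` (total count over the selected set) and
    ``ratio`` = n_original / n_improved (inf if n_improved is 0).
    A ratio above 1 means the selection reduced the candidate space.
    """
    indices = list(getattr(selected, "indices", selected))
    if len(indices) != k:
        raise ValueError(f"selected set has {len(indices)} members, expected {k}")
    if matrix is None:
        matrix = similarity_matrix(data, params, workers=workers)
    n_original = total_candidate_count(list(range(k)), matrix)
    n_improved = total_candidate_count(indices, matrix)
    ratio = float("inf") if n_improved == 0 else n_original / n_improved
    return {"n_original": n_original, "n_improved": n_improved, "ratio": ratio}


def brute_force_common_neighbors(
    lmers,
    d: int,
    sigma: int,
    *,
    return_set: bool = False,
):
    """Count (by full enumeration) the l-length strings within distance d of
    every given l-mer.  Guarded at sigma^l <= 10^7 strings.

    For a single l-mer this is the d-ball volume; for pairs it independently
    cross-checks the tabulated common-candidate counts; for triples it
    supports tendency checks on the joint neighborhood.
    """
    lmers = list(lmers)
    if not lmers:
        raise ValueError("need at least one l-mer")
    l = len(lmers[0])
    if any(len(x) != l for x in lmers):
        raise ValueError("all l-mers must have equal length")
    if sigma**l > _BRUTE_FORCE_GUARD:
        raise ValueError(
            f"sigma^l = {sigma**l} exceeds the enumeration guard "
            f"({_BRUTE_FORCE_GUARD})"
        )
    centers = _encode_all(lmers, sigma)
    # enumerate all sigma^l strings as a (sigma^l, l) code array
    grid = np.array(
        list(itertools.product(range(sigma), repeat=l)), dtype=np.int8
    )
    ok = np.ones(grid.shape[0], dtype=bool)
    for c in centers:
        ok &= (grid != c).sum(axis=1) <= d
    if return_set:
        return int(ok.sum()), grid[ok]
    return int(ok.sum())


def _encode_all(lmers, sigma: int) -> list[np.ndarray]:
    """Map l-mers (strings or code sequences) to integer codes in [0, sigma),
    using one shared character mapping so cross-l-mer distances are correct."""
    if not isinstance(lmers[0], str):
        out = [np.asarray(x, dtype=np.int8) for x in lmers]
        if any(a.min() < 0 or a.max() >= sigma for a in out):
            raise ValueError("codes out of alphabet range")
        return out
    used = sorted(set("".join(lmers)))
    chars = None
    for name in ("dna", "protein"):
        canonical = resolve_alphabet(name)
        if len(canonical) == sigma and set(used) <= set(canonical):
            chars = canonical
            break
    if chars is None:
        if len(used) > sigma:
            raise ValueError(
                f"l-mers use {len(used)} distinct characters, more than sigma={sigma}"
            )
        chars = "".join(used)
    index = {ch: i for i, ch in enumerate(chars)}
    return [np.array([index[ch] for ch in x], dtype=np.int8) for x in lmers]
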