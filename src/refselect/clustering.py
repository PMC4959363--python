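"""Markov clustering of the similarity graph and greedy reference selection.

The similarity matrix is clustered with MCL (expansion = matrix squaring,
inflation = entrywise powering with column renormalization, inflation 1.8 by
default).  Each cluster is refined into an exactly-k reference set: clusters
of size k pass through, larger clusters are reduced greedily from their best
pair, smaller ones are grown greedily from the whole graph.  The set with the
highest total internal similarity wins.  An exhaustive enumerator over all
k-subsets serves as the exact baseline and test oracle.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .pairwise import SimilarityMatrix, total_candidate_count

__all__ = [
    "MCLConfig",
    "ClusterSet",
    "ReferenceSet",
    "mcl_cluster",
    "refine_cluster",
    "score_set",
    "select_references",
    "exhaustive_select",
]


@dataclass(frozen=True)
class MCLConfig:
    inflation: float = 1.8
    expansion: int = 2
    max_iterations: int = 100
    convergence_tolerance: float = 1e-8
    prune_threshold: float = 1e-14

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.expansion < 2:
            raise ValueError("expansion must be >= 2")
        if self.convergence_tolerance <= 0 or self.prune_threshold <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class ClusterSet:
    """Disjoint node clusters with per-cluster validity (singletons invalid)."""

    clusters: list[list[int]]
    converged: bool = True

    @property
    def validity(self) -> list[bool]:
        return [len(c) > 1 for c in self.clusters]


@dataclass
class ReferenceSet:
    """An ordered k-subset of sequence indices with its selection score."""

    indices: list[int]
    score: float
    total_count: int | None = None
    provenance: str = ""

    @property
    def k(self) -> int:
        return len(self.indices)


def _column_normalize(m: np.ndarray) -> np.ndarray:
    colsum = m.sum(axis=0)
    colsum[colsum == 0] = 1.0
    return m / colsum


def mcl_cluster(matrix: SimilarityMatrix, config: MCLConfig = MCLConfig()) -> ClusterSet:
    """Markov clustering of the similarity graph.

    Self-loops are set per node to its maximum incident similarity (standard
    damping), columns are normalized to stochastic, and expansion/inflation
    iterations run until the maximum absolute entry change drops below the
    tolerance or the iteration cap is hit.  Attractors are nodes with a
    positive diagonal in the limit matrix; overlapping attractor systems are
    merged, and each non-attractor node joins the system toward which it has
    the largest total weight (ties to the system with the lowest index).
    """
    sim = np.asarray(matrix.sim, dtype=np.float64)
    if not np.all(np.isfinite(sim)) or np.any(sim < 0):
        raise ValueError("similarity entries must be finite and non-negative")
    t = sim.shape[0]
    m = sim.copy()
    row_max = m.max(axis=1)
    row_max[row_max == 0] = 1.0
    np.fill_diagonal(m, row_max)
    m = _column_normalize(m)

    converged = False
    for _ in range(config.max_iterations):
        prev = m
        m = np.linalg.matrix_power(m, config.expansion)
        m = np.power(m, config.inflation)
        m[m < config.prune_threshold] = 0.0
        m = _column_normalize(m)
        if np.max(np.abs(m - prev)) < config.convergence_tolerance:
            converged = True
            break
    if not converged:
        warnings.warn(
            "MCL did not converge within max_iterations; "
            "interpreting the current matrix",
            RuntimeWarning,
            stacklevel=2,
        )

    eps = config.prune_threshold
    attractors = [i for i in range(t) if m[i, i] > eps]
    if not attractors:
        # degenerate limit; treat every node as its own attractor
        attractors = list(range(t))

    # merge attractor systems that overlap (flow between attractors)
    parent = list(range(len(attractors)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for ai, a in enumerate(attractors):
        for bi in range(ai + 1, len(attractors)):
            b = attractors[bi]
            if m[a, b] > eps or m[b, a] > eps:
                union(ai, bi)

    systems: dict[int, list[int]] = {}
    for ai, a in enumerate(attractors):
        systems.setdefault(find(ai), []).append(a)
    # order systems by their lowest attractor index for deterministic ties
    ordered = sorted(systems.values(), key=lambda s: min(s))

    clusters: list[list[int]] = [list(s) for s in ordered]
    member_of = {a: ci for ci, s in enumerate(ordered) for a in s}
    for v in range(t):
        if v in member_of:
            continue
        weights = [sum(m[a, v] for a in s) for s in ordered]
        best = int(np.argmax(weights))  # argmax takes first (lowest) on ties
        if weights[best] <= eps:
            clusters.append([v])  # isolated node: its own (invalid) cluster
        else:
            clusters[best].append(v)
    clusters = sorted((sorted(c) for c in clusters), key=lambda c: c[0])
    return ClusterSet(clusters=clusters, converged=converged)


def score_set(indices, matrix: SimilarityMatrix) -> float:
    """Total internal similarity: sum of sim over unordered pairs."""
    idx = list(indices)
    if len(idx) < 2:
        raise ValueError("need at least 2 indices to score")
    return float(
        sum(matrix.sim[a, b] for p, a in enumerate(idx) for b in idx[p + 1:])
    )


def _greedy_extend(
    current: list[int], pool: list[int], k: int, sim: np.ndarray
) -> list[int]:
    """Repeatedly add the pool node with the largest total similarity to the
    current set until it has k members.  Ties break to the lowest index."""
    chosen = list(current)
    remaining = sorted(set(pool) - set(chosen))
    while len(chosen) < k:
        best_node, best_gain = None, -np.inf
        for cand in remaining:
            gain = float(sim[cand, chosen].sum())
            if gain > best_gain:
                best_node, best_gain = cand, gain
        chosen.append(best_node)
        remaining.remove(best_node)
    return chosen


def _best_pair(nodes: list[int], sim: np.ndarray) -> tuple[int, int]:
    best, best_sim = None, -np.inf
    for a, b in itertools.combinations(sorted(nodes), 2):
        if sim[a, b] > best_sim:
            best, best_sim = (a, b), sim[a, b]
    return best


def refine_cluster(
    cluster, k: int, matrix: SimilarityMatrix
) -> ReferenceSet | None:
    """Turn one cluster into an exactly-k reference set (None if invalid).

    Size 1: invalid.  Size k: the cluster itself.  Size > k: greedy selection
    inside the cluster seeded with its most similar pair.  Size in (1, k):
    grow the cluster greedily from the whole graph.
    """
    nodes = sorted(cluster)
    t = matrix.t
    if not 1 < k < t:
        raise ValueError(f"require 1 < k < t, got k={k}, t={t}")
    if not nodes:
        raise ValueError("cluster must be non-empty")
    if len(nodes) == 1:
        return None
    sim = matrix.sim
    if len(nodes) == k:
        indices, case = nodes, "a"
    elif len(nodes) > k:
        seed = list(_best_pair(nodes, sim))
        indices = _greedy_extend(seed, nodes, k, sim)
        case = "b"
    else:
        indices = _greedy_extend(nodes, list(range(t)), k, sim)
        case = "c"
    indices = sorted(indices)
    return ReferenceSet(
        indices=indices, score=score_set(indices, matrix), provenance=f"case_{case}"
    )


def select_references(
    matrix: SimilarityMatrix, k: int, config: MCLConfig = MCLConfig()
) -> ReferenceSet:
    """Full selection: cluster, refine every valid cluster, keep the
    highest-scoring k-set (ties to the lexicographically smallest index
    list).  Falls back to whole-graph greedy if no cluster yields a set."""
    t = matrix.t
    if not 1 < k < t:
        raise ValueError(f"require 1 < k < t, got k={k}, t={t}")
    clusters = mcl_cluster(matrix, config)
    candidates = [
        rs
        for c in clusters.clusters
        if (rs := refine_cluster(c, k, matrix)) is not None
    ]
    if not candidates:
        nodes = list(range(t))
        seed = list(_best_pair(nodes, matrix.sim))
        indices = sorted(_greedy_extend(seed, nodes, k, matrix.sim))
        best = ReferenceSet(
            indices=indices,
            score=score_set(indices, matrix),
            provenance="fallback",
        )
    else:
        best = max(candidates, key=lambda rs: (rs.score, [-i for i in rs.indices]))
    best.total_count = total_candidate_count(best.indices, matrix)
    return best


def exhaustive_select(
    matrix: SimilarityMatrix, k: int, *, max_subsets: int = 10**6
) -> ReferenceSet:
    """Exact minimizer of the total candidate count over all k-subsets.

    Guard: refuses when C(t, k) exceeds ``max_subsets``.  Intended as the
    oracle / exact mode for small t.
    """
    from math import comb

    t = matrix.t
    if k == t:
        indices = list(range(t))
        return ReferenceSet(
            indices=indices,
            score=score_set(indices, matrix),
            total_count=total_candidate_count(indices, matrix),
            provenance="exhaustive",
        )
    if not 1 < k < t:
        raise ValueError(f"require 1 < k <= t, got k={k}, t={t}")
    n_subsets = comb(t, k)
    if n_subsets > max_subsets:
        raise ValueError(
            f"C({t}, {k}) = {n_subsets} subsets exceeds the enumeration guard "
            f"({max_subsets}); use select_references instead"
        )
    best_idx: tuple[int, ...] | None = None
    best_total: int | None = None
    for combo in itertools.combinations(range(t), k):
        tot = total_candidate_count(combo, matrix)
        if best_total is None or tot < best_total:
            best_idx, best_total = combo, tot
    indices = list(best_idx)
    return ReferenceSet(
        indices=indices,
        score=score_set(indices, matrix),
        total_count=best_total,
        provenance="exhaustive",
    )
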