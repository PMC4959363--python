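import itertools

import numpy as np
import pytest

from refselect.clustering import (
    MCLConfig,
    exhaustive_select,
    mcl_cluster,
    refine_cluster,
    score_set,
    select_references,
)
from refselect.motif_math import PMSParams
from refselect.pairwise import SimilarityMatrix, similarity_matrix, total_candidate_count
from refselect.synth_eval import generate_planted_dataset

from conftest import random_sequences


def matrix_from_sim(sim: np.ndarray) -> SimilarityMatrix:
    """Wrap a hand-built symmetric similarity matrix; raw counts mirror
    1/sim so that low similarity means many candidates."""
    t = sim.shape[0]
    raw = np.zeros((t, t), dtype=object)
    for i in range(t):
        for j in range(t):
            if i != j and sim[i, j] > 0:
                raw[i, j] = int(round(1e6 / sim[i, j]))
    return SimilarityMatrix(
        raw_counts=raw, weighted=sim.copy(), sim=sim.astype(float),
        max_weighted=float(sim.max()),
    )


def two_group_matrix(t: int = 12, within: float = 10.0, between: float = 1.0):
    sim = np.full((t, t), between)
    half = t // 2
    sim[:half, :half] = within
    sim[half:, half:] = within
    np.fill_diagonal(sim, 0.0)
    return sim


class TestMCLConfig:
    def test_defaults(self):
        cfg = MCLConfig()
        assert cfg.inflation == 1.8 and cfg.expansion == 2

    @pytest.mark.parametrize(
        "kwargs", [dict(inflation=1.0), dict(expansion=1), dict(prune_threshold=0)]
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            MCLConfig(**kwargs)


class TestMCL:
    def test_two_nodes_one_cluster(self):
        sim = np.array([[0.0, 2.0], [2.0, 0.0]])
        cs = mcl_cluster(matrix_from_sim(sim))
        assert cs.clusters == [[0, 1]]

    def test_block_diagonal_never_spans(self):
        sim = two_group_matrix(10, within=5.0, between=0.0)
        cs = mcl_cluster(matrix_from_sim(sim))
        for c in cs.clusters:
            assert set(c) <= {0, 1, 2, 3, 4} or set(c) <= {5, 6, 7, 8, 9}

    def test_planted_two_groups_recovered(self):
        sim = two_group_matrix(12)
        cs = mcl_cluster(matrix_from_sim(sim))
        assert sorted(map(sorted, cs.clusters)) == [
            [0, 1, 2, 3, 4, 5],
            [6, 7, 8, 9, 10, 11],
        ]

    def test_deterministic(self):
        sim = two_group_matrix(8)
        a = mcl_cluster(matrix_from_sim(sim))
        b = mcl_cluster(matrix_from_sim(sim))
        assert a.clusters == b.clusters

    def test_singleton_flagged_invalid(self):
        # one node weakly attached to nothing
        sim = two_group_matrix(6, within=10.0, between=0.0)
        sim[5, :] = 0.0
        sim[:, 5] = 0.0
        cs = mcl_cluster(matrix_from_sim(sim))
        flags = dict(zip(map(tuple, cs.clusters), cs.validity))
        assert flags[(5,)] is False

    def test_rejects_nonfinite(self):
        sim = two_group_matrix(4)
        sim[0, 1] = sim[1, 0] = np.inf
        with pytest.raises(ValueError):
            mcl_cluster(matrix_from_sim(sim))

    def test_every_node_assigned_once(self, rng):
        for _ in range(10):
            t = int(rng.integers(4, 12))
            sim = rng.uniform(1, 5, size=(t, t))
            sim = (sim + sim.T) / 2
            np.fill_diagonal(sim, 0.0)
            cs = mcl_cluster(matrix_from_sim(sim))
            members = sorted(i for c in cs.clusters for i in c)
            assert members == list(range(t))


class TestScoreSet:
    def test_two_indices(self):
        sim = two_group_matrix(6)
        m = matrix_from_sim(sim)
        assert score_set([0, 1], m) == pytest.approx(sim[0, 1])

    def test_superset_monotone(self):
        sim = two_group_matrix(6)
        m = matrix_from_sim(sim)
        assert score_set([0, 1, 2], m) > score_set([0, 1], m)

    def test_direct_sum_of_four(self):
        sim = two_group_matrix(6)
        m = matrix_from_sim(sim)
        idx = [0, 2, 3, 5]
        want = sum(sim[a, b] for a, b in itertools.combinations(idx, 2))
        assert score_set(idx, m) == pytest.approx(want)

    def test_too_few(self):
        m = matrix_from_sim(two_group_matrix(4))
        with pytest.raises(ValueError):
            score_set([1], m)


def naive_greedy(pool, seed, k, sim):
    """Independent re-implementation of the greedy extension."""
    chosen = list(seed)
    remaining = sorted(set(pool) - set(chosen))
    while len(chosen) < k:
        best = max(remaining, key=lambda c: (sum(sim[c, j] for j in chosen), -c))
        chosen.append(best)
        remaining.remove(best)
    return sorted(chosen)


class TestRefineCluster:
    def test_singleton_invalid(self):
        m = matrix_from_sim(two_group_matrix(6))
        assert refine_cluster([3], k=3, matrix=m) is None

    def test_exact_k_passthrough(self):
        m = matrix_from_sim(two_group_matrix(6))
        rs = refine_cluster([1, 3, 4], k=3, matrix=m)
        assert rs.indices == [1, 3, 4]
        assert rs.provenance == "case_a"

    def test_case_b_hand_trace(self):
        # 5 nodes, k = 3: best pair is (1, 2); node 0 then has the largest
        # summed similarity to {1, 2}
        sim = np.array(
            [
                [0, 5, 4, 1, 1],
                [5, 0, 9, 1, 1],
                [4, 9, 0, 2, 1],
                [1, 1, 2, 0, 3],
                [1, 1, 1, 3, 0],
            ],
            dtype=float,
        )
        rs = refine_cluster([0, 1, 2, 3, 4], k=3, matrix=matrix_from_sim(sim))
        assert rs.provenance == "case_b"
        assert rs.indices == [0, 1, 2]

    def test_case_c_grows_from_whole_graph(self):
        sim = two_group_matrix(8)
        m = matrix_from_sim(sim)
        rs = refine_cluster([0, 1], k=4, matrix=m)
        assert rs.provenance == "case_c"
        assert len(rs.indices) == 4
        assert {0, 1} <= set(rs.indices)
        # grown nodes come from the same dense block
        assert set(rs.indices) <= {0, 1, 2, 3}

    @pytest.mark.parametrize("trial", range(20))
    def test_greedy_matches_naive_reimplementation(self, rng, trial):
        t = int(rng.integers(6, 11))
        sim = rng.uniform(0.5, 5, size=(t, t))
        sim = (sim + sim.T) / 2
        np.fill_diagonal(sim, 0.0)
        m = matrix_from_sim(sim)
        k = int(rng.integers(2, t - 1))
        cluster = sorted(
            rng.choice(t, size=int(rng.integers(2, t + 1)), replace=False).tolist()
        )
        rs = refine_cluster(cluster, k=k, matrix=m)
        if len(cluster) == k:
            assert rs.indices == cluster
        elif len(cluster) > k:
            pairs = list(itertools.combinations(cluster, 2))
            seed = max(pairs, key=lambda p: (sim[p[0], p[1]], (-p[0], -p[1])))
            assert rs.indices == naive_greedy(cluster, seed, k, sim)
        else:
            assert rs.indices == naive_greedy(range(t), cluster, k, sim)

    def test_cardinality_always_k(self, rng):
        for _ in range(30):
            t = int(rng.integers(5, 12))
            sim = rng.uniform(0.5, 3, size=(t, t))
            sim = (sim + sim.T) / 2
            np.fill_diagonal(sim, 0.0)
            m = matrix_from_sim(sim)
            k = int(rng.integers(2, t))
            size = int(rng.integers(2, t + 1))
            cluster = sorted(rng.choice(t, size=size, replace=False).tolist())
            rs = refine_cluster(cluster, k=k, matrix=m)
            assert len(rs.indices) == k == len(set(rs.indices))

    def test_k_out_of_range(self):
        m = matrix_from_sim(two_group_matrix(5))
        with pytest.raises(ValueError):
            refine_cluster([0, 1], k=1, matrix=m)
        with pytest.raises(ValueError):
            refine_cluster([0, 1], k=5, matrix=m)


class TestSelectReferences:
    def test_returns_k_distinct(self, rng, toy_params):
        data = random_sequences(rng, t=8, n=30)
        m = similarity_matrix(data, toy_params)
        rs = select_references(m, k=3)
        assert len(rs.indices) == 3 == len(set(rs.indices))
        assert rs.total_count == total_candidate_count(rs.indices, m)

    def test_deterministic(self, rng, toy_params):
        data = random_sequences(rng, t=8, n=30)
        m = similarity_matrix(data, toy_params)
        assert select_references(m, k=3).indices == select_references(m, k=3).indices

    def test_score_recomputable(self, rng, toy_params):
        data = random_sequences(rng, t=8, n=30)
        m = similarity_matrix(data, toy_params)
        rs = select_references(m, k=4)
        assert rs.score == pytest.approx(score_set(rs.indices, m))

    def test_beats_median_on_small_planted_instances(self):
        params = PMSParams(l=9, d=2, sigma=4)
        wins = 0
        for seed in range(20):
            ds = generate_planted_dataset(
                t=8, n=50, l=9, d=2, alphabet="dna", seed=seed
            )
            m = similarity_matrix(ds.data, params)
            rs = select_references(m, k=3)
            totals = sorted(
                total_candidate_count(c, m)
                for c in itertools.combinations(range(8), 3)
            )
            median = totals[len(totals) // 2]
            if rs.total_count <= median:
                wins += 1
        assert wins >= 16  # >= 80 % of 20 seeds

    def test_avoids_pairing_identical_implants(self):
        # two sequences sharing an identical planted l-mer have a huge raw
        # count; selection should rarely put both in the reference set
        params = PMSParams(l=9, d=2, sigma=4)
        together = 0
        n_seeds = 50
        rng = np.random.default_rng(7)
        for _ in range(n_seeds):
            data = random_sequences(rng, t=8, n=50)
            motif = "".join("ACGT"[c] for c in rng.integers(0, 4, 9))
            seqs = list(data.sequences)
            for idx in (0, 1):
                pos = int(rng.integers(0, 50 - 9 + 1))
                seqs[idx] = seqs[idx][:pos] + motif + seqs[idx][pos + 9:]
            data.sequences = seqs
            m = similarity_matrix(data, params)
            rs = select_references(m, k=3)
            if {0, 1} <= set(rs.indices):
                together += 1
        assert together < 0.2 * n_seeds


class TestExhaustiveSelect:
    def test_matches_naive_enumeration(self, rng, toy_params):
        data = random_sequences(rng, t=8, n=25)
        m = similarity_matrix(data, toy_params)
        rs = exhaustive_select(m, k=3)
        best = min(
            itertools.combinations(range(8), 3),
            key=lambda c: (total_candidate_count(c, m), c),
        )
        assert tuple(rs.indices) == best
        assert rs.total_count == total_candidate_count(best, m)

    def test_drop_one(self, rng, toy_params):
        data = random_sequences(rng, t=5, n=25)
        m = similarity_matrix(data, toy_params)
        rs = exhaustive_select(m, k=4)
        candidates = [
            sorted(set(range(5)) - {i}) for i in range(5)
        ]
        best = min(candidates, key=lambda c: (total_candidate_count(c, m), c))
        assert rs.indices == best

    def test_k_equals_t(self, rng, toy_params):
        data = random_sequences(rng, t=4, n=25)
        m = similarity_matrix(data, toy_params)
        assert exhaustive_select(m, k=4).indices == [0, 1, 2, 3]

    def test_guard(self, rng, toy_params):
        data = random_sequences(rng, t=8, n=25)
        m = similarity_matrix(data, toy_params)
        with pytest.raises(ValueError, match="guard"):
            exhaustive_select(m, k=4, max_subsets=10)
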