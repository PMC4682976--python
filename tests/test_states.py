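import numpy as np
import pytest
from sympy.utilities.iterables import multiset_partitions

import netstates as ns


def exhaustive_max_modularity(S, gamma=1.0):
    """Oracle: enumerate all set partitions of T <= ~10 windows."""
    T = S.shape[0]
    best_q, best_labels = -np.inf, None
    for part in multiset_partitions(list(range(T))):
        labels = np.empty(T, dtype=int)
        for k, block in enumerate(part):
            labels[list(block)] = k
        q = ns.modularity_score(S, labels, gamma)
        if q > best_q:
            best_q, best_labels = q, labels
    return best_q, best_labels


def direct_modularity(S, labels, gamma):
    """Brute-force double sum over all window pairs."""
    W = ns.preprocess_similarity(S)
    two_m = W.sum()
    if two_m == 0:
        return 0.0
    s = W.sum(axis=1)
    q = 0.0
    for k in range(len(labels)):
        for l in range(len(labels)):
            if labels[k] == labels[l]:
                q += W[k, l] - gamma * s[k] * s[l] / two_m
    return q / two_m


def two_block_similarity(sizes=(4, 4), within=0.9, between=0.0):
    T = sum(sizes)
    S = np.full((T, T), between)
    S[: sizes[0], : sizes[0]] = within
    S[sizes[0] :, sizes[0] :] = within
    np.fill_diagonal(S, 1.0)
    return S


class TestConfigurationSimilarity:
    def test_identical_columns(self):
        cfg = np.tile(np.array([[1.0], [2.0], [5.0]]), (1, 3))
        S = ns.configuration_similarity(cfg)
        assert np.allclose(S, 1.0)

    def test_anticorrelated_columns(self):
        col = np.array([1.0, 2.0, 3.0])
        S = ns.configuration_similarity(np.column_stack([col, -col]))
        assert S[0, 1] == pytest.approx(-1.0)

    def test_matches_direct_pearson(self, rng):
        cfg = rng.standard_normal((6, 4))
        S = ns.configuration_similarity(cfg)
        for k in range(4):
            for l in range(4):
                expected = np.corrcoef(cfg[:, k], cfg[:, l])[0, 1]
                assert S[k, l] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_column_warns(self, rng):
        cfg = rng.standard_normal((6, 3))
        cfg[:, 1] = 0.7
        with pytest.warns(UserWarning, match="zero-variance"):
            S = ns.configuration_similarity(cfg)
        assert S[0, 1] == 0.0 and S[1, 1] == 1.0


class TestModularityScore:
    def test_two_disconnected_blocks_give_half(self):
        S = two_block_similarity(within=0.8, between=0.0)
        np.fill_diagonal(S, 0.0)
        labels = np.array([0] * 4 + [1] * 4)
        assert ns.modularity_score(S, labels, 1.0) == pytest.approx(0.5)

    def test_single_community_is_zero(self, rng):
        X = rng.standard_normal((10, 6))
        S = np.corrcoef(X, rowvar=False)
        assert ns.modularity_score(S, np.zeros(6, int), 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_summation(self, rng):
        for _ in range(5):
            X = rng.standard_normal((10, 7))
            S = np.corrcoef(X, rowvar=False)
            labels = rng.integers(0, 3, size=7)
            assert ns.modularity_score(S, labels, 1.2) == pytest.approx(
                direct_modularity(S, labels, 1.2), abs=1e-10
            )

    def test_matches_networkx_modularity(self, rng):
        import networkx as nx

        X = rng.standard_normal((12, 8))
        S = ns.preprocess_similarity(np.corrcoef(X, rowvar=False))
        G = nx.from_numpy_array(S)
        labels = rng.integers(0, 3, size=8)
        comms = [set(np.flatnonzero(labels == k)) for k in range(3) if (labels == k).any()]
        expected = nx.community.modularity(G, comms, weight="weight", resolution=1.0)
        assert ns.modularity_score(S, labels, 1.0) == pytest.approx(expected, abs=1e-10)


class TestLouvain:
    def test_planted_two_blocks_recovered_any_seed(self):
        S = two_block_similarity()
        for seed in range(10):
            labels = ns.louvain_optimize(S, 1.0, seed)
            assert len(np.unique(labels)) == 2
            assert len(np.unique(labels[:4])) == 1 and len(np.unique(labels[4:])) == 1

    def test_reaches_exhaustive_maximum_on_most_seeds(self):
        hits = 0
        for seed in range(30):
            gen = np.random.default_rng(seed)
            T = gen.integers(5, 9)
            S = np.corrcoef(gen.standard_normal((10, T)), rowvar=False)
            best_q, _ = exhaustive_max_modularity(S)
            q = ns.modularity_score(S, ns.louvain_optimize(S, 1.0, seed), 1.0)
            hits += q >= best_q - 1e-9
        assert hits >= 27  # single greedy runs reach the global optimum on >= 90%

    def test_zero_offdiagonal_similarity_gives_singletons(self):
        S = np.eye(6)
        labels = ns.louvain_optimize(S, 1.0, 0)
        assert len(np.unique(labels)) == 6
        assert ns.modularity_score(S, labels, 1.0) == 0.0


class TestConsensus:
    def test_planted_recovery_and_binary_association(self):
        S = two_block_similarity(sizes=(5, 5))
        part = ns.consensus_partition(S, 1.0, n_optimizations=50, seed=0)
        assert part.converged
        assert len(np.unique(part.assignment)) == 2
        assert part.Q == pytest.approx(
            ns.modularity_score(S, np.array([0] * 5 + [1] * 5), 1.0)
        )

    def test_single_optimization_equals_single_run(self, rng):
        X = rng.standard_normal((10, 8))
        S = np.corrcoef(X, rowvar=False)
        part = ns.consensus_partition(S, 1.0, n_optimizations=1, seed=7)
        rng_run = np.random.default_rng(7)
        single = ns.louvain_optimize(S, 1.0, rng_run)
        assert np.array_equal(part.assignment, single)

    def test_window_permutation_equivariance(self, rng):
        S = two_block_similarity(sizes=(4, 5), within=0.8, between=0.1)
        perm = rng.permutation(9)
        part = ns.consensus_partition(S, 1.0, n_optimizations=30, seed=3)
        part_p = ns.consensus_partition(S[np.ix_(perm, perm)], 1.0, n_optimizations=30, seed=3)
        # unpermuted labels describe the same partition
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(part.assignment, part_p.assignment[np.argsort(perm)]) == 1.0

    def test_consensus_not_below_single_runs_on_planted(self):
        S = two_block_similarity(sizes=(6, 6), within=0.7, between=0.05)
        part = ns.consensus_partition(S, 1.0, n_optimizations=40, seed=1)
        rng = np.random.default_rng(1)
        for _ in range(40):
            q = ns.modularity_score(S, ns.louvain_optimize(S, 1.0, rng), 1.0)
            assert part.Q >= q - 1e-9

    def test_seed_determinism(self, rng):
        X = rng.standard_normal((10, 9))
        S = np.corrcoef(X, rowvar=False)
        a = ns.consensus_partition(S, 1.0, n_optimizations=25, seed=42)
        b = ns.consensus_partition(S, 1.0, n_optimizations=25, seed=42)
        assert np.array_equal(a.assignment, b.assignment) and a.Q == b.Q


class TestTuneGamma:
    def test_planted_blocks_fully_reliable(self):
        S = two_block_similarity(sizes=(5, 5))
        gamma = ns.tune_gamma(S, gamma_grid=[0.8, 1.0, 1.2], n_reps=8, seed=0)
        runs = [ns.louvain_optimize(S, gamma, seed) for seed in range(8)]
        from netstates.states import partition_reliability

        assert partition_reliability(runs) == pytest.approx(1.0)

    def test_reliability_of_identical_partitions_is_one(self):
        from netstates.states import partition_reliability

        runs = [np.array([0, 0, 1, 1, 2])] * 5
        assert partition_reliability(runs) == 1.0

    def test_pure_noise_flagged_degenerate(self):
        S = np.eye(8)
        with pytest.warns(UserWarning, match="degenerate"):
            gamma = ns.tune_gamma(S, gamma_grid=[0.9, 1.0, 1.1], n_reps=5, seed=0)
        assert gamma == 1.0


class TestFinalizeStates:
    def _partition(self, labels):
        return ns.StatePartition(
            assignment=np.asarray(labels), Q=0.3, gamma=1.0, n_optimizations=10
        )

    def test_three_largest_retained(self):
        # sizes: a=10, b=7, c=5, d=2
        labels = [0] * 10 + [1] * 7 + [2] * 5 + [3] * 2
        out = ns.finalize_states(self._partition(labels))
        assert out.retained_states == [0, 1, 2]
        sizes = out.state_sizes()
        assert sorted((sizes[s] for s in out.retained_states), reverse=True) == [10, 7, 5]
        assert sizes[3] == 2  # smallest state kept in the sequence, not retained

    def test_relabel_by_median_occurrence(self):
        # medians: A ~ 30, B ~ 5, C ~ 15  ->  order B, C, A
        labels = np.empty(40, dtype=int)
        labels[:10] = 1  # B early
        labels[10:20] = 2  # C middle
        labels[20:] = 0  # A late
        out = ns.finalize_states(self._partition(labels))
        assert np.all(out.assignment[:10] == 0)
        assert np.all(out.assignment[10:20] == 1)
        assert np.all(out.assignment[20:] == 2)

    def test_exactly_three_states_all_retained(self):
        out = ns.finalize_states(self._partition([0, 1, 2, 0, 1, 2]))
        assert out.retained_states == [0, 1, 2]

    def test_fewer_than_three_states_warns(self):
        with pytest.warns(UserWarning, match="retaining all"):
            out = ns.finalize_states(self._partition([0, 0, 1, 1]))
        assert out.retained_states == [0, 1]
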