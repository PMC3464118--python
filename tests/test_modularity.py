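"""RV coefficient, bipartition enumeration, contiguity filtering, two-block
PLS and its permutation test."""

from itertools import combinations

import numpy as np
import pytest

import morphomod as mm
from morphomod.modularity import left_tail_p


class TestRvCoefficient:
    def test_self_congruence(self, rng):
        X = rng.normal(size=(10, 4))
        assert mm.rv_coefficient(X, X) == pytest.approx(1.0, abs=1e-12)

    def test_block_rotation_invariance(self, rng):
        X, Y = rng.normal(size=(12, 4)), rng.normal(size=(12, 6))
        rv0 = mm.rv_coefficient(X, Y)
        qx, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        qy, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        assert mm.rv_coefficient(X @ qx, Y @ qy) == pytest.approx(rv0, abs=1e-12)

    def test_definition_oracle(self):
        X = np.array([[1.0, 0.3], [0.2, -1.1], [0.5, 0.9], [-0.7, 0.1], [1.3, -0.4]])
        Y = np.array([[0.9, -0.2], [0.1, 0.8], [-0.5, 0.4], [0.3, -1.0], [0.6, 0.2]])
        rv = mm.rv_coefficient(X, Y)
        # element-wise brute force of the defining traces
        Xc, Yc = X - X.mean(0), Y - Y.mean(0)
        sxx, syy, sxy = Xc.T @ Xc / 4, Yc.T @ Yc / 4, Xc.T @ Yc / 4
        num = np.trace(sxy @ sxy.T)
        den = np.sqrt(np.trace(sxx @ sxx) * np.trace(syy @ syy))
        assert rv == pytest.approx(num / den, abs=1e-12)
        assert 0.0 <= rv <= 1.0

    def test_in_unit_interval(self, rng):
        for _ in range(20):
            X, Y = rng.normal(size=(8, 3)), rng.normal(size=(8, 5))
            assert 0.0 <= mm.rv_coefficient(X, Y) <= 1.0


class TestEnumeration:
    def test_counts_match_closed_form(self):
        assert mm.count_bipartitions(16, (8, 8)) == 6435
        assert mm.count_bipartitions(4, (2, 2)) == 3
        assert mm.count_bipartitions(5, (2, 3)) == 10

    def test_exhaustive_uniqueness_oracle(self):
        for k, sizes in [(5, (2, 3)), (6, (3, 3)), (8, (4, 4)), (7, (3, 4))]:
            blocks = list(mm.enumerate_bipartitions(k, sizes))
            assert len(blocks) == mm.count_bipartitions(k, sizes)
            # brute-force oracle: all unordered {A, B} pairs via raw subsets
            seen = set()
            for sub in combinations(range(1, k + 1), sizes[0]):
                a = frozenset(sub)
                b = frozenset(range(1, k + 1)) - a
                seen.add(frozenset((a, b)))
            ours = {frozenset((a, frozenset(range(1, k + 1)) - a)) for a in blocks}
            assert ours == seen

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            mm.count_bipartitions(10, (4, 5))


class TestContiguity:
    @staticmethod
    def _cycle(k):
        return mm.AdjacencyGraph(k, [(i, i + 1) for i in range(1, k)] + [(k, 1)])

    def test_six_cycle_has_three_contiguous_halves(self):
        graph = self._cycle(6)
        parts = list(mm.enumerate_bipartitions(6, (3, 3)))
        contig = mm.contiguous_subset(parts, graph)
        assert len(contig) == 3
        # brute-force connectivity oracle with a hand-rolled DFS
        adj = {i: set() for i in range(1, 7)}
        for a, b in graph.edges:
            adj[a].add(b)
            adj[b].add(a)

        def connected(nodes):
            nodes = set(nodes)
            seen = {next(iter(nodes))}
            frontier = list(seen)
            while frontier:
                cur = frontier.pop()
                for nb in adj[cur] & nodes:
                    if nb not in seen:
                        seen.add(nb)
                        frontier.append(nb)
            return seen == nodes

        expected = [
            p for p in parts if connected(p) and connected(frozenset(range(1, 7)) - p)
        ]
        assert sorted(map(sorted, contig)) == sorted(map(sorted, expected))

    def test_complete_graph_all_contiguous(self):
        graph = mm.AdjacencyGraph(5, [(a, b) for a in range(1, 6) for b in range(a + 1, 6)])
        parts = list(mm.enumerate_bipartitions(5, (2, 3)))
        assert len(mm.contiguous_subset(parts, graph)) == len(parts)

    def test_path_graph_single_contiguous_split(self):
        graph = mm.AdjacencyGraph(4, [(1, 2), (2, 3), (3, 4)])
        parts = list(mm.enumerate_bipartitions(4, (2, 2)))
        contig = mm.contiguous_subset(parts, graph)
        assert [sorted(c) for c in contig] == [[1, 2]]

    def test_sixteen_cycle_contiguous_count(self):
        # arcs of length 8 on a 16-cycle: 16 rotations / 2 (complement pairs)
        graph = self._cycle(16)
        parts = mm.enumerate_bipartitions(16, (8, 8))
        assert len(mm.contiguous_subset(parts, graph)) == 8


class TestRvPartitionTest:
    def test_empirical_p_rule(self):
        values = np.concatenate([np.full(141, 0.1), [0.2], np.full(6435 - 142, 0.5)])
        count, p = left_tail_p(values, 0.2)
        assert count == 142
        assert p == pytest.approx(142 / 6435)
        assert round(p, 3) == 0.022

    def test_observed_partition_counted(self, rng, hypothesis_partition):
        data = rng.normal(size=(10, 32))
        res = mm.rv_partition_test(data, hypothesis_partition)
        assert res.p_full > 0
        assert res.count_leq_full >= 1
        assert res.n_total_partitions == 6435
        assert res.n_contiguous == 8

    def test_observed_rv_is_distribution_entry(self, rng, hypothesis_partition):
        data = rng.normal(size=(12, 32))
        res = mm.rv_partition_test(data, hypothesis_partition)
        idx = res.partitions.index(hypothesis_partition.block_a)
        assert res.observed_rv == res.rv_distribution[idx]
        # and matches a direct RV computation on the two blocks
        cols_a = np.ravel([[2 * (j - 1), 2 * (j - 1) + 1] for j in sorted(hypothesis_partition.block_a)])
        cols_b = np.ravel([[2 * (j - 1), 2 * (j - 1) + 1] for j in sorted(hypothesis_partition.block_b)])
        direct = mm.rv_coefficient(data[:, cols_a], data[:, cols_b])
        assert res.observed_rv == pytest.approx(direct, abs=1e-12)

    def test_modular_signal_lands_in_left_tail(self, rng, hypothesis_partition):
        """Data with independent blocks across the a-priori split score in
        the left tail of the enumerated RV distribution."""
        n = 40
        data = np.zeros((n, 32))
        cols_a = np.ravel([[2 * (j - 1), 2 * (j - 1) + 1] for j in sorted(hypothesis_partition.block_a)])
        cols_b = np.ravel([[2 * (j - 1), 2 * (j - 1) + 1] for j in sorted(hypothesis_partition.block_b)])
        data[:, cols_a] = rng.normal(size=(n, len(cols_a)))
        data[:, cols_b] = rng.normal(size=(n, len(cols_b)))
        res = mm.rv_partition_test(data, hypothesis_partition)
        assert res.p_full < 0.05


class TestTwoBlockPls:
    def test_identical_blocks(self, rng):
        X = rng.normal(size=(15, 4))
        res = mm.two_block_pls(X, X)
        assert res.score_correlations[0] == pytest.approx(1.0, abs=1e-10)
        # covariance fractions = normalized squared eigenvalues of Sxx
        Xc = X - X.mean(0)
        evals = np.sort(np.linalg.eigvalsh(Xc.T @ Xc / 14))[::-1]
        np.testing.assert_allclose(res.covariance_fractions, evals**2 / (evals**2).sum(), atol=1e-10)

    def test_diagonal_cross_covariance_fractions(self):
        X = np.array([[1.0, 0], [-1, 0], [0, 1], [0, -1]])
        Y = np.array([[4.5, 0], [-4.5, 0], [0, 1.5], [0, -1.5]])
        res = mm.two_block_pls(X, Y)
        np.testing.assert_allclose(res.singular_values, [3.0, 1.0], atol=1e-12)
        np.testing.assert_allclose(res.covariance_fractions, [0.9, 0.1], atol=1e-12)

    def test_power_iteration_oracle(self, rng):
        X, Y = rng.normal(size=(6, 3)), rng.normal(size=(6, 4))
        res = mm.two_block_pls(X, Y)
        Xc, Yc = X - X.mean(0), Y - Y.mean(0)
        S = Xc.T @ Yc / 5
        # power iteration with deflation on S S^T
        M = S @ S.T
        got = []
        for _ in range(3):
            v = np.ones(M.shape[0])
            for _ in range(5000):
                w = M @ v
                n = np.linalg.norm(w)
                if n == 0:
                    break
                v = w / n
            lam = float(v @ M @ v)
            got.append(np.sqrt(max(lam, 0.0)))
            M = M - lam * np.outer(v, v)
        np.testing.assert_allclose(res.singular_values, got, atol=1e-8)

    def test_fraction_invariants(self, rng):
        X, Y = rng.normal(size=(9, 5)), rng.normal(size=(9, 5))
        res = mm.two_block_pls(X, Y)
        assert res.covariance_fractions.sum() == pytest.approx(1.0)
        assert res.covariance_fractions[0] >= res.covariance_fractions.max() - 1e-15


class TestPlsPermutation:
    def test_identical_blocks_minimum_p(self, rng):
        X = rng.normal(size=(12, 3))
        res = mm.pls_permutation_test(X, X, n_perm=199, seed=1)
        assert res.permutation_p_covariance == pytest.approx(1 / 200)

    def test_seed_determinism(self, rng):
        X, Y = rng.normal(size=(10, 3)), rng.normal(size=(10, 3))
        r1 = mm.pls_permutation_test(X, Y, n_perm=199, seed=42)
        r2 = mm.pls_permutation_test(X, Y, n_perm=199, seed=42)
        assert r1.permutation_p_covariance == r2.permutation_p_covariance
        assert r1.permutation_p_correlation == r2.permutation_p_correlation

    def test_null_type_one_error(self, rng):
        n_rep = 150
        hits = 0
        for _ in range(n_rep):
            X, Y = rng.normal(size=(10, 3)), rng.normal(size=(10, 3))
            res = mm.pls_permutation_test(X, Y, n_perm=99, seed=int(rng.integers(2**31)))
            hits += res.permutation_p_covariance < 0.05
        rate = hits / n_rep
        assert rate < 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_minimum_permutations_enforced(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="99"):
            mm.pls_permutation_test(X, X, n_perm=10)
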