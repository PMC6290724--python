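from collections import deque

import numpy as np
import pytest

from rsnconn.nbs import (
    EdgeStats,
    edge_index_pairs,
    edge_statistics,
    nbs_test,
    suprathreshold_components,
)


def _bfs_components(edge_list, n_nodes):
    """Independent traversal oracle: components as frozensets of edges."""
    adj = {v: set() for v in range(n_nodes)}
    for i, j in edge_list:
        adj[i].add(j)
        adj[j].add(i)
    seen = set()
    comps = []
    for start in range(n_nodes):
        if start in seen or not adj[start]:
            continue
        nodes = set()
        q = deque([start])
        seen.add(start)
        while q:
            v = q.popleft()
            nodes.add(v)
            for w in adj[v]:
                if w not in seen:
                    seen.add(w)
                    q.append(w)
        edges = frozenset(
            tuple(sorted(e)) for e in edge_list if e[0] in nodes and e[1] in nodes
        )
        if edges:
            comps.append(edges)
    return comps


def _stats_from_edges(edge_list, n_nodes, t_val=3.0):
    E = n_nodes * (n_nodes - 1) // 2
    edges = edge_index_pairs(n_nodes)
    lut = {tuple(e): k for k, e in enumerate(map(tuple, edges))}
    t = np.zeros(E)
    for e in edge_list:
        t[lut[tuple(sorted(e))]] = t_val
    return EdgeStats(t=t, F=t * t, edges=edges, n_nodes=n_nodes)


class TestEdgeStatistics:
    def test_f_equals_t_squared(self, rng):
        Y = rng.normal(size=(20, 50))
        labels = ["patient"] * 10 + ["control"] * 10
        cov = np.column_stack([rng.normal(size=20), rng.integers(0, 2, 20)])
        es = edge_statistics(Y, labels, cov, n_nodes=None)
        assert np.allclose(es.F, es.t**2, atol=1e-9)

    def test_identical_groups_give_zero_f(self, rng):
        half = rng.normal(size=(5, 10))
        Y = np.vstack([half, half])
        labels = ["patient"] * 5 + ["control"] * 5
        es = edge_statistics(Y, labels)
        assert np.allclose(es.F, 0.0, atol=1e-16)

    def test_planted_shift_attains_max_f(self, rng):
        Y = rng.normal(size=(20, 30))
        Y[:10, 7] += 8.0
        labels = ["patient"] * 10 + ["control"] * 10
        es = edge_statistics(Y, labels)
        assert np.argmax(es.F) == 7
        assert es.t[7] > 0  # patients higher

    def test_matches_rss_ratio_oracle(self, rng):
        # F from the reduced-vs-full residual-sum-of-squares ratio
        n = 8
        Y = rng.normal(size=(n, 4))
        g = np.array([1.0, 1, 1, 1, 0, 0, 0, 0])
        cov = rng.normal(size=(n, 2))
        labels = ["patient" if v else "control" for v in g]
        es = edge_statistics(Y, labels, cov)
        Z = np.column_stack([np.ones(n), cov])
        X = np.column_stack([Z, g])
        for e in range(4):
            y = Y[:, e]
            r_red = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
            r_full = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
            rss_red, rss_full = r_red @ r_red, r_full @ r_full
            F = (rss_red - rss_full) / (rss_full / (n - X.shape[1]))
            assert es.F[e] == pytest.approx(F, abs=1e-9)


class TestComponents:
    def test_chain_is_one_component_of_size_two(self):
        stats = _stats_from_edges([(1, 2), (2, 3)], n_nodes=5)
        comps = suprathreshold_components(stats, f_threshold=5.3)
        assert len(comps) == 1 and comps[0].size == 2

    def test_disjoint_edges_are_separate_components(self):
        stats = _stats_from_edges([(1, 2), (3, 4)], n_nodes=6)
        comps = suprathreshold_components(stats, f_threshold=5.3)
        assert sorted(c.size for c in comps) == [1, 1]

    def test_threshold_is_strict(self):
        stats = _stats_from_edges([(0, 1)], n_nodes=3, t_val=np.sqrt(5.3))
        assert suprathreshold_components(stats, f_threshold=5.3) == []

    def test_direction_filtering(self):
        stats = _stats_from_edges([(0, 1)], n_nodes=3, t_val=-4.0)
        assert suprathreshold_components(stats, direction="patients>controls") == []
        down = suprathreshold_components(stats, direction="patients<controls")
        assert len(down) == 1

    def test_matches_bfs_oracle_on_random_graphs(self, rng):
        for _ in range(1000):
            n_nodes = 10
            m = rng.integers(0, 12)
            pairs = edge_index_pairs(n_nodes)
            chosen = pairs[rng.choice(len(pairs), size=m, replace=False)]
            edge_list = [tuple(e) for e in chosen]
            stats = _stats_from_edges(edge_list, n_nodes)
            comps = suprathreshold_components(stats, f_threshold=5.3)
            ours = {frozenset(tuple(sorted(e)) for e in c.edges) for c in comps}
            oracle = set(_bfs_components(edge_list, n_nodes))
            assert ours == oracle


class TestNBSTest:
    @staticmethod
    def _planted_data(rng, n_nodes=12, shift=4.0):
        pairs = edge_index_pairs(n_nodes)
        E = len(pairs)
        Y = rng.normal(size=(20, E))
        lut = {tuple(e): k for k, e in enumerate(map(tuple, pairs))}
        block = [(0, 1), (1, 2), (0, 2), (2, 3), (3, 4)]  # dense 5-edge block
        for e in block:
            Y[:10, lut[e]] += shift
        labels = ["patient"] * 10 + ["control"] * 10
        return Y, labels, block, lut

    def test_strong_planted_block_is_significant(self, rng):
        Y, labels, block, lut = self._planted_data(rng)
        res = nbs_test(Y, labels, n_permutations=500, seed=9, n_nodes=12)
        sig = res.significant(0.05)
        assert sig, "planted block should reach significance"
        found = {tuple(sorted(e)) for c in sig for e in c.edges}
        assert set(block) <= found

    def test_boundary_p_is_one_over_b_plus_one(self, rng):
        Y, labels, _, _ = self._planted_data(rng, shift=12.0)
        res = nbs_test(Y, labels, n_permutations=200, seed=2, n_nodes=12)
        top = res.components[0]
        null = np.maximum(
            res.null_max_size["patients>controls"],
            res.null_max_size["patients<controls"],
        )
        if top.size > null.max():  # observed beats every permutation
            assert top.p_corrected == pytest.approx(1.0 / 201.0)

    def test_p_monotone_in_component_size(self, rng):
        Y = rng.normal(size=(20, 66))
        labels = ["patient"] * 10 + ["control"] * 10
        res = nbs_test(Y, labels, n_permutations=300, seed=4, n_nodes=12,
                       f_threshold=2.0)
        for d in ("patients>controls", "patients<controls"):
            comps = [c for c in res.components if c.direction == d]
            comps.sort(key=lambda c: c.size)
            ps = [c.p_corrected for c in comps]
            assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))

    def test_no_suprathreshold_edges_yields_empty_result(self, rng):
        half = rng.normal(size=(8, 28))
        Y = np.vstack([half, half])  # identical groups: all F = 0
        labels = ["patient"] * 8 + ["control"] * 8
        res = nbs_test(Y, labels, n_permutations=100, seed=1, n_nodes=8)
        assert res.components == []
        assert all(len(v) == 100 for v in res.null_max_size.values())

    def test_deterministic_given_seed(self, rng):
        Y = rng.normal(size=(16, 45))
        labels = ["patient"] * 8 + ["control"] * 8
        r1 = nbs_test(Y, labels, n_permutations=200, seed=7, n_nodes=10)
        r2 = nbs_test(Y, labels, n_permutations=200, seed=7, n_nodes=10)
        assert [c.p_corrected for c in r1.components] == [
            c.p_corrected for c in r2.components
        ]
        for d in r1.null_max_size:
            assert np.array_equal(r1.null_max_size[d], r2.null_max_size[d])

    def test_paper_strict_convention(self, rng):
        Y, labels, _, _ = self._planted_data(rng, shift=12.0)
        res = nbs_test(Y, labels, n_permutations=200, seed=2, n_nodes=12,
                       paper_strict=True)
        top = res.components[0]
        null = np.maximum(
            res.null_max_size["patients>controls"],
            res.null_max_size["patients<controls"],
        )
        assert top.p_corrected == pytest.approx((null > top.size).sum() / 200)
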