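"""Graph measures: strength, betweenness, modularity, roles, module graphs."""

import itertools

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from hinet.graph import (
    ConsensusError,
    _random_weight_preserving,
    between_module_graph,
    betweenness,
    consensus_partition,
    hemispheric_asymmetry,
    louvain,
    modularity_q,
    modularity_significance,
    module_sync,
    node_strength,
    sync_timecourse,
    z_p_roles,
)
from hinet.spectral import ConnectivityStack


def _edges_to_matrix(n, edges):
    w = np.zeros((n, n))
    for i, j, v in edges:
        w[i, j] = w[j, i] = v
    return w


def _planted_modular(rng, sizes, w_in=1.0, w_out=0.05, p_in=1.0, p_out=0.3):
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if labels[i] == labels[j]:
                if rng.random() < p_in:
                    w[i, j] = w[j, i] = w_in * rng.uniform(0.8, 1.2)
            elif rng.random() < p_out:
                w[i, j] = w[j, i] = w_out * rng.uniform(0.8, 1.2)
    return w, labels


class TestStrength:
    def test_triangle_and_star(self):
        tri = _edges_to_matrix(3, [(0, 1, 1), (1, 2, 1), (0, 2, 1)])
        assert np.allclose(node_strength(tri), 2.0)
        star = _edges_to_matrix(5, [(0, k, 1) for k in range(1, 5)])
        assert np.allclose(node_strength(star), [4, 1, 1, 1, 1])

    def test_handshake_property(self, rng):
        w = np.abs(rng.normal(size=(7, 7)))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        total = w[np.triu_indices(7, 1)].sum()
        assert node_strength(w).sum() == pytest.approx(2 * total)

    def test_negative_weights_rejected(self):
        w = _edges_to_matrix(3, [(0, 1, -1.0)])
        with pytest.raises(ValueError):
            node_strength(w)


class TestBetweenness:
    def test_path_and_star(self):
        path = _edges_to_matrix(3, [(0, 1, 1), (1, 2, 1)])
        assert np.allclose(betweenness(path), [0, 1, 0])
        star = _edges_to_matrix(5, [(0, k, 1) for k in range(1, 5)])
        assert np.allclose(betweenness(star), [6, 0, 0, 0, 0])  # C(4,2) leaf pairs

    def test_against_exhaustive_path_enumeration(self, rng):
        """Random 7-node weighted graphs vs brute-force shortest-path counts."""
        for _ in range(5):
            w = np.abs(rng.normal(1, 0.3, (7, 7)))
            w = (w + w.T) / 2
            np.fill_diagonal(w, 0)
            mask = rng.random((7, 7)) < 0.3
            mask |= mask.T
            w[mask] = 0.0
            got = betweenness(w)
            g = nx.Graph()
            g.add_nodes_from(range(7))
            for i in range(7):
                for j in range(i + 1, 7):
                    if w[i, j] > 0:
                        g.add_edge(i, j, length=1.0 / w[i, j])
            expected = np.zeros(7)
            for s in range(7):
                for t in range(s + 1, 7):
                    if not nx.has_path(g, s, t):
                        continue
                    paths = list(nx.all_simple_paths(g, s, t))
                    lens = [
                        sum(g[a][b]["length"] for a, b in zip(p, p[1:])) for p in paths
                    ]
                    best = min(lens)
                    shortest = [p for p, l in zip(paths, lens) if l <= best * (1 + 1e-12)]
                    for v in range(7):
                        if v in (s, t):
                            continue
                        through = sum(1 for p in shortest if v in p)
                        expected[v] += through / len(shortest)
            assert np.allclose(got, expected, atol=1e-8)


class TestLouvain:
    def test_two_cliques_recovered(self):
        w = np.zeros((8, 8))
        for grp in (range(4), range(4, 8)):
            for i, j in itertools.combinations(grp, 2):
                w[i, j] = w[j, i] = 1.0
        w[3, 4] = w[4, 3] = 0.05
        labels, q = louvain(w, seed=0)
        assert adjusted_rand_score(labels, [0] * 4 + [1] * 4) == 1.0
        assert q > 0.4

    def test_q_matches_nested_loop_oracle(self, rng):
        w = np.abs(rng.normal(size=(6, 6)))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        labels, q = louvain(w, seed=1)
        two_mu = w.sum()
        s = w.sum(axis=1)
        q_manual = 0.0
        for i in range(6):
            for j in range(6):
                if labels[i] == labels[j]:
                    q_manual += w[i, j] - s[i] * s[j] / two_mu
        q_manual /= two_mu
        assert q == pytest.approx(q_manual, rel=1e-12)

    def test_near_optimal_on_small_graph(self, rng):
        """Louvain Q within 5% of the exhaustive maximum on a 6-node graph."""
        w, _ = _planted_modular(rng, [3, 3], p_out=0.5)
        best = max(
            modularity_q(w, np.array(p))
            for p in itertools.product(range(3), repeat=6)
        )
        q_louvain = max(louvain(w, seed=s)[1] for s in range(5))
        assert q_louvain >= 0.95 * best

    def test_empty_graph_errors(self):
        with pytest.raises(ValueError):
            louvain(np.zeros((4, 4)))


class TestConsensus:
    def test_disconnected_cliques_converge_first_iteration(self):
        w = np.zeros((6, 6))
        for grp in (range(3), range(3, 6)):
            for i, j in itertools.combinations(grp, 2):
                w[i, j] = w[j, i] = 1.0
        res = consensus_partition(w, n_runs=50, seed=0)
        assert res.n_iterations == 1
        off = res.agreement[~np.eye(6, dtype=bool)]
        assert set(np.round(off, 12)) <= {0.0, 1.0}
        assert res.n_modules == 2

    def test_recovers_planted_partition(self, rng):
        w, labels = _planted_modular(rng, [8, 7, 9])
        res = consensus_partition(w, n_runs=100, seed=1)
        assert adjusted_rand_score(res.partition, labels) == 1.0
        assert res.q == pytest.approx(modularity_q(w, res.partition))

    def test_determinism(self, rng):
        w, _ = _planted_modular(rng, [6, 6])
        a = consensus_partition(w, n_runs=60, seed=99)
        b = consensus_partition(w, n_runs=60, seed=99)
        assert np.array_equal(a.partition, b.partition)
        assert a.q == b.q


class TestModularitySignificance:
    def test_null_preserves_weight_multiset(self, rng):
        w, _ = _planted_modular(rng, [5, 5])
        null = _random_weight_preserving(w, np.random.default_rng(0))
        iu = np.triu_indices(10, 1)
        assert sorted(null[iu][null[iu] > 0]) == pytest.approx(sorted(w[iu][w[iu] > 0]))
        assert np.allclose(null, null.T)

    def test_modular_graph_significant(self, rng):
        w, _ = _planted_modular(rng, [8, 8], p_out=0.4)
        _, null_q, p = modularity_significance(w, n_random=20, seed=2, n_runs=40)
        assert p < 0.05

    def test_null_family_calibrated(self, rng):
        """Graphs drawn from the null family get unremarkable p values."""
        ps = []
        for k in range(5):
            base, _ = _planted_modular(rng, [12], p_in=0.5)  # unstructured
            w = _random_weight_preserving(base, np.random.default_rng(k))
            _, _, p = modularity_significance(w, n_random=9, seed=k, n_runs=25)
            ps.append(p)
        assert 0.05 < np.median(ps) < 0.95


class TestZPRoles:
    def _fixture(self):
        # module 1 = star around node 0 (nodes 0-7); module 2 = {8, 9};
        # node 0 also reaches node 8 -> the designed connector hub.
        edges = [(0, k, 1.0) for k in range(1, 8)]
        edges += [(0, 8, 1.75), (8, 9, 1.75)]
        w = _edges_to_matrix(10, edges)
        partition = np.array([1] * 8 + [2, 2])
        return w, partition

    def test_designed_connector_flagged_exactly(self):
        w, part = self._fixture()
        m = z_p_roles(w, part)
        connectors = [i for i, r in enumerate(m.role) if r == "connector_hub"]
        assert connectors == [0]
        assert m.z[0] == pytest.approx(np.sqrt(7), rel=1e-9)  # > 2.5
        assert m.participation[0] == pytest.approx(0.32)

    def test_interior_and_splitter_participation(self):
        w, part = self._fixture()
        m = z_p_roles(w, part)
        assert np.allclose(m.participation[1:8], 0.0)  # interior nodes
        assert m.participation[9] == 0.0
        assert m.participation[8] == pytest.approx(0.5)  # even 2-module splitter

    def test_z_mean_zero_unit_sd_within_modules(self, rng):
        w, labels = _planted_modular(rng, [6, 8])
        m = z_p_roles(w, labels)
        for mod in np.unique(labels):
            z = m.z[labels == mod]
            assert abs(z.mean()) < 1e-10
            assert z.std() == pytest.approx(1.0, rel=1e-9)

    def test_singleton_module_warns(self):
        w = _edges_to_matrix(3, [(0, 1, 1.0), (1, 2, 1.0)])
        with pytest.warns(UserWarning, match="singleton"):
            m = z_p_roles(w, np.array([1, 1, 2]))
        assert m.z[2] == 0.0


class TestModuleGraphs:
    def test_within_between_conservation(self, rng):
        w, labels = _planted_modular(rng, [5, 6, 4])
        mg = between_module_graph(w, labels)
        total = w[np.triu_indices(15, 1)].sum()
        between_total = mg.between_sync[np.triu_indices(3, 1)].sum()
        assert mg.within_sync.sum() + between_total == pytest.approx(total)

    def test_two_modules_single_bridge(self):
        w = _edges_to_matrix(4, [(0, 1, 1.0), (2, 3, 1.0), (1, 2, 0.4)])
        mg = between_module_graph(w, np.array([1, 1, 2, 2]))
        assert mg.between_sync[0, 1] == pytest.approx(0.4)
        assert np.allclose(mg.module_strength, 0.4)
        assert np.allclose(mg.within_sync, 1.0)

    def test_central_module_has_max_strength_and_betweenness(self):
        # 5 modules of 2 nodes; module 0 bridges to every other module
        edges = [(0, 1, 1.0), (2, 3, 1.0), (4, 5, 1.0), (6, 7, 1.0), (8, 9, 1.0)]
        for k, target in enumerate([2, 4, 6, 8]):
            edges.append((0, target, 0.5 + 0.01 * k))
        w = _edges_to_matrix(10, edges)
        labels = np.repeat(np.arange(1, 6), 2)
        mg = between_module_graph(w, labels)
        assert np.argmax(mg.module_strength) == 0
        assert np.argmax(mg.module_betweenness) == 0

    def test_single_module_errors(self):
        w = _edges_to_matrix(3, [(0, 1, 1.0)])
        with pytest.raises(ValueError):
            between_module_graph(w, np.array([1, 1, 1]))

    def test_module_sync_single_module_total(self, rng):
        w, _ = _planted_modular(rng, [6])
        sync = module_sync(w, np.zeros(6, dtype=int))
        assert sync[0] == pytest.approx(w[np.triu_indices(6, 1)].sum())


class TestAsymmetryAndTimecourse:
    def test_identical_hemispheres_t_zero(self):
        v = np.array([0.1, 0.2, 0.3, 0.4])
        t, p = hemispheric_asymmetry(v, v)
        assert t == 0.0 and p == 1.0

    def test_lateralized_significant(self, rng):
        left = rng.normal(1.0, 0.1, 20)
        right = left - 0.5 + rng.normal(0, 0.05, 20)
        t, p = hemispheric_asymmetry(left, right)
        assert t > 3 and p < 0.01

    def test_symmetric_null(self, rng):
        left = rng.normal(1.0, 0.1, 30)
        right = rng.normal(1.0, 0.1, 30)
        t, p = hemispheric_asymmetry(left, right)
        assert abs(t) < 2.5

    def _stack(self, n=4):
        grid = -300.0 + 20.0 * np.arange(46)
        rngl = np.random.default_rng(0)
        w = np.abs(rngl.normal(0.1, 0.02, (n, n, 46)))
        w = (w + np.transpose(w, (1, 0, 2))) / 2
        return ConnectivityStack(w, grid, (4.0, 7.0), 20)

    def test_single_edge_equals_its_trace(self):
        st = self._stack()
        tc = sync_timecourse(st, [(0, 2)])
        assert np.array_equal(tc, st.wpli_d[0, 2, :])

    def test_baseline_subtraction_zero_mean_in_window(self):
        st = self._stack()
        tc = sync_timecourse(st, [(0, 1), (1, 2)], baseline_window=(-300.0, -100.0))
        sel = st.time_points <= -100.0
        assert tc[sel].mean() == pytest.approx(0.0, abs=1e-12)

    def test_empty_edge_set_errors(self):
        with pytest.raises(ValueError):
            sync_timecourse(self._stack(), [])
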