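import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import templex as tx
from templex.modularity import (
    directed_modularity,
    group_average,
    hierarchical_split,
    louvain_directed,
    module_connectivity,
    q_significance,
)


class TestGroupAverage:
    def test_identical_subjects(self, rng):
        w = rng.random((5, 5))
        np.testing.assert_array_equal(group_average([w, w]), w)

    def test_disjoint_links_halved(self):
        a = np.zeros((3, 3))
        b = np.zeros((3, 3))
        a[0, 1] = 2.0
        b[1, 2] = 4.0
        avg = group_average([a, b])
        assert avg[0, 1] == 1.0 and avg[1, 2] == 2.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            group_average([np.zeros((3, 3)), np.zeros((4, 4))])


class TestDirectedModularity:
    def test_matches_networkx_oracle(self, rng):
        w = rng.random((10, 10)) * (rng.random((10, 10)) < 0.4)
        np.fill_diagonal(w, 0.0)
        part = rng.integers(0, 3, 10)
        g = nx.from_numpy_array(w, create_using=nx.DiGraph)
        comms = [set(np.flatnonzero(part == m)) for m in range(3)]
        comms = [c for c in comms if c]
        expected = nx.community.modularity(g, comms, weight="weight")
        assert directed_modularity(w, part) == pytest.approx(expected)

    def test_one_module_partition_scores_zero(self, rng):
        w = rng.random((8, 8))
        np.fill_diagonal(w, 0.0)
        assert directed_modularity(w, np.zeros(8, dtype=int)) == pytest.approx(0.0)

    def test_label_permutation_invariance(self, rng):
        w = rng.random((9, 9))
        np.fill_diagonal(w, 0.0)
        part = rng.integers(0, 3, 9)
        relabeled = (part + 7) % 3  # same grouping, different ids
        assert directed_modularity(w, part) == pytest.approx(
            directed_modularity(w, relabeled)
        )


class TestLouvain:
    def test_disconnected_cliques_separate(self):
        w = np.zeros((10, 10))
        for block in (range(5), range(5, 10)):
            for i in block:
                for j in block:
                    if i != j:
                        w[i, j] = 1.0
        part, q = louvain_directed(w, n_restarts=5, seed=0)
        assert q > 0.4
        assert len(set(part[:5])) == 1 and len(set(part[5:])) == 1
        assert part[0] != part[5]

    def test_best_q_not_below_trivial_partition(self, rng):
        w = rng.random((12, 12)) * (rng.random((12, 12)) < 0.3)
        np.fill_diagonal(w, 0.0)
        _, q = louvain_directed(w, n_restarts=5, seed=1)
        assert q >= 0.0

    def test_complete_uniform_network_near_zero_q(self):
        w = np.ones((10, 10)) - np.eye(10)
        _, q = louvain_directed(w, n_restarts=5, seed=2)
        assert q == pytest.approx(0.0, abs=0.05)

    def test_planted_three_module_recovery(self):
        part = np.repeat([0, 1, 2], 12)
        net = tx.gen_multiplex(36, n_layers=1, density=0.18,
                               partition=part, module_ratio=10, seed=3)
        found, q = louvain_directed(net.layers[0], n_restarts=10, seed=4)
        assert adjusted_rand_score(part, found) > 0.9

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            louvain_directed(np.zeros((5, 5)))


class TestSignificanceAndHierarchy:
    def test_planted_modular_layer_is_significant(self):
        part = np.repeat([0, 1, 2], 12)
        net = tx.gen_multiplex(36, n_layers=1, density=0.18,
                               partition=part, module_ratio=10, seed=5)
        found, q = louvain_directed(net.layers[0], n_restarts=10, seed=6)
        sig, null_q = q_significance(net.layers[0], q, n_rand=30, seed=7,
                                     n_restarts=5)
        assert sig
        assert q > null_q.max()

    def test_two_level_hierarchy_recovered(self):
        # two super-modules, each of three 6-node sub-modules
        rng = np.random.default_rng(8)
        n = 36
        sub = np.repeat(np.arange(6), 6)
        sup = (sub // 3)
        p = np.full((n, n), 0.02)
        p[sup[:, None] == sup[None, :]] = 0.10
        p[sub[:, None] == sub[None, :]] = 0.85
        w = (rng.random((n, n)) < p) * rng.uniform(0.5, 1.5, (n, n))
        np.fill_diagonal(w, 0.0)
        res = hierarchical_split(w, n_rand=30, seed=9, n_restarts=10,
                                 null_restarts=5)
        assert res.significant
        top = np.empty(n, dtype=int)
        for node, path in res.module_paths().items():
            top[node] = int(path.split(".")[0])
        # top level should align with either the super- or sub-structure
        ari_sup = adjusted_rand_score(sup, top)
        ari_sub = adjusted_rand_score(sub, top)
        assert max(ari_sup, ari_sub) > 0.9
        # and the full nested paths must resolve the 6 sub-modules
        leaves = [res.module_paths()[i] for i in range(n)]
        assert adjusted_rand_score(sub, pd_factorize(leaves)) > 0.9

    def test_recursion_terminates_on_random_input(self, rng):
        w = rng.random((12, 12)) * (rng.random((12, 12)) < 0.4)
        np.fill_diagonal(w, 0.0)
        res = hierarchical_split(w, n_rand=20, seed=10, n_restarts=5,
                                 null_restarts=3)
        paths = res.module_paths()
        assert set(paths) == set(range(12))


def pd_factorize(labels):
    import pandas as pd

    return pd.factorize(np.asarray(labels))[0]


class TestModuleConnectivity:
    def test_block_matrix_within_between(self):
        part = np.array([0, 0, 1, 1])
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 2.0
        w[2, 3] = w[3, 2] = 2.0
        conn = module_connectivity(w, part)
        assert conn[(0, 0)] == pytest.approx(2.0)
        assert conn[(1, 1)] == pytest.approx(2.0)
        assert conn[(0, 1)] == 0.0 and conn[(1, 0)] == 0.0

    def test_uniform_matrix_equal_within_between(self):
        w = np.ones((6, 6)) - np.eye(6)
        part = np.array([0, 0, 0, 1, 1, 1])
        conn = module_connectivity(w, part)
        assert conn[(0, 0)] == conn[(0, 1)] == 1.0

    def test_singleton_module_within_undefined(self):
        w = np.ones((3, 3)) - np.eye(3)
        part = np.array([0, 0, 1])
        conn = module_connectivity(w, part)
        assert (1, 1) not in conn
        assert (0, 1) in conn
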