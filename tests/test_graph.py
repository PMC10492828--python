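"""Neighbour graph, MNN augmentation, clustering and diffusion."""

import networkx as nx
import numpy as np
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

from emtscape import graph as gm


class TestBuildGraph:
    def test_collinear_points(self):
        emb = np.array([[0.0], [1.0], [2.0]])
        g = gm.build_graph(emb, k=1)
        nxg = g.to_networkx()
        assert nxg.has_edge(0, 1) and nxg.has_edge(1, 2)

    def test_identical_neighbour_sets_have_jaccard_one(self):
        # two tight pairs far apart: within each pair, both nodes see the
        # same (self-inclusive) neighbour set
        emb = np.array([[0.0], [0.1], [100.0], [100.1]])
        g = gm.build_graph(emb, k=1)
        assert g.weights[0, 1] == pytest.approx(1.0)
        assert g.weights[2, 3] == pytest.approx(1.0)

    def test_k_too_large_errors(self):
        with pytest.raises(ValueError):
            gm.build_graph(np.zeros((5, 2)), k=5)

    def test_mnn_pairs_match_brute_force(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(40, 3))
        b = rng.normal(size=(35, 3)) + 0.5
        k = 5
        pairs = set(gm.mutual_nearest_pairs(a, b, k))
        # exhaustive check over all cross distances
        d = np.linalg.norm(a[:, None] - b[None, :], axis=2)
        ab = {i: set(np.argsort(d[i])[:k]) for i in range(len(a))}
        ba = {j: set(np.argsort(d[:, j])[:k]) for j in range(len(b))}
        expected = {
            (i, j) for i in range(len(a)) for j in range(len(b))
            if j in ab[i] and i in ba[j]
        }
        assert pairs == expected

    def test_augmented_edges_cross_consecutive_timepoints_only(self):
        rng = np.random.default_rng(0)
        emb = np.vstack([
            rng.normal(size=(30, 2)),
            rng.normal(size=(30, 2)) + 5,
            rng.normal(size=(30, 2)) + 10,
        ])
        tps = np.repeat(["t0", "t1", "t2"], 30)
        g = gm.build_graph(emb, k=5, timepoints=tps, timepoint_order=["t0", "t1", "t2"], k_mnn=3)
        for i, j in g.augmented_pairs:
            pair = {tps[i], tps[j]}
            assert pair in ({"t0", "t1"}, {"t1", "t2"})

    def test_graph_invariant_to_cell_order(self):
        rng = np.random.default_rng(5)
        emb = rng.normal(size=(80, 4))
        perm = rng.permutation(80)
        g1 = gm.build_graph(emb, k=6)
        g2 = gm.build_graph(emb[perm], k=6)
        w1 = g1.weights.toarray()
        w2 = g2.weights.toarray()
        assert np.allclose(w1[np.ix_(perm, perm)], w2)


class TestClusterGraph:
    def _clique(self, n, offset=0):
        g = nx.complete_graph(n)
        return nx.relabel_nodes(g, {i: i + offset for i in range(n)})

    def test_two_disconnected_cliques(self):
        g = nx.compose(self._clique(10), self._clique(10, offset=10))
        nx.set_edge_attributes(g, 1.0, "weight")
        labels = gm.cluster_graph(g, seed=0)
        assert len(set(labels[:10])) == 1
        assert len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_single_clique_one_cluster(self):
        g = self._clique(12)
        nx.set_edge_attributes(g, 1.0, "weight")
        assert len(set(gm.cluster_graph(g, seed=0))) == 1

    def test_empty_graph_errors(self):
        with pytest.raises(ValueError):
            gm.cluster_graph(nx.Graph())

    def test_deterministic_given_seed(self):
        g = nx.stochastic_block_model([50, 50], [[0.3, 0.02], [0.02, 0.3]], seed=4)
        nx.set_edge_attributes(g, 1.0, "weight")
        assert np.array_equal(gm.cluster_graph(g, seed=2), gm.cluster_graph(g, seed=2))

    def test_ari_degrades_as_blocks_merge(self):
        """Raising between-block density toward the within-block level
        lowers recovery on average."""
        sizes = [60, 60, 60]
        scores = []
        for p_out in (0.02, 0.18, 0.30):
            aris = []
            for rep in range(3):
                g = nx.stochastic_block_model(
                    sizes, [[0.3 if i == j else p_out for j in range(3)] for i in range(3)],
                    seed=10 * rep + int(p_out * 100),
                )
                nx.set_edge_attributes(g, 1.0, "weight")
                labels = gm.cluster_graph(g, seed=0)
                aris.append(adjusted_rand_score(np.repeat([0, 1, 2], 60), labels))
            scores.append(np.mean(aris))
        assert scores[0] >= scores[1] >= scores[2]
        assert scores[0] > scores[2]


class TestDiffusion:
    def _graph(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        emb = rng.normal(size=(n, 3))
        return gm.build_graph(emb, k=6)

    def test_transition_matrix_row_stochastic(self):
        space = gm.diffusion_components(self._graph(), d=5)
        rows = np.asarray(space.transition_matrix.sum(axis=1)).ravel()
        assert np.allclose(rows, 1.0, atol=1e-10)

    def test_leading_eigenpair_trivial(self):
        space = gm.diffusion_components(self._graph(), d=5)
        assert space.eigenvalues[0] == pytest.approx(1.0, abs=1e-8)
        assert np.all(np.diff(space.eigenvalues) <= 1e-12)

    def test_disconnected_graph_doubles_unit_eigenvalue(self):
        emb = np.vstack([
            np.random.default_rng(1).normal(size=(20, 2)),
            np.random.default_rng(2).normal(size=(20, 2)) + 1000,
        ])
        g = gm.build_graph(emb, k=4)
        space = gm.diffusion_components(g, d=5)
        assert space.eigenvalues[1] == pytest.approx(1.0, abs=1e-8)

    def test_matches_dense_eigensolver(self):
        """Eigenvalues agree with a dense eigendecomposition of the same
        operator on a 50-node graph."""
        g = self._graph(n=50)
        space = gm.diffusion_components(g, d=6)
        p_dense = np.asarray(space.transition_matrix.todense())
        vals = np.sort(np.linalg.eigvals(p_dense).real)[::-1]
        assert np.allclose(space.eigenvalues, vals[:7], atol=1e-6)

    def test_diffuse_t0_is_identity(self):
        g = self._graph()
        space = gm.diffusion_components(g, d=4)
        x = np.random.default_rng(0).normal(size=(50, 3))
        assert np.array_equal(gm.diffuse_expression(x, space, t=0), x)

    def test_two_node_average(self):
        space = gm.DiffusionSpace(
            eigenvalues=np.array([1.0, 0.0]),
            components=np.zeros((2, 1)),
            transition_matrix=sp.csr_matrix(np.full((2, 2), 0.5)),
            stationary=np.array([0.5, 0.5]),
        )
        x = np.array([[0.0], [2.0]])
        assert np.allclose(gm.diffuse_expression(x, space, t=1), [[1.0], [1.0]])

    def test_long_diffusion_collapses_range(self):
        """After many steps on a connected 30-node graph each gene is
        nearly constant."""
        rng = np.random.default_rng(4)
        emb = rng.normal(size=(30, 2))
        g = gm.build_graph(emb, k=15)  # dense graph: wide spectral gap
        space = gm.diffusion_components(g, d=4)
        x = rng.normal(size=(30, 3))
        out = gm.diffuse_expression(x, space, t=200)
        initial = x.max(axis=0) - x.min(axis=0)
        final = out.max(axis=0) - out.min(axis=0)
        assert np.all(final < 0.01 * initial)

    def test_stationary_mean_conserved(self):
        g = self._graph()
        space = gm.diffusion_components(g, d=4)
        x = np.random.default_rng(7).normal(size=(50, 4))
        pi = space.stationary
        for t in (1, 5, 20):
            out = gm.diffuse_expression(x, space, t=t)
            assert np.allclose(pi @ out, pi @ x, atol=1e-10)
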