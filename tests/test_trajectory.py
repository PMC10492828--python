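"""Trajectory inference: pseudotime, absorption, entropy, trends."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from emtscape import trajectory as traj
from emtscape.graph import NeighbourGraph


def graph_from_edges(n, edges):
    """Unit-weight NeighbourGraph from an explicit edge list."""
    w = np.zeros((n, n))
    for i, j in edges:
        w[i, j] = w[j, i] = 1.0
    dist = w.copy()
    k = max(int(w.sum(axis=1).max()), 1)
    # fabricate kNN arrays consistent with the adjacency
    knn_ind = np.zeros((n, k), dtype=int)
    knn_dist = np.ones((n, k))
    for i in range(n):
        nbrs = np.flatnonzero(w[i])
        knn_ind[i, : len(nbrs)] = nbrs
        knn_ind[i, len(nbrs):] = nbrs[0] if len(nbrs) else i
    return NeighbourGraph(
        n_nodes=n,
        k=k,
        knn_indices=knn_ind,
        knn_distances=knn_dist,
        weights=sp.csr_matrix(w),
        distances=sp.csr_matrix(dist),
    )


def y_graph(trunk=20, branch=20):
    """Path trunk 0..trunk-1 branching into two arms at the last trunk node."""
    edges = [(i, i + 1) for i in range(trunk - 1)]
    a0 = trunk
    b0 = trunk + branch
    edges.append((trunk - 1, a0))
    edges.append((trunk - 1, b0))
    edges += [(a0 + i, a0 + i + 1) for i in range(branch - 1)]
    edges += [(b0 + i, b0 + i + 1) for i in range(branch - 1)]
    n = trunk + 2 * branch
    hops = np.empty(n)
    hops[:trunk] = np.arange(trunk)
    hops[a0 : a0 + branch] = trunk + np.arange(branch)
    hops[b0 : b0 + branch] = trunk + np.arange(branch)
    return graph_from_edges(n, edges), hops, a0 + branch - 1, b0 + branch - 1


class TestStartCell:
    def _adata(self, marker_col):
        values = np.zeros((4, 2))
        values[:, 0] = marker_col
        a = ad.AnnData(
            X=values,
            obs=pd.DataFrame(index=["c3", "c1", "c0", "c2"]),
            var=pd.DataFrame(index=["marker", "other"]),
        )
        a.layers["lognorm"] = values
        return a

    def test_unique_maximum(self):
        assert traj.select_start_cell(self._adata([1, 4, 2, 0]), "marker") == 1

    def test_tie_breaks_by_lowest_identifier(self):
        # cells c1 (row 1) and c0 (row 2) tie; c0 sorts first
        assert traj.select_start_cell(self._adata([0, 4, 4, 0]), "marker") == 2

    def test_all_zero_marker_errors(self):
        with pytest.raises(ValueError, match="zero"):
            traj.select_start_cell(self._adata([0, 0, 0, 0]), "marker")

    def test_absent_marker_errors(self):
        with pytest.raises(ValueError, match="absent"):
            traj.select_start_cell(self._adata([1, 0, 0, 0]), "ghost")

    def test_planted_start_is_early(self, bifurcation_run):
        s = bifurcation_run["adata"].obs["s"].to_numpy()
        assert s[bifurcation_run["start"]] < 0.2


class TestPseudotime:
    def test_start_cell_zero_and_hop_count(self):
        g, _, _, _ = y_graph(trunk=5, branch=3)
        emb = np.zeros((g.n_nodes, 1))  # rely on unit distances? use 1D line
        # place nodes so that every edge has length 1
        pt = traj.compute_pseudotime(g, _unit_embedding(g), 0)
        assert pt[0] == 0.0
        assert pt[4] == pytest.approx(4.0)

    def test_matches_dense_shortest_path_oracle(self):
        rng = np.random.default_rng(2)
        emb = rng.normal(size=(40, 3))
        from emtscape.graph import build_graph

        g = build_graph(emb, k=5)
        pt = traj.compute_pseudotime(g, emb, 7)
        # dense Floyd-Warshall on the same weighted adjacency
        d = np.full((40, 40), np.inf)
        np.fill_diagonal(d, 0.0)
        coo = g.distances.tocoo()
        for i, j in zip(coo.row, coo.col):
            w = np.linalg.norm(emb[i] - emb[j])
            d[i, j] = d[j, i] = w
        for m in range(40):
            d = np.minimum(d, d[:, [m]] + d[[m], :])
        assert np.allclose(pt, d[7], atol=1e-10)

    def test_invariant_under_rotation(self):
        rng = np.random.default_rng(8)
        emb = rng.normal(size=(60, 4))
        from emtscape.graph import build_graph
        from scipy.stats import ortho_group

        g = build_graph(emb, k=6)
        rot = ortho_group.rvs(4, random_state=1)
        assert np.allclose(
            traj.compute_pseudotime(g, emb, 0),
            traj.compute_pseudotime(g, emb @ rot, 0),
        )

    def test_bad_start_errors(self):
        g, _, _, _ = y_graph(trunk=4, branch=2)
        with pytest.raises(ValueError):
            traj.compute_pseudotime(g, _unit_embedding(g), 99)


def _unit_embedding(g):
    """1-D embedding giving every graph edge length 1 via BFS depth."""
    import networkx as nx

    nxg = g.to_networkx()
    depth = nx.single_source_shortest_path_length(nxg, 0)
    emb = np.zeros((g.n_nodes, 2))
    for node, d in depth.items():
        emb[node, 0] = d
    # spread branches in the second axis so arm nodes at equal depth
    # do not coincide
    emb[:, 1] = np.arange(g.n_nodes) * 1e-9
    return emb


class TestBranchProbabilities:
    def test_committed_cell_is_one_hot(self):
        g, hops, term_a, term_b = y_graph()
        probs = traj.branch_probabilities(g, hops, [term_a, term_b])
        a0 = 20  # first node of arm A
        assert probs[a0] == pytest.approx([1.0, 0.0], abs=1e-12)

    def test_symmetric_start_is_half_half(self):
        g, hops, term_a, term_b = y_graph()
        probs = traj.branch_probabilities(g, hops, [term_a, term_b])
        assert probs[0] == pytest.approx([0.5, 0.5], abs=1e-10)

    def test_rows_sum_to_one(self, bifurcation_run):
        probs = bifurcation_run["result"].branch_probs
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-8)
        for j, t in enumerate(bifurcation_run["result"].termini):
            assert probs[t, j] == pytest.approx(1.0)

    def test_no_terminus_errors(self):
        g, hops, _, _ = y_graph(trunk=4, branch=2)
        with pytest.raises(ValueError):
            traj.branch_probabilities(g, hops, [])


class TestDifferentiationPotential:
    def test_known_entropies(self):
        dp = traj.differentiation_potential(np.array([[1.0, 0.0], [0.5, 0.5]]))
        assert dp[0] == 0.0
        assert dp[1] == pytest.approx(np.log(2), abs=1e-12)

    def test_bounded_by_log_n_termini(self, bifurcation_run):
        dp = bifurcation_run["result"].diff_potential
        k = bifurcation_run["result"].branch_probs.shape[1]
        assert np.all(dp >= -1e-12)
        assert np.all(dp <= np.log(k) + 1e-12)

    def test_elevated_inside_hybrid_window(self, bifurcation_run):
        """Mean differentiation potential peaks in the planted hybrid
        window relative to both the early trunk and the branches."""
        s = bifurcation_run["adata"].obs["s"].to_numpy()
        dp = bifurcation_run["result"].diff_potential
        lo, hi = bifurcation_run["config"].emp_window
        in_win = (s >= lo) & (s <= hi)
        early = s < 0.3
        late = s > 0.7
        assert dp[in_win].mean() > dp[early].mean()
        assert dp[in_win].mean() > dp[late].mean()


class TestGeneTrends:
    def test_constant_gene_flat(self):
        rng = np.random.default_rng(0)
        pt = rng.uniform(size=200)
        vals = np.full((200, 1), 3.3)
        _, trend, _ = traj.gene_trends(vals, pt, np.ones(200), bandwidth=0.2)
        assert np.allclose(trend.to_numpy(), 3.3, atol=1e-9)

    def test_zero_weight_cells_have_no_influence(self):
        rng = np.random.default_rng(1)
        pt = np.concatenate([rng.uniform(size=100), rng.uniform(size=100)])
        base = np.concatenate([pt[:100] * 2.0, np.full(100, 50.0)])
        w = np.concatenate([np.ones(100), np.zeros(100)])
        _, with_junk, _ = traj.gene_trends(base[:, None], pt, w, bandwidth=0.2)
        _, clean, _ = traj.gene_trends(
            base[:100, None], pt[:100], np.ones(100), bandwidth=0.2
        )
        assert np.allclose(with_junk.to_numpy(), clean.to_numpy(), atol=1e-9)

    def test_recovers_planted_linear_program(self):
        rng = np.random.default_rng(5)
        pt = rng.uniform(size=2000)
        y = 2.0 * pt + rng.normal(0, 0.1, size=2000)
        _, trend, _ = traj.gene_trends(y[:, None], pt, np.ones(2000), bandwidth=0.1)
        grid = trend.columns.to_numpy(float)
        err = np.abs(trend.to_numpy().ravel() - 2.0 * grid)
        assert err.max() < 0.1 * (y.max() - y.min())

    def test_all_zero_weights_error(self):
        with pytest.raises(ValueError):
            traj.gene_trends(np.ones((5, 1)), np.arange(5.0), np.zeros(5))


class TestRobustness:
    def test_identical_k_correlates_perfectly(self, bifurcation_run):
        out = traj.robustness_check(
            bifurcation_run["embedding"],
            bifurcation_run["start"],
            [30, 30],
            termini=bifurcation_run["result"].termini,
            timepoints=bifurcation_run["adata"].obs["timepoint"].to_numpy(),
        )
        assert out["pseudotime"].iloc[0, 1] == pytest.approx(1.0)

    def test_permuted_pseudotime_uncorrelated(self, bifurcation_run):
        pt = bifurcation_run["result"].pseudotime
        shuffled = np.random.default_rng(0).permutation(pt)
        assert abs(np.corrcoef(pt, shuffled)[0, 1]) < 0.1

    def test_needs_two_k_values(self, bifurcation_run):
        with pytest.raises(ValueError):
            traj.robustness_check(bifurcation_run["embedding"], 0, [30])
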