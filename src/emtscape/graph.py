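"""kNN graph construction, cross-timepoint MNN augmentation, Jaccard
edge weights, Louvain community clustering, diffusion components and
diffusion smoothing.

The graph is built in a PCA (or diffusion) embedding with Euclidean
distances.  When timepoint labels are given, mutual nearest neighbours
between *consecutive* timepoints are added as extra edges — a
lightweight stand-in for full augmented-affinity batch integration that
keeps the stated mechanism (cross-timepoint MNN pairs) and nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "NeighbourGraph",
    "DiffusionSpace",
    "build_graph",
    "mutual_nearest_pairs",
    "cluster_graph",
    "diffusion_components",
    "diffuse_expression",
]


@dataclass
class NeighbourGraph:
    """Symmetric kNN graph with Jaccard-refined weights.

    ``knn_indices``/``knn_distances`` hold each node's k nearest
    neighbours (excluding self).  ``weights`` is the symmetric sparse
    Jaccard-weight matrix; ``distances`` the symmetric sparse Euclidean
    distance matrix over the same edge set (including MNN-augmented
    edges).
    """

    n_nodes: int
    k: int
    knn_indices: np.ndarray
    knn_distances: np.ndarray
    weights: sp.csr_matrix
    distances: sp.csr_matrix
    augmented_pairs: list = field(default_factory=list)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        coo = sp.triu(self.weights, k=1).tocoo()
        g.add_weighted_edges_from(zip(coo.row.tolist(), coo.col.tolist(), coo.data.tolist()))
        return g

    def edge_list(self):
        """(i, j, jaccard_weight, distance) tuples, i < j."""
        coo = sp.triu(self.weights, k=1).tocoo()
        dist = self.distances
        return [
            (int(i), int(j), float(w), float(dist[i, j]))
            for i, j, w in zip(coo.row, coo.col, coo.data)
        ]


def mutual_nearest_pairs(
    a: np.ndarray, b: np.ndarray, k: int
) -> list[tuple[int, int]]:
    """Mutual nearest neighbours between two point sets.

    Returns (i, j) index pairs (into ``a`` and ``b``) where j is among
    the ``k`` nearest of i in ``b`` and i is among the ``k`` nearest of
    j in ``a``.
    """
    k_ab = min(k, len(b))
    k_ba = min(k, len(a))
    nn_b = NearestNeighbors(n_neighbors=k_ab).fit(b)
    _, ab = nn_b.kneighbors(a)
    nn_a = NearestNeighbors(n_neighbors=k_ba).fit(a)
    _, ba = nn_a.kneighbors(b)
    ba_sets = [set(row) for row in ba]
    pairs = []
    for i, row in enumerate(ab):
        for j in row:
            if i in ba_sets[j]:
                pairs.append((i, int(j)))
    return pairs


def build_graph(
    embedding: np.ndarray,
    k: int,
    timepoints=None,
    timepoint_order: list | None = None,
    k_mnn: int = 20,
) -> NeighbourGraph:
    """Build the symmetric Jaccard-weighted kNN graph.

    Edge weight is the Jaccard index of the two endpoints' (self-
    inclusive) kNN sets.  With ``timepoints`` given, MNN edges between
    consecutive timepoints are added before the Jaccard refinement.
    """
    embedding = np.asarray(embedding, float)
    n = embedding.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    dist, ind = nn.kneighbors(embedding)
    knn_ind, knn_dist = ind[:, 1:], dist[:, 1:]

    rows = np.repeat(np.arange(n), k)
    cols = knn_ind.ravel()
    data = knn_dist.ravel()

    augmented: list[tuple[int, int]] = []
    if timepoints is not None:
        timepoints = np.asarray(timepoints)
        if timepoint_order is None:
            timepoint_order = list(pd_unique_sorted(timepoints))
        extra_r, extra_c, extra_d = [], [], []
        for t0, t1 in zip(timepoint_order[:-1], timepoint_order[1:]):
            ia = np.flatnonzero(timepoints == t0)
            ib = np.flatnonzero(timepoints == t1)
            if ia.size == 0 or ib.size == 0:
                continue
            for i, j in mutual_nearest_pairs(embedding[ia], embedding[ib], k_mnn):
                gi, gj = int(ia[i]), int(ib[j])
                augmented.append((gi, gj))
                extra_r.append(gi)
                extra_c.append(gj)
                extra_d.append(float(np.linalg.norm(embedding[gi] - embedding[gj])))
        rows = np.concatenate([rows, extra_r]).astype(int) if extra_r else rows
        cols = np.concatenate([cols, extra_c]).astype(int) if extra_c else cols
        data = np.concatenate([data, extra_d]) if extra_d else data

    dist_mat = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    dist_mat = dist_mat.maximum(dist_mat.T)  # symmetric union of edges

    # neighbour sets for Jaccard: self + adjacency of the (augmented) graph
    adj = (dist_mat > 0).astype(np.float64) + sp.identity(n, format="csr")
    inter = (adj @ adj.T).tocsr()
    sizes = np.asarray(adj.sum(axis=1)).ravel()
    coo = dist_mat.tocoo()
    inter_vals = np.asarray(inter[coo.row, coo.col]).ravel()
    union = sizes[coo.row] + sizes[coo.col] - inter_vals
    jw = inter_vals / union
    weights = sp.csr_matrix((jw, (coo.row, coo.col)), shape=(n, n))
    weights = weights.maximum(weights.T)
    weights.setdiag(0)
    weights.eliminate_zeros()
    return NeighbourGraph(
        n_nodes=n,
        k=k,
        knn_indices=knn_ind,
        knn_distances=knn_dist,
        weights=weights,
        distances=dist_mat,
        augmented_pairs=augmented,
    )


def pd_unique_sorted(values: np.ndarray):
    """Unique values in order of first appearance after lexical sort."""
    return sorted(set(values.tolist()))


def cluster_graph(graph, resolution: float = 1.0, seed: int = 0) -> np.ndarray:
    """Louvain community labels on the weighted graph.

    Accepts a :class:`NeighbourGraph` or any ``networkx.Graph``.
    Deterministic given ``seed``; community ids are relabelled by the
    lowest node index they contain so label numbering is stable.
    """
    g = graph.to_networkx() if isinstance(graph, NeighbourGraph) else graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comms = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=seed
    )
    comms = sorted(comms, key=min)
    labels = np.empty(g.number_of_nodes(), dtype=int)
    node_index = {node: i for i, node in enumerate(sorted(g.nodes()))}
    for label, comm in enumerate(comms):
        for node in comm:
            labels[node_index[node]] = label
    return labels


@dataclass
class DiffusionSpace:
    """Diffusion decomposition of the cell-cell transition matrix.

    ``eigenvalues`` descend from the trivial eigenvalue 1;
    ``components`` holds the corresponding nontrivial right
    eigenvectors, each scaled by eigenvalue / (1 - eigenvalue).
    """

    eigenvalues: np.ndarray
    components: np.ndarray
    transition_matrix: sp.csr_matrix
    stationary: np.ndarray


def _adaptive_kernel(graph: NeighbourGraph) -> sp.csr_matrix:
    """Adaptive Gaussian kernel: sigma_i = distance to the ceil(k/3)-th
    nearest neighbour; w_ij = exp(-d_ij^2 / (sigma_i * sigma_j))."""
    idx = max(int(np.ceil(graph.k / 3)) - 1, 0)
    sigma = graph.knn_distances[:, idx].copy()
    sigma[sigma <= 0] = max(sigma[sigma > 0].min() if np.any(sigma > 0) else 1.0, 1e-12)
    coo = graph.distances.tocoo()
    w = np.exp(-(coo.data**2) / (sigma[coo.row] * sigma[coo.col]))
    kernel = sp.csr_matrix((w, (coo.row, coo.col)), shape=graph.distances.shape)
    return ((kernel + kernel.T) / 2.0).tocsr()


def diffusion_components(graph: NeighbourGraph, d: int = 10) -> DiffusionSpace:
    """Top nontrivial eigenpairs of the row-stochastic diffusion operator.

    The kernel matrix W is symmetrized and row-normalized to P = D^-1 W;
    eigenpairs are computed through the symmetric conjugate
    S = D^-1/2 W D^-1/2 so the decomposition is numerically stable.
    """
    n = graph.n_nodes
    if d >= n:
        raise ValueError("d must be smaller than the number of cells")
    w = _adaptive_kernel(graph)
    w = w + sp.identity(n, format="csr")  # self-affinity keeps P aperiodic
    deg = np.asarray(w.sum(axis=1)).ravel()
    inv_sqrt = 1.0 / np.sqrt(deg)
    s_mat = sp.diags(inv_sqrt) @ w @ sp.diags(inv_sqrt)
    k_eigs = d + 1
    if n <= max(3 * k_eigs, 300):
        vals, vecs = np.linalg.eigh(np.asarray(s_mat.todense()))
        vals, vecs = vals[::-1], vecs[:, ::-1]
        vals, vecs = vals[:k_eigs], vecs[:, :k_eigs]
    else:
        v0 = np.full(n, 1.0 / np.sqrt(n))
        vals, vecs = sp.linalg.eigsh(s_mat, k=k_eigs, which="LA", v0=v0)
        order = np.argsort(-vals)
        vals, vecs = vals[order], vecs[:, order]
    # right eigenvectors of P = D^-1/2 * eigenvectors of S
    psi = vecs * inv_sqrt[:, None]
    # deterministic sign: largest-magnitude entry positive
    for j in range(psi.shape[1]):
        i_max = np.argmax(np.abs(psi[:, j]))
        if psi[i_max, j] < 0:
            psi[:, j] *= -1
    # normalize the trivial eigenvector to the constant 1
    psi[:, 0] = psi[:, 0] / psi[0, 0]
    scale = vals[1:] / (1.0 - vals[1:])
    comps = psi[:, 1:] / np.linalg.norm(psi[:, 1:], axis=0)
    comps = comps * scale[None, :]
    p_mat = (sp.diags(1.0 / deg) @ w).tocsr()
    return DiffusionSpace(
        eigenvalues=vals,
        components=comps,
        transition_matrix=p_mat,
        stationary=deg / deg.sum(),
    )


def diffuse_expression(
    values: np.ndarray, space: DiffusionSpace, t: int = 1
) -> np.ndarray:
    """Diffusion smoothing P^t X (visualization-grade imputation).

    ``t = 0`` returns the input unchanged.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    values = np.asarray(values, float)
    if values.shape[0] != space.transition_matrix.shape[0]:
        raise ValueError("cell dimension mismatch")
    out = values.copy()
    for _ in range(t):
        out = space.transition_matrix @ out
    return out
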