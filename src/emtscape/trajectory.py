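"""Trajectory inference on the diffusion manifold.

Pseudotime is the shortest-path distance from a start cell over the kNN
graph with edge lengths measured in diffusion-component space (exact
per-cell paths replace waypoint subsampling, which is a scalability
device rather than part of the model).  Branch probabilities come from
an absorbing Markov chain on the pseudotime-directed graph: edges are
kept only toward neighbours of equal or greater pseudotime, the terminal
cells are absorbing, and each cell's row of absorption probabilities is
obtained from the exact linear system.  Differentiation potential is the
Shannon entropy (natural log) of that row — maximal for multipotent
cells, zero at termini.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph

from .graph import NeighbourGraph, build_graph, cluster_graph, diffusion_components

__all__ = [
    "TrajectoryResult",
    "select_start_cell",
    "compute_pseudotime",
    "find_termini",
    "branch_probabilities",
    "differentiation_potential",
    "gene_trends",
    "run_trajectory",
    "robustness_check",
]


@dataclass
class TrajectoryResult:
    """Per-cell pseudotime, branch probabilities and differentiation potential."""

    start_cell: int
    termini: list
    pseudotime: np.ndarray
    branch_probs: np.ndarray
    diff_potential: np.ndarray
    k_used: int


def select_start_cell(adata, marker_gene: str, layer: str = "lognorm") -> int:
    """Index of the cell maximizing the marker's expression (ties → lowest
    cell identifier in lexical order); an all-zero marker is an error."""
    if marker_gene not in adata.var_names:
        raise ValueError(f"marker gene {marker_gene!r} absent from the matrix")
    col = int(pd.Index(adata.var_names).get_loc(marker_gene))
    values = np.asarray(adata.layers[layer], float)[:, col]
    if np.all(values == 0):
        raise ValueError(f"marker gene {marker_gene!r} is zero in every cell")
    best = values.max()
    candidates = np.flatnonzero(values == best)
    names = np.asarray(adata.obs_names)[candidates]
    return int(candidates[np.argsort(names, kind="stable")[0]])


def _edge_lengths(graph: NeighbourGraph, embedding: np.ndarray) -> sp.csr_matrix:
    coo = graph.distances.tocoo()
    lengths = np.linalg.norm(embedding[coo.row] - embedding[coo.col], axis=1)
    mat = sp.csr_matrix((lengths, (coo.row, coo.col)), shape=graph.distances.shape)
    return mat.maximum(mat.T)


def compute_pseudotime(
    graph: NeighbourGraph, embedding: np.ndarray, start: int
) -> np.ndarray:
    """Shortest-path distance from ``start`` with Euclidean edge lengths in
    the given (diffusion-component) embedding; unreachable cells are inf."""
    n = graph.n_nodes
    if not (0 <= start < n):
        raise ValueError(f"start cell {start} not in graph of {n} nodes")
    lengths = _edge_lengths(graph, np.asarray(embedding, float))
    pt = csgraph.dijkstra(lengths, directed=False, indices=start)
    if np.any(np.isinf(pt)):
        warnings.warn(
            f"{int(np.isinf(pt).sum())} cells unreachable from the start cell",
            stacklevel=2,
        )
    return pt


def find_termini(
    graph: NeighbourGraph, pseudotime: np.ndarray, labels: np.ndarray
) -> list[int]:
    """Auto-detect terminal cells: each cluster's pseudotime-argmax cell,
    retained when it is a pseudotime local maximum over its two-hop graph
    neighbourhood (the wider neighbourhood suppresses spurious interior
    maxima caused by pseudotime noise)."""
    pseudotime = np.asarray(pseudotime, float)
    adj = graph.weights.tocsr()
    adj2 = ((adj + adj @ adj) > 0).tocsr()
    termini = []
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        finite = members[np.isfinite(pseudotime[members])]
        if finite.size == 0:
            continue
        cand = int(finite[np.argmax(pseudotime[finite])])
        nbrs = adj2.indices[adj2.indptr[cand] : adj2.indptr[cand + 1]]
        nbrs = nbrs[nbrs != cand]
        if nbrs.size == 0 or pseudotime[cand] >= pseudotime[nbrs].max():
            termini.append(cand)
    return sorted(set(termini))


def branch_probabilities(
    graph: NeighbourGraph,
    pseudotime: np.ndarray,
    termini: list[int],
    backward_scale: float = 0.0,
) -> np.ndarray:
    """Absorption probabilities at each terminus.

    The chain keeps edges toward neighbours with pseudotime >= own (ties
    in both directions), with transition probabilities proportional to
    the graph's Jaccard edge weights; termini are absorbing.  With
    ``backward_scale`` > 0, edges to neighbours up to
    ``backward_scale * sigma_i`` earlier in pseudotime are also kept,
    where sigma_i is the standard deviation of cell i's neighbour
    pseudotime offsets — on noisy data this lets the walk mix laterally
    instead of being funnelled down whichever corridor happens to sit
    marginally ahead in pseudotime.  A non-terminal cell with no forward
    edge is attached to the cell with the smallest pseudotime gap above
    it (with a warning).  Rows sum to 1; terminus rows are one-hot.
    """
    pseudotime = np.asarray(pseudotime, float)
    n = graph.n_nodes
    termini = [int(t) for t in termini]
    if not termini:
        raise ValueError("at least one terminus is required")
    term_set = set(termini)
    coo = graph.weights.tocoo()
    if backward_scale > 0:
        diffs = pseudotime[coo.col] - pseudotime[coo.row]
        sq = np.bincount(coo.row, weights=diffs**2, minlength=n)
        cnt = np.bincount(coo.row, minlength=n)
        sigma = np.sqrt(sq / np.maximum(cnt, 1))
        forward = diffs >= -backward_scale * sigma[coo.row]
    else:
        forward = pseudotime[coo.col] >= pseudotime[coo.row]
    rows, cols, vals = coo.row[forward], coo.col[forward], coo.data[forward]

    out_deg = np.bincount(rows, minlength=n)
    dangling = [
        i for i in range(n) if out_deg[i] == 0 and i not in term_set and np.isfinite(pseudotime[i])
    ]
    if dangling:
        warnings.warn(
            f"{len(dangling)} cells with no forward edge attached to their "
            "nearest forward cell",
            stacklevel=2,
        )
        extra_r, extra_c = [], []
        for i in dangling:
            ahead = np.flatnonzero(pseudotime >= pseudotime[i])
            ahead = ahead[ahead != i]
            if ahead.size == 0:
                continue
            j = ahead[np.argmin(pseudotime[ahead] - pseudotime[i])]
            extra_r.append(i)
            extra_c.append(int(j))
        rows = np.concatenate([rows, extra_r]).astype(int)
        cols = np.concatenate([cols, extra_c]).astype(int)
        vals = np.concatenate([vals, np.ones(len(extra_r))])

    # absorbing rows: identity
    keep = ~np.isin(rows, termini)
    rows, cols, vals = rows[keep], cols[keep], vals[keep]
    w = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    row_sum = np.asarray(w.sum(axis=1)).ravel()
    transient = np.array([i for i in range(n) if i not in term_set])
    # unreachable / isolated transient cells: uniform over termini later
    ok = transient[row_sum[transient] > 0]
    inv = np.zeros(n)
    inv[row_sum > 0] = 1.0 / row_sum[row_sum > 0]
    p = sp.diags(inv) @ w

    q = p[ok][:, ok]
    r = p[ok][:, termini]
    b_ok = sp.linalg.spsolve(sp.identity(len(ok), format="csc") - q.tocsc(), r.tocsc())
    b_ok = np.asarray(b_ok.todense()) if sp.issparse(b_ok) else np.atleast_2d(b_ok)

    probs = np.full((n, len(termini)), np.nan)
    probs[ok] = b_ok
    for j, t in enumerate(termini):
        probs[t] = 0.0
        probs[t, j] = 1.0
    bad = np.isnan(probs).any(axis=1)
    if bad.any():
        probs[bad] = 1.0 / len(termini)
    # clean numerical residue and renormalize exactly
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum(axis=1, keepdims=True)
    return probs


def differentiation_potential(branch_probs: np.ndarray) -> np.ndarray:
    """Shannon entropy (natural log) of each branch-probability row."""
    p = np.asarray(branch_probs, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log(p), 0.0)
    return terms.sum(axis=1)


def gene_trends(
    values: np.ndarray,
    pseudotime: np.ndarray,
    branch_weights: np.ndarray,
    bandwidth: float = 0.1,
    n_grid: int = 100,
    gene_names=None,
):
    """Branch-weighted local-linear gene trends along pseudotime.

    For each gene, a degree-1 local polynomial regression of expression
    on pseudotime with weights = branch probability toward the chosen
    terminus times a Gaussian kernel in pseudotime, evaluated on a fixed
    grid of ``n_grid`` points spanning the weighted pseudotime range.
    Returns (grid, trend DataFrame genes x grid, se DataFrame).
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    values = np.atleast_2d(np.asarray(values, float))
    if values.shape[0] == len(pseudotime) and values.ndim == 2:
        values = values.T  # genes x cells
    pt = np.asarray(pseudotime, float)
    bw_weights = np.asarray(branch_weights, float)
    if np.all(bw_weights == 0):
        raise ValueError("all branch weights are zero")
    mask = np.isfinite(pt)
    pt, bw_weights, values = pt[mask], bw_weights[mask], values[:, mask]
    support = bw_weights > 0
    lo, hi = pt[support].min(), pt[support].max()
    grid = np.linspace(lo, hi, n_grid)
    h = bandwidth * max(hi - lo, 1e-12)

    n_genes = values.shape[0]
    trend = np.empty((n_genes, n_grid))
    se = np.empty((n_genes, n_grid))
    for gidx, g in enumerate(grid):
        kern = np.exp(-0.5 * ((pt - g) / h) ** 2)
        w = kern * bw_weights
        sw = w.sum()
        if sw <= 0:
            trend[:, gidx] = np.nan
            se[:, gidx] = np.nan
            continue
        x = pt - g
        sx = (w * x).sum()
        sxx = (w * x * x).sum()
        sy = values @ w
        sxy = values @ (w * x)
        denom = sw * sxx - sx * sx
        if denom <= 1e-30:
            beta0 = sy / sw
            var0 = 1.0 / sw
        else:
            # weighted least squares intercept at the grid point
            beta0 = (sxx * sy - sx * sxy) / denom
            var0 = sxx / denom
        trend[:, gidx] = beta0
        resid_scale = np.sqrt(
            np.maximum((values**2 @ w) / sw - (sy / sw) ** 2, 0.0)
        )
        se[:, gidx] = resid_scale * np.sqrt(var0)
    index = gene_names if gene_names is not None else range(n_genes)
    return (
        grid,
        pd.DataFrame(trend, index=index, columns=grid),
        pd.DataFrame(se, index=index, columns=grid),
    )


def run_trajectory(
    embedding: np.ndarray,
    start: int,
    k: int = 30,
    n_components: int = 10,
    termini: list[int] | None = None,
    timepoints=None,
    resolution: float = 1.0,
    backward_scale: float = 1.0,
    smooth_steps: int = 1,
    seed: int = 0,
) -> TrajectoryResult:
    """End-to-end trajectory: graph → diffusion → pseudotime →
    branch probabilities → differentiation potential.

    ``backward_scale`` defaults to 1.0 here (unlike the strict
    :func:`branch_probabilities` default) because estimated pseudotime on
    real or simulated noisy data needs the local tolerance.
    ``smooth_steps`` diffusion-averages the solved absorption
    probabilities over the neighbourhood graph — the per-cell
    interpolation step of waypoint-based trajectory methods — before the
    entropy is taken; terminus rows stay one-hot.
    """
    graph = build_graph(embedding, k=k, timepoints=timepoints)
    space = diffusion_components(graph, d=n_components)
    pt = compute_pseudotime(graph, space.components, start)
    if termini is None:
        labels = cluster_graph(graph, resolution=resolution, seed=seed)
        termini = find_termini(graph, pt, labels)
        if not termini:
            raise ValueError("no termini detected; supply them explicitly")
    probs = branch_probabilities(graph, pt, termini, backward_scale=backward_scale)
    for _ in range(smooth_steps):
        probs = space.transition_matrix @ probs
        probs /= probs.sum(axis=1, keepdims=True)
    for j, t in enumerate(termini):
        probs[t] = 0.0
        probs[t, j] = 1.0
    return TrajectoryResult(
        start_cell=int(start),
        termini=list(termini),
        pseudotime=pt,
        branch_probs=probs,
        diff_potential=differentiation_potential(probs),
        k_used=k,
    )


def robustness_check(
    embedding: np.ndarray,
    start: int,
    k_values: list[int],
    termini: list[int] | None = None,
    n_components: int = 10,
    timepoints=None,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Pairwise Pearson correlations of trajectory outputs across k.

    Termini are detected at the first k and reused so branch-probability
    columns align.  A k whose graph leaves cells unreachable from the
    start is flagged and excluded.
    """
    if len(k_values) < 2:
        raise ValueError("need at least two k values")
    results: list[tuple[int, TrajectoryResult]] = []
    excluded = []
    for k in k_values:
        res = run_trajectory(
            embedding,
            start,
            k=k,
            n_components=n_components,
            termini=termini,
            timepoints=timepoints,
            seed=seed,
        )
        if np.any(~np.isfinite(res.pseudotime)):
            excluded.append(k)
            continue
        if termini is None:
            termini = res.termini
        results.append((k, res))
    if excluded:
        warnings.warn(f"excluded disconnected k values: {excluded}", stacklevel=2)
    ks = [k for k, _ in results]

    def corr_matrix(extract) -> pd.DataFrame:
        mat = pd.DataFrame(index=ks, columns=ks, dtype=float)
        for i, (_, ra) in enumerate(results):
            for j, (_, rb) in enumerate(results):
                mat.iloc[i, j] = float(np.corrcoef(extract(ra), extract(rb))[0, 1])
        return mat

    return {
        "pseudotime": corr_matrix(lambda r: r.pseudotime),
        "diff_potential": corr_matrix(lambda r: r.diff_potential),
        "branch_probs": corr_matrix(lambda r: r.branch_probs.ravel()),
        "excluded_k": excluded,
    }
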