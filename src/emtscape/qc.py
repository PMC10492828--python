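"""Cell QC, size-factor log-normalization, HVG selection and the
density-ratio doublet score.

Cells are kept when they detect strictly more than ``min_genes`` genes
and carry strictly less than ``max_mito_fraction`` mitochondrial RNA.
Size factors are per-cell library sizes rescaled to mean 1 (a deliberate
simplification of pooled deconvolution factors; see docs/methods.md),
and normalization is log2(count / size_factor + 1).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "QCThresholds",
    "DEFAULT_EXCLUSION_PATTERNS",
    "filter_cells",
    "compute_size_factors",
    "log_normalize",
    "select_hvgs",
    "density_ratio",
    "doublet_score",
]

#: HVG exclusion defaults: ribosomal and mitochondrial prefixes,
#: Y-chromosome genes and Xist (mouse naming conventions).
DEFAULT_EXCLUSION_PATTERNS = (
    r"^mt-",
    r"^Rp[sl]",
    r"^Mrp[sl]",
    r"^Xist$",
    r"^Ddx3y$",
    r"^Eif2s3y$",
    r"^Uty$",
    r"^Kdm5d$",
)


@dataclass(frozen=True)
class QCThresholds:
    """Strict QC bounds: keep cells with detected genes > ``min_genes``
    and mitochondrial fraction < ``max_mito_fraction``."""

    min_genes: int = 2000
    max_mito_fraction: float = 0.20

    def __post_init__(self) -> None:
        if not np.isfinite(self.min_genes) or self.min_genes < 0:
            raise ValueError("min_genes must be a finite non-negative integer")
        if not (0.0 <= self.max_mito_fraction <= 1.0):
            raise ValueError("max_mito_fraction must lie in [0, 1]")


def _counts(adata: ad.AnnData) -> sp.csr_matrix:
    x = adata.X
    return x.tocsr() if sp.issparse(x) else sp.csr_matrix(x)


def filter_cells(
    adata: ad.AnnData,
    thresholds: QCThresholds = QCThresholds(),
    mito_column: str = "mito_fraction",
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Apply the QC thresholds; returns (filtered AnnData, per-cell report).

    Both bounds are strict: a cell detecting exactly ``min_genes`` genes
    or at exactly ``max_mito_fraction`` mitochondrial content is removed.
    """
    if mito_column not in adata.obs:
        raise ValueError(f"missing mitochondrial-fraction column {mito_column!r}")
    x = _counts(adata)
    detected = np.asarray((x > 0).sum(axis=1)).ravel()
    mito = adata.obs[mito_column].to_numpy(float)
    pass_genes = detected > thresholds.min_genes
    pass_mito = mito < thresholds.max_mito_fraction
    keep = pass_genes & pass_mito
    report = pd.DataFrame(
        {
            "n_genes_detected": detected,
            "mito_fraction": mito,
            "pass_genes": pass_genes,
            "pass_mito": pass_mito,
            "keep": keep,
        },
        index=adata.obs_names,
    )
    out = adata[keep].copy()
    out.obs["n_genes_detected"] = detected[keep]
    return out, report


def compute_size_factors(adata: ad.AnnData) -> np.ndarray:
    """Library-size factors: cell total / mean total, mean-normalized to 1."""
    lib = np.asarray(_counts(adata).sum(axis=1)).ravel().astype(float)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        names = list(adata.obs_names[zero[:5]])
        raise ValueError(f"zero-count cells cannot be size-factor normalized: {names}")
    return lib / lib.mean()


def log_normalize(
    adata: ad.AnnData, size_factors: np.ndarray | None = None, layer: str = "lognorm"
) -> ad.AnnData:
    """log2(count / size_factor + 1), stored as a dense layer.

    Writes ``adata.obs["size_factor"]`` and ``adata.layers[layer]`` in
    place and returns the same object.
    """
    x = _counts(adata)
    if x.size and x.min() < 0:
        raise ValueError("negative counts")
    if size_factors is None:
        size_factors = compute_size_factors(adata)
    size_factors = np.asarray(size_factors, float)
    if np.any(size_factors <= 0):
        raise ValueError("size factors must be positive")
    dense = np.asarray(x.todense(), float) / size_factors[:, None]
    adata.layers[layer] = np.log2(dense + 1.0)
    adata.obs["size_factor"] = size_factors
    return adata


def select_hvgs(
    adata: ad.AnnData,
    n_top: int,
    exclusion_patterns: tuple[str, ...] = DEFAULT_EXCLUSION_PATTERNS,
    layer: str = "lognorm",
) -> pd.DataFrame:
    """Rank genes by variance of log-normalized expression.

    Genes matching any exclusion pattern (regex, case-sensitive) are
    dropped before ranking.  Returns a DataFrame of the top ``n_top``
    genes ordered by decreasing variance.
    """
    values = adata.layers[layer]
    var_stat = np.asarray(values, float).var(axis=0, ddof=1)
    excluded = np.zeros(adata.n_vars, bool)
    compiled = [re.compile(p) for p in exclusion_patterns]
    for i, name in enumerate(adata.var_names):
        if any(p.search(name) for p in compiled):
            excluded[i] = True
    eligible = np.flatnonzero(~excluded)
    if eligible.size == 0:
        raise ValueError("no genes left after applying exclusion patterns")
    if n_top > eligible.size:
        raise ValueError(
            f"n_top={n_top} exceeds the {eligible.size} non-excluded genes"
        )
    order = eligible[np.argsort(-var_stat[eligible], kind="stable")][:n_top]
    return pd.DataFrame(
        {"variance": var_stat[order]},
        index=pd.Index(adata.var_names[order], name="gene_id"),
    )


def density_ratio(dens_sim, dens_orig):
    """Doublet score kernel: simulated-doublet density over squared
    original-cell density; zero original density maps to +inf."""
    dens_sim = np.asarray(dens_sim, float)
    dens_orig = np.asarray(dens_orig, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = dens_sim / dens_orig**2
    return np.where(dens_orig == 0, np.inf, score)


def doublet_score(
    adata: ad.AnnData,
    n_sim: int | None = None,
    k: int = 20,
    n_pcs: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Density-ratio doublet score per cell.

    ``n_sim`` artificial doublets (default: one per original cell) are
    built by summing random cell pairs' counts.  Originals and doublets
    are library-size log-normalized and embedded in a common PCA space;
    each original cell's score is the local density of simulated doublets
    divided by the squared local density of original cells, with density
    the inverse mean distance to the ``k`` nearest neighbours of each
    set (normalized by set size).  Cells with zero original density get
    ``+inf``.
    """
    n = adata.n_obs
    if n < 2:
        raise ValueError("need at least 2 cells")
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    if n_sim is None:
        n_sim = n
    if n_sim == 0:
        return np.zeros(n)
    rng = np.random.default_rng([seed, 5])
    counts = np.asarray(_counts(adata).todense(), float)
    pa = rng.integers(0, n, size=n_sim)
    pb = rng.integers(0, n, size=n_sim)
    doublets = counts[pa] + counts[pb]

    def _lognorm(m: np.ndarray) -> np.ndarray:
        lib = m.sum(axis=1)
        lib[lib == 0] = 1.0
        sf = lib / lib.mean()
        return np.log2(m / sf[:, None] + 1.0)

    combined = _lognorm(np.vstack([counts, doublets]))
    n_pcs = min(n_pcs, combined.shape[1], combined.shape[0] - 1)
    emb = PCA(n_components=n_pcs, random_state=0).fit_transform(combined)
    orig, dbl = emb[:n], emb[n:]

    k_dbl = min(k, n_sim)
    nn_orig = NearestNeighbors(n_neighbors=k + 1).fit(orig)
    d_orig, _ = nn_orig.kneighbors(orig)
    mean_d_orig = d_orig[:, 1:].mean(axis=1)  # drop self
    nn_dbl = NearestNeighbors(n_neighbors=k_dbl).fit(dbl)
    d_dbl, _ = nn_dbl.kneighbors(orig)
    mean_d_dbl = d_dbl.mean(axis=1)

    with np.errstate(divide="ignore"):
        dens_orig = np.where(mean_d_orig > 0, 1.0 / mean_d_orig, np.inf) * (k / n)
        dens_dbl = np.where(mean_d_dbl > 0, 1.0 / mean_d_dbl, np.inf) * (
            k_dbl / n_sim
        )
    score = density_ratio(dens_dbl, dens_orig)
    if np.any(~np.isfinite(score)):
        warnings.warn(
            f"{int((~np.isfinite(score)).sum())} cells with degenerate local "
            "density; scores set to +inf",
            stacklevel=2,
        )
    return score
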