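"""Wilcoxon rank-sum marker calling with fold-change / detection-fraction
/ FDR filters.

Cluster markers use the one-vs-rest convention: a gene is a marker of a
group when its log2 fold change (difference of group means on
log-normalized values) exceeds 0.25, it is detected (count > 0) in more
than 25% of the group, and its Benjamini–Hochberg q-value is at most
0.05 — positively enriched genes only.  Batch-associated genes use the
stricter 0.5 / 75% thresholds with the same machinery.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

__all__ = [
    "wilcoxon_test",
    "bh_adjust",
    "find_markers",
    "find_batch_genes",
]

_EXACT_MAX_N = 12


def wilcoxon_test(x, y, method: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) test.

    With ``method="auto"`` the exact null distribution is used when
    n_x + n_y <= 12 and there are no ties across the pooled sample,
    otherwise the normal approximation with tie correction and
    continuity correction ("exact"/"asymptotic" force either path).
    Returns (U statistic of x, two-sided p).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if method == "auto":
        pooled = np.concatenate([x, y])
        no_ties = len(np.unique(pooled)) == len(pooled)
        method = "exact" if (x.size + y.size <= _EXACT_MAX_N and no_ties) else "asymptotic"
    if method == "exact":
        res = mannwhitneyu(x, y, alternative="two-sided", method="exact")
    elif method == "asymptotic":
        res = mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _dense(x) -> np.ndarray:
    return np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x)


def _group_table(
    values: np.ndarray,
    detected: np.ndarray,
    in_mask: np.ndarray,
    gene_names,
    group_label,
) -> pd.DataFrame:
    """One-vs-rest DE table for a single group over all genes."""
    out_mask = ~in_mask
    x_in = values[in_mask]
    x_out = values[out_mask]
    if min(len(x_in), len(x_out)) > _EXACT_MAX_N:
        res = mannwhitneyu(
            x_in, x_out, alternative="two-sided", method="asymptotic",
            use_continuity=True, axis=0,
        )
        pvals = np.minimum(np.atleast_1d(res.pvalue), 1.0)
    else:
        pvals = np.array(
            [wilcoxon_test(x_in[:, j], x_out[:, j])[1] for j in range(values.shape[1])]
        )
    log_fc = x_in.mean(axis=0) - x_out.mean(axis=0)
    frac_in = detected[in_mask].mean(axis=0)
    frac_out = detected[out_mask].mean(axis=0)
    return pd.DataFrame(
        {
            "gene": list(gene_names),
            "group": group_label,
            "log_fc": log_fc,
            "frac_in": frac_in,
            "frac_out": frac_out,
            "p_value": pvals,
            "q_value": bh_adjust(pvals),
        }
    )


def find_markers(
    adata,
    groupby: str,
    layer: str = "lognorm",
    logfc_min: float = 0.25,
    frac_min: float = 0.25,
    q_max: float = 0.05,
    mode: str = "one_vs_rest",
    return_all: bool = False,
) -> pd.DataFrame:
    """Marker genes per group under the fold-change/fraction/FDR filters.

    Detection ("expressed") means raw count > 0.  Genes are retained when
    log_fc > logfc_min (hence positively enriched), frac_in > frac_min
    and q <= q_max; output is sorted per group by (q, -log_fc).
    In ``pairwise`` mode every ordered group pair is contrasted and the
    detection-fraction filter applies to the higher-expressing side.
    With ``return_all`` the full unfiltered table is returned with a
    boolean ``passed`` column instead (needed by downstream gene-set
    definitions that must see non-differential genes too).
    """
    labels = np.asarray(adata.obs[groupby])
    uniq = list(pd.unique(labels))
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    values = np.asarray(adata.layers[layer], float)
    detected = _dense(adata.X > 0).astype(float)
    tables = []
    if mode == "one_vs_rest":
        contrasts = [(g, None) for g in uniq]
    elif mode == "pairwise":
        contrasts = [(a, b) for a in uniq for b in uniq if a != b]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    for g, other in contrasts:
        in_mask = labels == g
        sel = np.ones(len(labels), bool) if other is None else (in_mask | (labels == other))
        if in_mask.sum() < 2:
            warnings.warn(f"group {g!r} has fewer than 2 cells; skipped", stacklevel=2)
            continue
        label = g if other is None else f"{g}_vs_{other}"
        tab = _group_table(
            values[sel], detected[sel], in_mask[sel], adata.var_names, label
        )
        frac_high = np.maximum(tab["frac_in"], tab["frac_out"]) if other is not None else tab["frac_in"]
        keep = (
            (tab["log_fc"] > max(logfc_min, 0.0))
            & (frac_high > frac_min)
            & (tab["q_value"] <= q_max)
        )
        if return_all:
            tab = tab.assign(passed=keep.to_numpy())
        else:
            tab = tab[keep]
        tab = tab.sort_values(["q_value", "log_fc"], ascending=[True, False])
        tables.append(tab)
    if not tables:
        return pd.DataFrame(
            columns=["gene", "group", "log_fc", "frac_in", "frac_out", "p_value", "q_value"]
        )
    return pd.concat(tables, ignore_index=True)


def find_batch_genes(
    adata,
    batch_column: str = "batch",
    layer: str = "lognorm",
    logfc_min: float = 0.5,
    frac_min: float = 0.75,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Batch-associated genes: the marker machinery at the stricter
    log-fold-change 0.5 / detection 75% thresholds, one batch vs rest."""
    out = find_markers(
        adata,
        groupby=batch_column,
        layer=layer,
        logfc_min=logfc_min,
        frac_min=frac_min,
        q_max=q_max,
        mode="one_vs_rest",
    )
    return out.rename(columns={"group": "batch"})
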