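"""Per-cell gene-profile scores and dual-threshold EMP classification.

A cell's profile score for a signature is the arithmetic mean of its
log-normalized expression over the signature genes present in the
matrix.  A cell exhibits epithelial-mesenchymal plasticity (EMP) when it
meets the thresholds of both the epithelial-side profile (endothelial or
epicardial, depending on the lineage analyzed) and the mesenchymal
profile.  EMP is a continuum; the binary flag keeps both raw scores for
downstream use.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ProfileScores",
    "EmpContrast",
    "score_signatures",
    "nearest_rank_percentile",
    "otsu_threshold",
    "set_thresholds",
    "classify_emp",
    "emp_contrast",
    "mean_scale",
]

logger = logging.getLogger(__name__)


@dataclass
class ProfileScores:
    """Cell x role profile scores with per-role thresholds and EMP flags."""

    scores: pd.DataFrame
    thresholds: dict = field(default_factory=dict)
    threshold_strategy: str | None = None
    emp_flag: pd.Series | None = None
    emp_roles: tuple | None = None

    @property
    def roles(self) -> list[str]:
        return list(self.scores.columns)


def score_signatures(
    adata, signatures: dict[str, list[str]], layer: str = "lognorm"
) -> ProfileScores:
    """Mean log-normalized expression over each signature's genes.

    Signature genes absent from the matrix are logged and dropped; a
    signature with no gene in the matrix is an error.
    """
    values = np.asarray(adata.layers[layer], float)
    var_index = pd.Index(adata.var_names)
    cols = {}
    for name, genes in signatures.items():
        present = [g for g in genes if g in var_index]
        missing = [g for g in genes if g not in var_index]
        if missing:
            logger.info(
                "signature %s: dropping %d genes absent from the matrix: %s",
                name, len(missing), missing[:10],
            )
        if not present:
            raise ValueError(f"signature {name!r} has no genes in the matrix")
        idx = var_index.get_indexer(present)
        cols[name] = values[:, idx].mean(axis=1)
    scores = pd.DataFrame(cols, index=adata.obs_names)
    return ProfileScores(scores=scores)


def nearest_rank_percentile(values: np.ndarray, p: float) -> float:
    """Nearest-rank percentile: the ceil(p/100 * n)-th smallest value."""
    values = np.sort(np.asarray(values, float))
    n = len(values)
    if n == 0:
        raise ValueError("empty value vector")
    rank = max(int(np.ceil(p / 100.0 * n)), 1)
    return float(values[rank - 1])


def otsu_threshold(values: np.ndarray, n_bins: int = 128) -> float:
    """Otsu's between-class-variance-maximizing threshold on a score vector."""
    values = np.asarray(values, float)
    hist, edges = np.histogram(values, bins=n_bins)
    mids = (edges[:-1] + edges[1:]) / 2.0
    total = hist.sum()
    w0 = np.cumsum(hist)
    w1 = total - w0
    mu_cum = np.cumsum(hist * mids)
    mu_total = mu_cum[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu_cum / w0
        mu1 = (mu_total - mu_cum) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between[~np.isfinite(between)] = -1.0
    return float(mids[int(np.argmax(between))])


def set_thresholds(
    scores: ProfileScores,
    strategy: str = "percentile",
    percentile: float = 75.0,
    fixed: dict | None = None,
) -> ProfileScores:
    """Attach per-role thresholds by the chosen strategy.

    ``percentile`` uses the nearest-rank convention; ``otsu`` maximizes
    between-class variance on each score vector; ``fixed`` takes
    user-supplied per-role values (all roles must be covered).
    """
    if strategy == "percentile":
        thresholds = {
            role: nearest_rank_percentile(scores.scores[role].to_numpy(), percentile)
            for role in scores.roles
        }
    elif strategy == "otsu":
        thresholds = {
            role: otsu_threshold(scores.scores[role].to_numpy())
            for role in scores.roles
        }
    elif strategy == "fixed":
        if fixed is None:
            raise ValueError("fixed strategy requires explicit threshold values")
        missing = [r for r in scores.roles if r not in fixed]
        if missing:
            raise ValueError(f"fixed thresholds missing for roles: {missing}")
        thresholds = {role: float(fixed[role]) for role in scores.roles}
    else:
        raise ValueError(f"unknown threshold strategy {strategy!r}")
    return replace(scores, thresholds=thresholds, threshold_strategy=strategy)


def classify_emp(
    scores: ProfileScores,
    epithelial_role: str = "endothelial",
    mesenchymal_role: str = "mesenchymal",
) -> ProfileScores:
    """Flag cells meeting both the epithelial-side and mesenchymal
    thresholds (score >= threshold on each axis)."""
    for role in (epithelial_role, mesenchymal_role):
        if role not in scores.roles:
            raise ValueError(f"role {role!r} not among scored profiles {scores.roles}")
        if role not in scores.thresholds:
            raise ValueError(f"no threshold set for role {role!r}")
    epi = scores.scores[epithelial_role] >= scores.thresholds[epithelial_role]
    mes = scores.scores[mesenchymal_role] >= scores.thresholds[mesenchymal_role]
    return replace(
        scores,
        emp_flag=(epi & mes).rename("emp"),
        emp_roles=(epithelial_role, mesenchymal_role),
    )


@dataclass
class EmpContrast:
    """EMP fractions of two conditions with a bootstrap CI on the fold change."""

    fraction_a: float
    fraction_b: float
    fold_change: float
    ci_low: float
    ci_high: float
    n_boot: int


def emp_contrast(
    scores_a: ProfileScores,
    scores_b: ProfileScores,
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 95.0,
) -> EmpContrast:
    """Fold change of EMP fractions (condition b over condition a) with a
    percentile bootstrap CI over cells."""
    for s in (scores_a, scores_b):
        if s.emp_flag is None:
            raise ValueError("classify_emp must be run on both conditions first")
    flags_a = scores_a.emp_flag.to_numpy(bool)
    flags_b = scores_b.emp_flag.to_numpy(bool)
    frac_a = float(flags_a.mean())
    frac_b = float(flags_b.mean())
    if frac_a == 0.0:
        warnings.warn("condition-a EMP fraction is 0; fold change is +inf", stacklevel=2)
        fold = np.inf
    else:
        fold = frac_b / frac_a
    rng = np.random.default_rng([seed, 31])
    boots = np.empty(n_boot)
    na, nb = len(flags_a), len(flags_b)
    for i in range(n_boot):
        fa = flags_a[rng.integers(0, na, na)].mean()
        fb = flags_b[rng.integers(0, nb, nb)].mean()
        boots[i] = np.inf if fa == 0 else fb / fa
    alpha = (100.0 - ci) / 2.0
    lo, hi = np.percentile(boots, [alpha, 100.0 - alpha])
    return EmpContrast(
        fraction_a=frac_a,
        fraction_b=frac_b,
        fold_change=float(fold),
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
    )


def mean_scale(scores: ProfileScores) -> ProfileScores:
    """Centre each role's score vector to mean 0 (for comparison plots)."""
    if len(scores.scores) < 2:
        raise ValueError("mean scaling needs at least 2 cells")
    centred = scores.scores - scores.scores.mean(axis=0)
    return replace(scores, scores=centred)
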