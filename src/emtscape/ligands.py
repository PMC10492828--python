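"""Correlation-based ligand-activity ranking.

Given a ligand → target regulatory-potential prior and a
receiver-population response gene set (differentially enriched genes),
each candidate ligand's activity is the Pearson correlation between its
potential vector over the gene universe (response ∪ background,
restricted to prior targets) and the binary response-membership
indicator.  Ligands are ranked by activity and the top quartile of
scores is flagged for visualization; the full table is always reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "LigandPrior",
    "define_gene_sets",
    "filter_candidate_ligands",
    "ligand_activities",
    "top_quartile_filter",
    "top_targets",
]


@dataclass
class LigandPrior:
    """Ligand x target non-negative regulatory-potential matrix with an
    optional ligand → receptor mapping."""

    potential: pd.DataFrame
    receptor_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.potential.to_numpy() < 0).any():
            raise ValueError("regulatory potentials must be non-negative")
        if self.potential.index.duplicated().any():
            raise ValueError("duplicate ligand rows in the prior")

    @property
    def ligands(self) -> list[str]:
        return list(self.potential.index)

    @property
    def targets(self) -> list[str]:
        return list(self.potential.columns)

    @classmethod
    def from_csv(cls, potential_path, receptor_map_path=None) -> "LigandPrior":
        potential = pd.read_csv(potential_path, index_col=0)
        receptor_map: dict = {}
        if receptor_map_path is not None:
            rm = pd.read_csv(receptor_map_path, header=None, names=["ligand", "receptor"])
            for ligand, sub in rm.groupby("ligand"):
                receptor_map[ligand] = list(sub["receptor"])
        return cls(potential=potential, receptor_map=receptor_map)


def define_gene_sets(
    de: pd.DataFrame,
    logfc_min: float = 0.25,
    frac_min: float = 0.25,
    q_max: float = 0.05,
    background_frac_min: float = 0.10,
) -> tuple[list[str], list[str]]:
    """Response and background gene sets from a receiver DE table.

    Response genes pass log_fc > logfc_min, detection > frac_min and
    q <= q_max, ranked by FDR.  Background genes are expressed (detection
    fraction above ``background_frac_min`` on either side) but not in the
    response set.  The two sets are disjoint by construction.
    """
    required = {"gene", "log_fc", "frac_in", "frac_out", "q_value"}
    missing = required - set(de.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    resp_mask = (
        (de["log_fc"] > logfc_min) & (de["frac_in"] > frac_min) & (de["q_value"] <= q_max)
    )
    response = list(de.loc[resp_mask].sort_values("q_value")["gene"])
    if not response:
        raise ValueError("empty response gene set under the stated filters")
    detected = np.maximum(de["frac_in"], de["frac_out"]) >= background_frac_min
    background = [
        g for g in de.loc[detected, "gene"] if g not in set(response)
    ]
    return response, background


def filter_candidate_ligands(
    adata,
    sender_column: str,
    sender_labels: list,
    prior: LigandPrior,
    receiver_label=None,
    expr_frac_min: float = 0.10,
) -> list[str]:
    """Candidate ligands detected in senders (and receptors in the receiver).

    A ligand is kept when it is detected (count > 0) in more than
    ``expr_frac_min`` of at least one sender population, and — if the
    prior maps it to receptors and a receiver is given — at least one of
    its receptors is detected in the receiver population.  Ligands with
    no receptor mapping pass the receptor check.
    """
    labels = np.asarray(adata.obs[sender_column])
    x = adata.X
    detected = np.asarray((x > 0).todense()) if sp.issparse(x) else (np.asarray(x) > 0)
    var_index = pd.Index(adata.var_names)
    in_matrix = [lg for lg in prior.ligands if lg in var_index]
    if not in_matrix:
        raise ValueError("no ligand of the prior is present in the matrix")
    receiver_mask = labels == receiver_label if receiver_label is not None else None
    kept = []
    for ligand in in_matrix:
        col = var_index.get_loc(ligand)
        expressed = False
        for s in sender_labels:
            mask = labels == s
            if mask.any() and detected[mask, col].mean() > expr_frac_min:
                expressed = True
                break
        if not expressed:
            continue
        receptors = [
            r for r in prior.receptor_map.get(ligand, []) if r in var_index
        ]
        if receptors and receiver_mask is not None and receiver_mask.any():
            rec_cols = var_index.get_indexer(receptors)
            if not detected[np.ix_(receiver_mask, rec_cols)].any():
                continue
        kept.append(ligand)
    return kept


def ligand_activities(
    prior: LigandPrior,
    response_set: list[str],
    background_set: list[str],
    ligands: list[str] | None = None,
) -> pd.DataFrame:
    """Pearson activity of each ligand against response membership.

    The universe is (response ∪ background) ∩ prior targets; the
    activity of a ligand is corr(potential over universe, indicator).
    Constant potential vectors give missing activity with a warning.
    Returns a table sorted by descending activity.
    """
    overlap = set(response_set) & set(background_set)
    if overlap:
        raise ValueError(f"response and background sets overlap: {sorted(overlap)[:5]}")
    target_index = pd.Index(prior.targets)
    universe = [g for g in list(response_set) + list(background_set) if g in target_index]
    if len(universe) < 3:
        raise ValueError("gene universe too small after restricting to prior targets")
    indicator = np.array([1.0 if g in set(response_set) else 0.0 for g in universe])
    if indicator.std() == 0:
        raise ValueError("response indicator is constant over the universe")
    use = ligands if ligands is not None else prior.ligands
    rows = []
    for ligand in use:
        vec = prior.potential.loc[ligand, universe].to_numpy(float)
        if vec.std() == 0:
            warnings.warn(
                f"ligand {ligand!r} has a constant potential vector; activity undefined",
                stacklevel=2,
            )
            activity = np.nan
        else:
            activity = float(np.corrcoef(vec, indicator)[0, 1])
        rows.append({"ligand": ligand, "activity": activity})
    out = pd.DataFrame(rows).sort_values(
        "activity", ascending=False, na_position="last"
    )
    return out.reset_index(drop=True)


def top_quartile_filter(activities: pd.DataFrame) -> pd.DataFrame:
    """Flag the top quartile of activity scores.

    Keeps the top ceil(n/4) scores (ties at the threshold keep more;
    all-equal scores keep everything).  With fewer than 4 scored ligands
    everything is kept with a warning.  The full table is returned with a
    boolean ``kept`` column.
    """
    out = activities.copy()
    scores = out["activity"].to_numpy(float)
    finite = np.isfinite(scores)
    n = int(finite.sum())
    if n < 4:
        warnings.warn("fewer than 4 scored ligands; keeping all", stacklevel=2)
        out["kept"] = finite
        return out
    m = int(np.ceil(n / 4.0))
    threshold = np.sort(scores[finite])[::-1][m - 1]
    out["kept"] = finite & (scores >= threshold)
    return out


def top_targets(prior: LigandPrior, ligand: str, n: int = 10) -> pd.DataFrame:
    """A kept ligand's top-n targets by regulatory potential."""
    row = prior.potential.loc[ligand].sort_values(ascending=False).head(n)
    return pd.DataFrame({"target": row.index, "potential": row.to_numpy()})
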