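"""Shared fixtures: small simulated datasets reused across test modules.

Everything is generated programmatically with fixed seeds; the heavier
bifurcation run (n=1500) is session-scoped because trajectory tests and
several acceptance checks share it.
"""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.decomposition import PCA

from emtscape import qc, trajectory as traj
from emtscape.sim import PROGENITOR_MARKER, SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_adata():
    """800-cell control simulation with log-normalized layer."""
    cfg = SimConfig(n_cells_per_condition=800, seed=3)
    adata = simulate_dataset(cfg, "control")
    qc.log_normalize(adata)
    return adata


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_cells_per_condition=800, seed=3)


def pca_embedding(adata, n_hvg=100, n_pcs=15):
    hvg = qc.select_hvgs(adata, n_top=n_hvg)
    idx = [adata.var_names.get_loc(g) for g in hvg.index]
    values = np.asarray(adata.layers["lognorm"])[:, idx]
    return PCA(n_components=n_pcs, random_state=0).fit_transform(values)


@pytest.fixture(scope="session")
def bifurcation_run():
    """Symmetric bifurcation world (n=1500, seed 0) with a full
    trajectory run; shared by trajectory and acceptance tests."""
    cfg = SimConfig(n_cells_per_condition=1500, seed=0)
    adata = simulate_dataset(cfg, "control")
    qc.log_normalize(adata)
    embedding = pca_embedding(adata)
    start = traj.select_start_cell(adata, PROGENITOR_MARKER)
    result = traj.run_trajectory(
        embedding,
        start,
        k=30,
        timepoints=adata.obs["timepoint"].to_numpy(),
        seed=0,
    )
    return {"config": cfg, "adata": adata, "embedding": embedding, "start": start, "result": result}
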