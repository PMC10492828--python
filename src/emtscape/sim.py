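"""Seeded synthetic scRNA-seq generator for a bifurcating EMT.

The generator plants a known latent structure — a progenitor trunk that
bifurcates into mesenchymal and endocardial termini, with a hybrid
epithelial-mesenchymal plasticity (EMP) window straddling the branch
point — and draws negative-binomial counts on top of it.  Every latent
quantity (latent time ``s``, branch, EMP membership, doublet status, true
size factor) is retained in the cell table so downstream stages can be
tested against planted truth.

Two conditions are supported: ``control``, and a ``stalled`` genotype in
which occupancy of the EMP window is multiplied by a configurable
enrichment factor (the mass outside the window, including the
mesenchymal terminus, is scaled down correspondingly).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "SimConfig",
    "simulate_latent",
    "simulate_counts",
    "simulate_dataset",
    "simulate_pair",
    "planted_thresholds",
    "simulate_ligand_prior",
]

CONDITIONS = ("control", "stalled")
BRANCHES = ("trunk", "mesenchymal", "endocardial")
PANEL_ROLES = ("endothelial", "mesenchymal", "epicardial", "shear_response")

# Decoy genes carried in every simulated matrix so that HVG exclusion
# rules (mitochondrial/ribosomal prefixes, Y-linked genes, Xist) have
# something to bite on.
DECOY_GENES = ("mt-Nd1", "mt-Co1", "Rps4x", "Rpl13", "Xist", "Ddx3y")

#: name of the planted progenitor marker gene (high only at small s);
#: used as the start-cell marker for trajectory inference.
PROGENITOR_MARKER = "ProgM"


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class SimConfig:
    """Stated world of the simulation.

    Latent time ``s`` lives in [0, 1]; cells with ``s < branch_point``
    are on the trunk, later cells are assigned to the mesenchymal or
    endocardial branch according to ``terminus_fractions``.  The EMP
    window is a sub-interval around the branch point inside which the
    endothelial and mesenchymal programs are co-elevated and the
    shear-response program switches on.
    """

    n_cells_per_condition: int = 2000
    n_genes: int = 200
    n_signature_genes_per_panel: int = 15
    branch_point: float = 0.5
    timepoint_windows: tuple = (
        ("E8.25", 0.0, 0.35),
        ("E9.25", 0.25, 0.65),
        ("E10.5", 0.55, 1.0),
    )
    emp_window: tuple = (0.40, 0.60)
    emp_enrichment_factor: float = 1.0
    terminus_fractions: tuple = (0.5, 0.5)  # (mesenchymal, endocardial)
    nb_dispersion: float = 10.0
    mean_library_size: float = 2000.0
    library_size_cv: float = 0.3
    doublet_rate: float = 0.0
    mito_fraction_params: tuple = (0.05, 0.02)
    low_quality_fraction: float = 0.0
    low_quality_mito_mean: float = 0.30
    n_lineage_genes: int = 40
    program_steepness: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells_per_condition <= 0:
            raise ValueError("n_cells_per_condition must be positive")
        if self.n_genes <= 0 or self.n_signature_genes_per_panel <= 0:
            raise ValueError("gene counts must be positive")
        n_reserved = (
            len(PANEL_ROLES) * self.n_signature_genes_per_panel
            + self.n_lineage_genes
            + len(DECOY_GENES)
            + 1  # progenitor marker
        )
        if n_reserved > self.n_genes:
            raise ValueError(
                f"signature panels + structural genes ({n_reserved}) exceed "
                f"n_genes ({self.n_genes})"
            )
        if not (0.0 < self.branch_point < 1.0):
            raise ValueError("branch_point must lie in (0, 1)")
        lo, hi = self.emp_window
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("emp_window must be a sub-interval of [0, 1]")
        if not (lo <= self.branch_point <= hi):
            raise ValueError("emp_window must contain branch_point")
        for label, w_lo, w_hi in self.timepoint_windows:
            if not (0.0 <= w_lo < w_hi <= 1.0):
                raise ValueError(f"timepoint window {label!r} not within [0, 1]")
        if abs(sum(self.terminus_fractions) - 1.0) > 1e-12:
            raise ValueError("terminus_fractions must sum to 1")
        if any(f < 0 for f in self.terminus_fractions):
            raise ValueError("terminus_fractions must be non-negative")
        if self.emp_enrichment_factor <= 0:
            raise ValueError("emp_enrichment_factor must be positive")
        if self.nb_dispersion <= 0 or self.mean_library_size <= 0:
            raise ValueError("nb_dispersion and mean_library_size must be positive")
        if self.library_size_cv < 0:
            raise ValueError("library_size_cv must be non-negative")
        if not (0.0 <= self.doublet_rate < 1.0):
            raise ValueError("doublet_rate must lie in [0, 1)")
        if not (0.0 <= self.low_quality_fraction < 1.0):
            raise ValueError("low_quality_fraction must lie in [0, 1)")

    def with_(self, **kwargs) -> "SimConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def _coverage(config: SimConfig) -> list[tuple[float, float]]:
    """Merged union of the timepoint windows as disjoint intervals."""
    ivs = sorted((lo, hi) for _, lo, hi in config.timepoint_windows)
    merged = [list(ivs[0])]
    for lo, hi in ivs[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def _emp_base_mass(config: SimConfig) -> float:
    """Fraction of covered latent time that lies in the EMP window."""
    cov = _coverage(config)
    total = sum(hi - lo for lo, hi in cov)
    e_lo, e_hi = config.emp_window
    inside = sum(max(0.0, min(hi, e_hi) - max(lo, e_lo)) for lo, hi in cov)
    return inside / total


def _sample_intervals(rng, intervals, n) -> np.ndarray:
    lengths = np.array([hi - lo for lo, hi in intervals], float)
    probs = lengths / lengths.sum()
    idx = rng.choice(len(intervals), size=n, p=probs)
    u = rng.uniform(size=n)
    lo = np.array([iv[0] for iv in intervals])
    hi = np.array([iv[1] for iv in intervals])
    return lo[idx] + u * (hi[idx] - lo[idx])


def simulate_latent(config: SimConfig, condition: str = "control") -> pd.DataFrame:
    """Draw per-cell latent states for one condition.

    Returns a cell table with columns ``s``, ``branch``, ``timepoint``,
    ``is_emp``, ``is_doublet`` (all False here; doublets are spiked in by
    :func:`simulate_counts`), ``condition``, and ``mito_fraction``.

    In the ``stalled`` condition the probability mass of the EMP window is
    multiplied by ``emp_enrichment_factor`` and the mass outside the
    window (including the mesenchymal terminus) is scaled down so the
    total stays 1.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    rng = np.random.default_rng([config.seed, 11, CONDITIONS.index(condition)])
    n = config.n_cells_per_condition

    m = _emp_base_mass(config)
    factor = config.emp_enrichment_factor if condition == "stalled" else 1.0
    p_emp = factor * m
    if p_emp >= 1.0:
        raise ValueError(
            f"emp_enrichment_factor={config.emp_enrichment_factor} would give the "
            f"EMP window probability mass {p_emp:.3f} >= 1 (base mass {m:.3f}); "
            "reduce the factor or the window size"
        )

    cov = _coverage(config)
    e_lo, e_hi = config.emp_window
    emp_ivs = [
        (max(lo, e_lo), min(hi, e_hi)) for lo, hi in cov if min(hi, e_hi) > max(lo, e_lo)
    ]
    out_ivs = []
    for lo, hi in cov:
        if hi <= e_lo or lo >= e_hi:
            out_ivs.append((lo, hi))
        else:
            if lo < e_lo:
                out_ivs.append((lo, e_lo))
            if hi > e_hi:
                out_ivs.append((e_hi, hi))

    in_emp = rng.uniform(size=n) < p_emp
    s = np.empty(n)
    if emp_ivs and in_emp.any():
        s[in_emp] = _sample_intervals(rng, emp_ivs, int(in_emp.sum()))
    if out_ivs and (~in_emp).any():
        s[~in_emp] = _sample_intervals(rng, out_ivs, int((~in_emp).sum()))

    # branch: trunk before the branch point, otherwise sampled terminus
    branch = np.full(n, "trunk", dtype=object)
    past = s >= config.branch_point
    fractions = np.asarray(config.terminus_fractions, float)
    choice = rng.choice(["mesenchymal", "endocardial"], size=int(past.sum()), p=fractions)
    branch[past] = choice

    # timepoint: uniform among windows covering s
    windows = config.timepoint_windows
    labels = np.empty(n, dtype=object)
    covers = np.array([[lo <= si <= hi for (_, lo, hi) in windows] for si in s])
    for i in range(n):
        opts = np.flatnonzero(covers[i])
        labels[i] = windows[opts[rng.integers(len(opts))]][0]

    mito_mean, mito_sd = config.mito_fraction_params
    mito = rng.normal(mito_mean, mito_sd, size=n)
    if config.low_quality_fraction > 0:
        low_q = rng.uniform(size=n) < config.low_quality_fraction
        mito[low_q] = rng.normal(config.low_quality_mito_mean, mito_sd, size=int(low_q.sum()))
    else:
        low_q = np.zeros(n, bool)
    mito = np.clip(mito, 0.0, 1.0)

    table = pd.DataFrame(
        {
            "s": s,
            "branch": pd.Categorical(branch, categories=list(BRANCHES)),
            "timepoint": labels,
            "is_emp": (s >= e_lo) & (s <= e_hi),
            "is_doublet": False,
            "is_low_quality": low_q,
            "condition": condition,
            "mito_fraction": mito,
        }
    )
    table.index = [f"{condition}_{i:05d}" for i in range(n)]
    table.index.name = "cell_id"
    return table


# ---------------------------------------------------------------------------
# expression programs

# intensity levels (arbitrary units; only relative shares matter)
_PANEL_HI = 2.0
_PANEL_LO = 0.05
_LINEAGE_LO = 0.5
_LINEAGE_HI = 1.5


def _program_intensity(
    role: str, s: np.ndarray, branch: np.ndarray, config: SimConfig
) -> np.ndarray:
    """Smooth program level in (s, branch) for one signature role."""
    st = config.program_steepness
    e_lo, e_hi = config.emp_window
    mes = branch == "mesenchymal"
    on_mid = (e_hi + config.branch_point) / 2.0  # decay centre past the window

    if role == "endothelial":
        # high on trunk and endocardial branch; decays along the
        # mesenchymal branch once cells leave the EMP window
        level = np.full_like(s, _PANEL_HI)
        decay = 1.0 - _sigmoid((s - (e_hi - 0.03)) / st)
        level[mes] = _PANEL_LO + (_PANEL_HI - _PANEL_LO) * decay[mes]
        return level
    if role == "mesenchymal":
        # sigmoidal activation entering the EMP window; stays high on the
        # mesenchymal branch, resolves quickly on the endocardial branch
        rise = _sigmoid((s - (e_lo + 0.10)) / st)
        level = _PANEL_LO + (_PANEL_HI - _PANEL_LO) * rise
        endo = branch == "endocardial"
        fall = 1.0 - _sigmoid((s - (e_hi - 0.03)) / st)
        level[endo] = _PANEL_LO + (level[endo] - _PANEL_LO) * fall[endo]
        return level
    if role == "shear_response":
        # elevated only inside the EMP window, any branch
        bump = _sigmoid((s - e_lo) / st) * (1.0 - _sigmoid((s - e_hi) / st))
        return _PANEL_LO + (_PANEL_HI - _PANEL_LO) * bump
    if role == "epicardial":
        # this lineage is endothelial-derived; the epicardial program
        # stays basal so its score axis is a negative control
        return np.full_like(s, _PANEL_LO)
    raise ValueError(f"unknown role {role!r}")


def _gene_names(config: SimConfig) -> tuple[list[str], dict[str, list[str]], pd.DataFrame]:
    prefixes = {
        "endothelial": "Endo",
        "mesenchymal": "Mes",
        "epicardial": "Epi",
        "shear_response": "Shear",
    }
    names: list[str] = []
    roles: list[str] = []
    signatures: dict[str, list[str]] = {}
    for role in PANEL_ROLES:
        panel = [f"{prefixes[role]}{i:03d}" for i in range(config.n_signature_genes_per_panel)]
        signatures[role] = panel
        names.extend(panel)
        roles.extend([role] * len(panel))
    names.append(PROGENITOR_MARKER)
    roles.append("progenitor_marker")
    for i in range(config.n_lineage_genes):
        names.append(f"Lin{i:03d}")
        roles.append("lineage")
    names.extend(DECOY_GENES)
    roles.extend(["decoy"] * len(DECOY_GENES))
    n_bg = config.n_genes - len(names)
    names.extend(f"Bg{i:03d}" for i in range(n_bg))
    roles.extend(["background"] * n_bg)
    var = pd.DataFrame({"role": roles}, index=pd.Index(names, name="gene_id"))
    return names, signatures, var


def simulate_counts(latent: pd.DataFrame, config: SimConfig) -> ad.AnnData:
    """Draw negative-binomial counts on top of latent states.

    Returns an :class:`~anndata.AnnData` with sparse integer counts in
    ``X``, the latent table (plus true size factors and doublet flags) in
    ``obs``, gene roles in ``var`` and the signature panels in
    ``uns["signatures"]``.  Doublets are sums of two random singlet count
    vectors and replace the tail of the cell list.
    """
    rng = np.random.default_rng([config.seed, 23, len(latent)])
    n = len(latent)
    names, signatures, var = _gene_names(config)
    s = latent["s"].to_numpy()
    branch = np.asarray(latent["branch"].astype(str))

    intensity = np.empty((n, config.n_genes))
    col = 0
    for role in PANEL_ROLES:
        level = _program_intensity(role, s, branch, config)
        for _ in range(config.n_signature_genes_per_panel):
            intensity[:, col] = level
            col += 1
    # progenitor marker: high only at the start of the trunk
    st = config.program_steepness
    intensity[:, col] = _PANEL_LO + (_PANEL_HI - _PANEL_LO) * (
        1.0 - _sigmoid((s - 0.12) / st)
    )
    col += 1
    # hidden lineage genes: shared smooth programs in s at modest
    # amplitude, plus strong branch-specific terminal activation programs
    # so each terminus has a distinct identity (as differentiated states
    # do) rather than reverting to the progenitor profile
    for _ in range(config.n_lineage_genes):
        affinity = rng.choice(["progenitor", "both", "mesenchymal", "endocardial"])
        if affinity == "progenitor":
            # early endothelial-progenitor program, off by mid-trunk
            centre = rng.uniform(0.15, 0.35)
            curve = 1.0 - _sigmoid((s - centre) / st)
            level = _PANEL_LO + (_PANEL_HI - _PANEL_LO) * curve
        elif affinity == "both":
            centre = rng.uniform(0.1, 0.9)
            sign = rng.choice([-1.0, 1.0])
            curve = _sigmoid(sign * (s - centre) / (2 * st))
            level = _LINEAGE_LO + (_LINEAGE_HI - _LINEAGE_LO) * curve
        else:
            # terminal identity programs activate right after the hybrid
            # window resolves: inside the window the two branches stay
            # transcriptionally identical, but neither branch retraces
            # the progenitor profile on exit
            centre = rng.uniform(config.emp_window[1] - 0.02, config.emp_window[1] + 0.10)
            curve = _sigmoid((s - centre) / st)
            curve[branch == ("endocardial" if affinity == "mesenchymal" else "mesenchymal")] = 0.0
            level = _PANEL_LO + (_PANEL_HI - _PANEL_LO) * curve
        intensity[:, col] = level
        col += 1
    # decoys and flat background
    n_rest = config.n_genes - col
    base = rng.uniform(0.2, 1.2, size=n_rest)
    intensity[:, col:] = base[None, :]

    # library sizes: lognormal with the requested CV, mean-1 size factors
    if config.library_size_cv > 0:
        sigma2 = np.log1p(config.library_size_cv**2)
        raw = rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size=n)
    else:
        raw = np.ones(n)
    size_factor = raw / raw.mean()
    lib = config.mean_library_size * size_factor

    rel = intensity / intensity.sum(axis=1, keepdims=True)
    mu = rel * lib[:, None]
    # NB via gamma-Poisson; dispersion r: var = mu + mu^2 / r
    r = config.nb_dispersion
    shape = rng.gamma(r, 1.0 / r, size=mu.shape)
    counts = rng.poisson(mu * shape).astype(np.int64)

    obs = latent.copy()
    obs["size_factor_true"] = size_factor

    n_doublets = int(round(config.doublet_rate * n))
    if n_doublets > 0:
        n_singlets = n - n_doublets
        if n_singlets < 2:
            raise ValueError("doublet_rate leaves fewer than two singlets")
        pa = rng.integers(0, n_singlets, size=n_doublets)
        pb = rng.integers(0, n_singlets, size=n_doublets)
        counts[n_singlets:] = counts[pa] + counts[pb]
        obs = obs.iloc[: n].copy()
        obs.iloc[n_singlets:, obs.columns.get_loc("is_doublet")] = True
        # latent annotations of a doublet follow its first parent
        for colname in ("s", "branch", "timepoint", "is_emp"):
            obs.iloc[n_singlets:, obs.columns.get_loc(colname)] = (
                obs.iloc[pa, obs.columns.get_loc(colname)].to_numpy()
            )
        obs["doublet_partner_branch"] = ""
        obs.iloc[n_singlets:, obs.columns.get_loc("doublet_partner_branch")] = (
            obs.iloc[pb, obs.columns.get_loc("branch")].astype(str).to_numpy()
        )

    adata = ad.AnnData(X=sp.csr_matrix(counts), obs=obs, var=var)
    adata.uns["signatures"] = signatures
    adata.uns["sim_condition"] = str(obs["condition"].iloc[0]) if n else "control"
    return adata


def simulate_dataset(config: SimConfig, condition: str = "control") -> ad.AnnData:
    """Convenience: latent draw + counts for one condition."""
    return simulate_counts(simulate_latent(config, condition), config)


def simulate_pair(config: SimConfig) -> dict[str, ad.AnnData]:
    """Simulate both conditions with the shared seed."""
    return {cond: simulate_dataset(config, cond) for cond in CONDITIONS}


def planted_thresholds(config: SimConfig) -> dict[str, float]:
    """Signature-score thresholds at the planted program midpoints.

    The midpoint is taken in log2 space between the expected
    log-normalized expression at the program's on and off intensity
    levels, using the configured mean library size.  These are the
    `fixed`-strategy thresholds a planted-truth evaluation uses; they do
    not depend on any realized draw.
    """
    # expected relative intensity share of one gene at level v given the
    # average total intensity of a mid-trajectory cell
    n_panel = len(PANEL_ROLES) * config.n_signature_genes_per_panel
    n_named = n_panel + 1 + config.n_lineage_genes + len(DECOY_GENES)
    n_bg = config.n_genes - n_named
    # rough expected total intensity: half the panel genes on, lineage and
    # background at their mean levels
    total = (
        n_panel * (_PANEL_HI + _PANEL_LO) / 2.0
        + (1 + config.n_lineage_genes) * (_LINEAGE_LO + _LINEAGE_HI) / 2.0
        + (n_bg + len(DECOY_GENES)) * 0.7
    )
    lib = config.mean_library_size

    def lognorm(level: float) -> float:
        return float(np.log2(1.0 + lib * level / total))

    mid = (lognorm(_PANEL_HI) + lognorm(_PANEL_LO)) / 2.0
    return {role: mid for role in PANEL_ROLES}


def simulate_ligand_prior(
    response_genes: list[str],
    background_genes: list[str],
    n_decoys: int = 20,
    noise_sd: float = 0.2,
    seed: int = 0,
    driver_name: str = "DriverL",
):
    """Build a synthetic ligand→target regulatory-potential prior.

    One planted driver ligand has potential = response-membership
    indicator + half-normal noise of scale ``noise_sd``; the decoy
    ligands have pure half-normal potentials.  Returns a
    :class:`~emtscape.ligands.LigandPrior`.
    """
    from .ligands import LigandPrior

    rng = np.random.default_rng([seed, 47])
    targets = list(response_genes) + list(background_genes)
    indicator = np.concatenate(
        [np.ones(len(response_genes)), np.zeros(len(background_genes))]
    )
    rows = [np.clip(indicator + rng.normal(0.0, noise_sd, len(targets)), 0.0, None)]
    ligands = [driver_name]
    for i in range(n_decoys):
        rows.append(np.abs(rng.normal(0.0, noise_sd, len(targets))))
        ligands.append(f"Decoy{i:02d}")
    potential = pd.DataFrame(np.vstack(rows), index=ligands, columns=targets)
    return LigandPrior(potential=potential, receptor_map={})
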