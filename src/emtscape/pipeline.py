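"""Pipeline orchestration: simulate → qc → cluster → score → trajectory
→ markers → ligands from one YAML config, with seeding, structured
logging and a provenance manifest.

Each stage writes plain-text artifacts into the output directory; a
stage absent from ``stages`` is skipped, and a later stage that needs a
skipped stage's artifacts resumes from disk when they exist, otherwise
fails naming the stage to run.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.decomposition import PCA

from . import graph as graph_mod
from . import io as io_mod
from . import ligands as ligands_mod
from . import markers as markers_mod
from . import qc as qc_mod
from . import signatures as sig_mod
from . import sim as sim_mod
from . import trajectory as traj_mod

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline"]

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "qc", "cluster", "score", "trajectory", "markers", "ligands")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": list(ALL_STAGES),
    # default synthetic world: the stalled condition carries the
    # four-fold hybrid-window enrichment the pipeline is built to detect
    "sim": {"emp_enrichment_factor": 4.0},
    "qc": {"min_genes": 50, "max_mito": 0.20},
    "hvg": {"n_top": 100},
    "graph": {"k": 30, "n_pcs": 15, "k_mnn": 20, "resolution": 1.0},
    "score": {
        "strategy": "otsu",
        "percentile": 75.0,
        "epithelial_role": "endothelial",
        "n_boot": 1000,
    },
    "trajectory": {
        "k": 30,
        "n_components": 10,
        "start_marker": sim_mod.PROGENITOR_MARKER,
    },
    "markers": {"logfc_min": 0.25, "frac_min": 0.25, "q_max": 0.05},
    "ligands": {
        "expr_frac_min": 0.10,
        "n_decoys": 20,
        "noise_sd": 0.2,
        "background_frac_min": 0.10,
    },
}

_RANGE_CHECKS = {
    ("qc", "min_genes"): lambda v: v >= 0,
    ("qc", "max_mito"): lambda v: 0.0 <= v <= 1.0,
    ("hvg", "n_top"): lambda v: v >= 1,
    ("graph", "k"): lambda v: v >= 1,
    ("graph", "n_pcs"): lambda v: v >= 1,
    ("graph", "k_mnn"): lambda v: v >= 1,
    ("graph", "resolution"): lambda v: v > 0,
    ("score", "percentile"): lambda v: 0.0 <= v <= 100.0,
    ("score", "n_boot"): lambda v: v >= 1,
    ("trajectory", "k"): lambda v: v >= 1,
    ("trajectory", "n_components"): lambda v: v >= 1,
    ("markers", "logfc_min"): lambda v: v >= 0,
    ("markers", "frac_min"): lambda v: 0.0 <= v <= 1.0,
    ("markers", "q_max"): lambda v: 0.0 < v <= 1.0,
    ("ligands", "expr_frac_min"): lambda v: 0.0 <= v <= 1.0,
    ("ligands", "n_decoys"): lambda v: v >= 1,
    ("ligands", "noise_sd"): lambda v: v > 0,
    ("ligands", "background_frac_min"): lambda v: 0.0 <= v <= 1.0,
}


def validate_config(config) -> dict:
    """Validate a config mapping or YAML path; fill defaults.

    Unknown keys and out-of-range values raise ValueError listing the
    offending keys.  An empty file yields the defaults-only config.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping")
    merged = copy.deepcopy(DEFAULT_CONFIG)
    errors = []
    sim_fields = {f.name for f in sim_mod.SimConfig.__dataclass_fields__.values()}
    for key, value in config.items():
        if key not in merged:
            errors.append(f"unknown key: {key}")
            continue
        if key in ("seed",):
            merged[key] = int(value)
        elif key == "stages":
            bad = [s for s in value if s not in ALL_STAGES]
            if bad:
                errors.append(f"unknown stages: {bad}")
            else:
                merged[key] = list(value)
        elif key == "sim":
            bad = [k for k in value if k not in sim_fields or k == "seed"]
            if bad:
                errors.append(f"unknown sim keys: {bad}")
            else:
                merged[key] = dict(value)
        else:
            for sub, sub_value in value.items():
                if sub not in merged[key]:
                    errors.append(f"unknown key: {key}.{sub}")
                else:
                    merged[key][sub] = sub_value
    if not errors:
        for (section, key), check in _RANGE_CHECKS.items():
            value = merged[section][key]
            if not check(value):
                errors.append(f"out-of-range value: {section}.{key}={value!r}")
        if merged["score"]["strategy"] not in ("percentile", "otsu", "fixed"):
            errors.append(f"unknown score.strategy: {merged['score']['strategy']!r}")
        try:
            sim_mod.SimConfig(seed=merged["seed"], **merged["sim"])
        except (ValueError, TypeError) as exc:
            errors.append(f"sim: {exc}")
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    return merged


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(manifest, name, t0, **info):
    entry = {"stage": name, "elapsed_s": round(time.perf_counter() - t0, 3), **info}
    manifest["stages"].append(entry)
    logger.info("stage %s done in %.2fs %s", name, entry["elapsed_s"], info)


def run_pipeline(config, out_dir) -> dict:
    """Run the configured stages; returns the manifest (also written to
    ``manifest.json`` in the output directory)."""
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = cfg["stages"]
    seed = cfg["seed"]
    sim_config = sim_mod.SimConfig(seed=seed, **cfg["sim"])

    manifest: dict = {
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": seed,
        "package_version": _version(),
        "started_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": [],
        "outputs": {},
    }

    datasets: dict[str, object] = {}

    if "simulate" in stages:
        t0 = time.perf_counter()
        datasets = sim_mod.simulate_pair(sim_config)
        for cond, adata in datasets.items():
            io_mod.write_dataset(adata, out / f"sim_{cond}")
        _stage(
            manifest, "simulate", t0,
            n_cells={c: int(a.n_obs) for c, a in datasets.items()},
            n_genes=sim_config.n_genes,
        )
    else:
        for cond in sim_mod.CONDITIONS:
            path = out / f"sim_{cond}"
            if (path / "matrix.mtx").exists():
                datasets[cond] = io_mod.read_dataset(path)
        if not datasets and set(stages) & set(ALL_STAGES[1:]):
            raise ValueError("no simulated data found; run the 'simulate' stage first")

    thresholds = qc_mod.QCThresholds(
        min_genes=cfg["qc"]["min_genes"], max_mito_fraction=cfg["qc"]["max_mito"]
    )
    if "qc" in stages:
        t0 = time.perf_counter()
        kept = {}
        reports = []
        for cond, adata in datasets.items():
            filtered, report = qc_mod.filter_cells(adata, thresholds)
            qc_mod.log_normalize(filtered)
            report["condition"] = cond
            reports.append(report)
            kept[cond] = filtered
        pd.concat(reports).to_csv(out / "qc_report.csv")
        datasets = kept
        _stage(
            manifest, "qc", t0,
            n_cells_kept={c: int(a.n_obs) for c, a in datasets.items()},
        )
    elif set(stages) & {"cluster", "score", "trajectory", "markers", "ligands"}:
        raise ValueError("downstream stages need the 'qc' stage (log-normalization)")

    control = datasets.get("control")

    embedding = None
    if "cluster" in stages:
        t0 = time.perf_counter()
        hvg = qc_mod.select_hvgs(control, n_top=min(cfg["hvg"]["n_top"], control.n_vars - 10))
        idx = pd.Index(control.var_names).get_indexer(hvg.index)
        values = np.asarray(control.layers["lognorm"])[:, idx]
        n_pcs = min(cfg["graph"]["n_pcs"], values.shape[1] - 1, control.n_obs - 1)
        embedding = PCA(n_components=n_pcs, random_state=0).fit_transform(values)
        g = graph_mod.build_graph(
            embedding,
            k=cfg["graph"]["k"],
            timepoints=control.obs["timepoint"].to_numpy(),
            timepoint_order=[w[0] for w in sim_config.timepoint_windows],
            k_mnn=cfg["graph"]["k_mnn"],
        )
        labels = graph_mod.cluster_graph(g, resolution=cfg["graph"]["resolution"], seed=seed)
        control.obs["cluster"] = pd.Categorical(labels.astype(str))
        pd.DataFrame(
            g.edge_list(), columns=["i", "j", "jaccard", "distance"]
        ).to_csv(out / "graph_edges.tsv", sep="\t", index=False)
        control.obs[["cluster"]].to_csv(out / "clusters.csv")
        _stage(manifest, "cluster", t0, n_clusters=int(labels.max() + 1))
    else:
        g = None

    if "score" in stages:
        t0 = time.perf_counter()
        sigs = control.uns["signatures"]
        scored = {
            cond: sig_mod.score_signatures(adata, sigs) for cond, adata in datasets.items()
        }
        # thresholds fit on the pooled score distribution, applied to both
        pooled = sig_mod.ProfileScores(
            scores=pd.concat([scored[c].scores for c in scored])
        )
        strategy = cfg["score"]["strategy"]
        fixed = None
        if strategy == "fixed":
            fixed = sim_mod.planted_thresholds(sim_config)
        pooled = sig_mod.set_thresholds(
            pooled, strategy=strategy, percentile=cfg["score"]["percentile"], fixed=fixed
        )
        for cond in scored:
            scored[cond].thresholds = pooled.thresholds
            scored[cond].threshold_strategy = pooled.threshold_strategy
            scored[cond] = sig_mod.classify_emp(
                scored[cond], epithelial_role=cfg["score"]["epithelial_role"]
            )
            table = scored[cond].scores.copy()
            table["emp"] = scored[cond].emp_flag
            table.to_csv(out / f"scores_{cond}.csv")
        contrast = sig_mod.emp_contrast(
            scored["control"], scored["stalled"], n_boot=cfg["score"]["n_boot"], seed=seed
        )
        (out / "emp_contrast.json").write_text(
            json.dumps(contrast.__dict__, indent=2, default=float)
        )
        _stage(
            manifest, "score", t0,
            emp_fraction_control=contrast.fraction_a,
            emp_fraction_stalled=contrast.fraction_b,
            fold_change=contrast.fold_change,
        )

    trajectory_result = None
    if "trajectory" in stages:
        t0 = time.perf_counter()
        if embedding is None:
            raise ValueError("trajectory stage needs the 'cluster' stage embedding")
        start = traj_mod.select_start_cell(control, cfg["trajectory"]["start_marker"])
        trajectory_result = traj_mod.run_trajectory(
            embedding,
            start,
            k=cfg["trajectory"]["k"],
            n_components=cfg["trajectory"]["n_components"],
            timepoints=control.obs["timepoint"].to_numpy(),
            seed=seed,
        )
        control.obs["pseudotime"] = trajectory_result.pseudotime
        control.obs["diff_potential"] = trajectory_result.diff_potential
        for j in range(trajectory_result.branch_probs.shape[1]):
            control.obs[f"branch_prob_{j}"] = trajectory_result.branch_probs[:, j]
        traj_cols = ["pseudotime", "diff_potential"] + [
            f"branch_prob_{j}" for j in range(trajectory_result.branch_probs.shape[1])
        ]
        control.obs[traj_cols].to_csv(out / "trajectory.csv")
        _stage(
            manifest, "trajectory", t0,
            start_cell=int(trajectory_result.start_cell),
            termini=[int(t) for t in trajectory_result.termini],
        )

    marker_table = None
    if "markers" in stages:
        t0 = time.perf_counter()
        if "cluster" not in control.obs:
            raise ValueError("markers stage needs the 'cluster' stage labels")
        marker_table = markers_mod.find_markers(
            control,
            groupby="cluster",
            logfc_min=cfg["markers"]["logfc_min"],
            frac_min=cfg["markers"]["frac_min"],
            q_max=cfg["markers"]["q_max"],
        )
        marker_table.to_csv(out / "markers.csv", index=False)
        _stage(manifest, "markers", t0, n_markers=int(len(marker_table)))

    if "ligands" in stages:
        t0 = time.perf_counter()
        # receiver DE: mesenchymal-like vs endothelial-like compartments,
        # defined from the signature score axes (no planted truth used)
        sigs = control.uns["signatures"]
        sc = sig_mod.score_signatures(control, sigs).scores
        lineage = np.where(
            sc["mesenchymal"] > sc["endothelial"], "mes_like", "endo_like"
        )
        control.obs["_receiver_group"] = lineage
        de = markers_mod.find_markers(
            control, groupby="_receiver_group",
            logfc_min=cfg["markers"]["logfc_min"],
            frac_min=cfg["markers"]["frac_min"],
            q_max=cfg["markers"]["q_max"],
            return_all=True,
        )
        de_mes = de[de["group"] == "mes_like"]
        response, background = ligands_mod.define_gene_sets(
            de_mes, background_frac_min=cfg["ligands"]["background_frac_min"]
        )
        prior = sim_mod.simulate_ligand_prior(
            response,
            background,
            n_decoys=cfg["ligands"]["n_decoys"],
            noise_sd=cfg["ligands"]["noise_sd"],
            seed=seed,
        )
        activities = ligands_mod.ligand_activities(prior, response, background)
        activities = ligands_mod.top_quartile_filter(activities)
        activities.to_csv(out / "ligand_activities.csv", index=False)
        _stage(
            manifest, "ligands", t0,
            n_response=len(response), n_kept=int(activities["kept"].sum()),
        )

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][str(path.relative_to(out))] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("emtscape")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"
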