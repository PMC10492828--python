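"""Plain-text dataset I/O: Matrix Market counts, TSV gene/barcode lists,
CSV cell metadata and GMT signature sets.

The on-disk layout mirrors the common cell-by-gene sparse dump:

    matrix.mtx     cells x genes integer counts (rows = cells)
    genes.tsv      one gene identifier per line, column order of the MTX
    barcodes.tsv   one cell identifier per line, row order of the MTX
    cells.csv      per-cell metadata, indexed by cell_id
    signatures.gmt name <tab> description <tab> gene...

Writers and readers round-trip counts bit-exactly.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = ["write_dataset", "read_dataset", "write_gmt", "read_gmt"]


def write_gmt(signatures: dict[str, list[str]], path) -> None:
    """Write gene sets in GMT format (name, description, tab-joined genes)."""
    path = Path(path)
    with path.open("w") as fh:
        for name, genes in signatures.items():
            fh.write("\t".join([name, f"{len(genes)} genes", *genes]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file into an ordered name → gene-list mapping."""
    out: dict[str, list[str]] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed GMT line: {line!r}")
            out[fields[0]] = [g for g in fields[2:] if g]
    return out


def write_dataset(adata: ad.AnnData, dir_path) -> Path:
    """Write an AnnData of raw counts to a plain-text dataset directory."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    if adata.n_obs == 0:
        warnings.warn("writing an empty (0-cell) dataset", stacklevel=2)
    x = adata.X
    if not sp.issparse(x):
        x = sp.csr_matrix(x)
    x = x.astype(np.int64)
    scipy.io.mmwrite(str(dir_path / "matrix.mtx"), x)
    pd.Series(adata.var_names).to_csv(
        dir_path / "genes.tsv", sep="\t", index=False, header=False
    )
    pd.Series(adata.obs_names).to_csv(
        dir_path / "barcodes.tsv", sep="\t", index=False, header=False
    )
    adata.obs.to_csv(dir_path / "cells.csv")
    sigs = adata.uns.get("signatures")
    if sigs:
        write_gmt(sigs, dir_path / "signatures.gmt")
    return dir_path


def read_dataset(dir_path) -> ad.AnnData:
    """Read a dataset directory written by :func:`write_dataset`."""
    dir_path = Path(dir_path)
    x = sp.csr_matrix(scipy.io.mmread(str(dir_path / "matrix.mtx"))).astype(np.int64)
    genes = pd.read_csv(dir_path / "genes.tsv", sep="\t", header=None)[0].astype(str)
    barcodes_path = dir_path / "barcodes.tsv"
    if barcodes_path.stat().st_size > 0:
        barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str)
    else:
        barcodes = pd.Series([], dtype=str)
    obs = pd.read_csv(dir_path / "cells.csv", index_col=0)
    obs.index = obs.index.astype(str)
    if x.shape[0] != len(barcodes) or x.shape[1] != len(genes):
        raise ValueError(
            f"matrix shape {x.shape} does not match barcodes ({len(barcodes)}) "
            f"x genes ({len(genes)})"
        )
    adata = ad.AnnData(
        X=x,
        obs=obs.reindex(list(barcodes)),
        var=pd.DataFrame(index=pd.Index(list(genes), name="gene_id")),
    )
    gmt = dir_path / "signatures.gmt"
    if gmt.exists():
        adata.uns["signatures"] = read_gmt(gmt)
    return adata
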