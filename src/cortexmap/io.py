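"""Readers/writers for cell tables and pipeline configuration.

A cell table on disk is Matrix Market (cells x genes counts) plus
``cells.csv`` (per-cell metadata) and ``genes.tsv``; a single combined
CSV (metadata columns then gene columns) is also accepted.  Coordinates
are floating-point micrometres; counts are integers before normalization
and reals after.  Configuration is YAML with strict key checking.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

REQUIRED_OBS = ["x_um", "y_um", "volume_um3", "slice", "batch", "region"]
OPTIONAL_OBS = ["subregion", "condition", "truth_subtype", "truth_major",
                "qc_pass", "doublet_flag", "pair_id"]

__all__ = ["read_cell_table", "write_cell_table", "load_config", "save_config",
           "CONFIG_SCHEMA"]


def write_cell_table(adata: ad.AnnData, out_dir) -> None:
    """Write MTX + cells.csv + genes.tsv.

    Raw counts (``layers["counts"]`` if present, else ``X``) go to the
    matrix file in integer coordinate format when integral.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    M = np.asarray(adata.layers.get("counts", adata.X))
    S = sparse.coo_matrix(M)
    if np.all(np.mod(S.data, 1) == 0):
        S = S.astype(np.int64)
    spio.mmwrite(out / "matrix.mtx", S)
    obs = adata.obs.copy()
    obs.index.name = "cell_id"
    obs.to_csv(out / "cells.csv")
    pd.Series(adata.var_names, name="gene").to_csv(
        out / "genes.tsv", sep="\t", index=False, header=False)


def read_cell_table(path) -> ad.AnnData:
    """Read a cell table from an MTX directory or a combined CSV.

    Validates dimensional consistency (errors name the offending file),
    required metadata columns, and positive volumes.  Raw-count matrices
    must be in integer (or integral real) coordinate format.
    """
    path = Path(path)
    if path.is_dir():
        mtx = path / "matrix.mtx"
        cells = path / "cells.csv"
        genes = path / "genes.tsv"
        for f in (mtx, cells, genes):
            if not f.exists():
                raise FileNotFoundError(f"missing {f.name} in {path}")
        M = spio.mmread(mtx)
        obs = pd.read_csv(cells, index_col=0)
        gene_names = pd.read_csv(genes, sep="\t", header=None)[0].tolist()
        if M.shape[0] != len(obs):
            raise ValueError(
                f"cells.csv has {len(obs)} rows but matrix.mtx has "
                f"{M.shape[0]} rows")
        if M.shape[1] != len(gene_names):
            raise ValueError(
                f"genes.tsv has {len(gene_names)} genes but matrix.mtx has "
                f"{M.shape[1]} columns")
        X = np.asarray(M.todense() if sparse.issparse(M) else M)
        if np.any(np.mod(X, 1) != 0):
            raise ValueError("matrix.mtx: raw counts must be integers "
                             "(general real matrices are rejected)")
        X = X.astype(np.int64)
    else:
        df = pd.read_csv(path, index_col=0)
        meta_cols = [c for c in REQUIRED_OBS + OPTIONAL_OBS if c in df.columns]
        gene_cols = [c for c in df.columns if c not in meta_cols]
        obs = df[meta_cols]
        gene_names = gene_cols
        X = df[gene_cols].to_numpy()
    missing = [c for c in REQUIRED_OBS if c not in obs.columns]
    if missing:
        raise ValueError(f"cells metadata missing required columns: {missing}")
    if np.any(obs["volume_um3"].to_numpy() <= 0):
        raise ValueError("volume_um3 must be positive")
    adata = ad.AnnData(
        X=X, obs=obs,
        var=pd.DataFrame(index=pd.Index(gene_names, name="gene")))
    adata.layers["counts"] = np.asarray(adata.X).copy()
    return adata


#: allowed keys per stage block (strict schema)
CONFIG_SCHEMA = {
    "global": {"seed", "out_dir", "log_level"},
    "simulate": {"n_slices", "n_cells_per_slice", "n_surface_cells_per_slice",
                 "pfc_fraction", "width_um", "seed"},
    "codebook": {"n_bits", "weight", "min_distance", "n_codewords_requested",
                 "seed", "n_restarts", "n_improve"},
    "qc": {"volume_min", "volume_max", "counts_min", "counts_quantile_max",
           "features_min", "norm_target", "doublets"},
    "cluster": {"k_round1", "resolution_round1", "k_round2",
                "resolution_round2", "n_shuffles", "seed"},
    "integrate": {"n_pcs", "k", "gamma", "cost", "train_fraction", "seed"},
    "spatial": {"k", "n_shuffles", "alpha", "fc_min", "seed"},
    "pain": {"arg_suppression", "n_pairs", "n_subsample", "seed"},
}


def load_config(path) -> dict:
    """Load and validate a pipeline YAML config (unknown keys rejected)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    unknown_stages = set(cfg) - set(CONFIG_SCHEMA)
    if unknown_stages:
        raise ValueError(f"unknown config sections: {sorted(unknown_stages)}")
    for stage, block in cfg.items():
        if block is None:
            cfg[stage] = {}
            continue
        bad = set(block) - CONFIG_SCHEMA[stage]
        if bad:
            raise ValueError(f"unknown keys in [{stage}]: {sorted(bad)}")
    return cfg


def save_config(cfg: dict, path) -> None:
    validate_config(cfg)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
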