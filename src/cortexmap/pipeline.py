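"""Stage orchestration: run the pipeline end to end with a manifest.

Stages (in dependency order): simulate -> qc -> cluster -> spatial ->
pain, plus the independent codebook stage.  Each stage writes its
declared files under the output directory and appends a manifest record
(stage, parameters, input/output hashes, seed, runtime) so a rerun with
the same seed reproduces identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as cl
from . import codebook as cbk
from . import io as cio
from . import pain as pn
from . import qc as qcm
from . import spatial as sp
from . import synthetic as syn

STAGE_ORDER = ["simulate", "codebook", "qc", "cluster", "spatial", "pain"]
DEPENDS = {
    "simulate": [],
    "codebook": [],
    "qc": ["simulate"],
    "cluster": ["qc"],
    "spatial": ["cluster"],
    "pain": ["simulate"],
}

__all__ = ["run_pipeline", "STAGE_ORDER"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_simulate(cfg, out, seed):
    block = cfg.get("simulate", {})
    tc = syn.default_tissue_config(seed=block.get("seed", seed),
                                   **{k: v for k, v in block.items()
                                      if k != "seed"})
    adata = syn.generate_tissue(tc)
    cio.write_cell_table(adata, out / "tissue")
    return [out / "tissue" / f for f in ("matrix.mtx", "cells.csv", "genes.tsv")]


def _stage_codebook(cfg, out, seed):
    block = dict(cfg.get("codebook", {}))
    block.setdefault("seed", seed)
    cb = cbk.build_codebook(**block)
    n_genes = max(len(cb) - 60, 1)
    cb = cbk.assign_genes(cb, [f"gene{i:03d}" for i in range(n_genes)],
                          seed=block["seed"])
    cbk.write_codebook_csv(cb, out / "codebook.csv")
    return [out / "codebook.csv"]


def _stage_qc(cfg, out, seed):
    tissue_dir = out / "tissue"
    if not tissue_dir.exists():
        raise FileNotFoundError("missing tissue/ output; run 'simulate' first")
    adata = cio.read_cell_table(tissue_dir)
    block = cfg.get("qc", {})
    params = qcm.QCParams(**{k: v for k, v in block.items() if k != "doublets"})
    qcm.qc_pipeline(adata, params, doublets=block.get("doublets", True),
                    seed=seed)
    cio.write_cell_table(adata, out / "qc")
    np.save(out / "qc" / "lognorm.npy", np.asarray(adata.X))
    return [out / "qc" / f for f in ("matrix.mtx", "cells.csv", "genes.tsv")]


def _cluster_params(cfg, seed):
    block = cfg.get("cluster", {})
    tc = syn.default_tissue_config()
    marker_sets = {mc: tuple(g) for mc, g in tc.class_markers.items()}
    kwargs = dict(marker_sets=marker_sets, seed=block.get("seed", seed))
    for key in ("k_round1", "resolution_round1", "resolution_round2",
                "n_shuffles"):
        if key in block:
            kwargs[key] = block[key]
    if "k_round2" in block:
        kwargs["k_round2"] = dict(block["k_round2"])
    return cl.ClusterParams(**kwargs)


def _stage_cluster(cfg, out, seed):
    qc_dir = out / "qc"
    if not qc_dir.exists():
        raise FileNotFoundError("missing qc/ output; run 'qc' first")
    adata = cio.read_cell_table(qc_dir)
    lognorm = out / "qc" / "lognorm.npy"
    if lognorm.exists():
        adata.X = np.load(lognorm)
    assignment = cl.two_round_clustering(adata, _cluster_params(cfg, seed))
    labels = assignment.labels
    labels.to_csv(out / "labels.csv")
    return [out / "labels.csv"]


def _stage_spatial(cfg, out, seed):
    for req, stage in ((out / "labels.csv", "cluster"), (out / "qc", "qc")):
        if not req.exists():
            raise FileNotFoundError(f"missing {req.name}; run '{stage}' first")
    block = cfg.get("spatial", {})
    adata = cio.read_cell_table(out / "qc")
    lognorm = out / "qc" / "lognorm.npy"
    norm = np.expm1(np.load(lognorm)) if lognorm.exists() else np.asarray(adata.X)
    labels = pd.read_csv(out / "labels.csv", index_col=0)
    obs = adata.obs.loc[labels.index]
    surface = obs["truth_subtype"] == "VLMC" if "truth_subtype" in obs else None
    files = []
    # depth from the surface monolayer
    if surface is not None and surface.sum() >= 2:
        surfaces = {}
        for s in obs["slice"].unique():
            pts = obs.loc[surface & (obs["slice"] == s), ["x_um", "y_um"]]
            if len(pts) >= 2:
                surfaces[s] = sp.fit_surface_line(pts.to_numpy())
        ok = obs["slice"].isin(list(surfaces))
        depth = sp.cortical_depth(obs.loc[ok, ["x_um", "y_um"]].to_numpy(),
                                  obs.loc[ok, "slice"].to_numpy(), surfaces)
        depth.index = obs.index[ok]
        depth.to_csv(out / "depth.csv")
        files.append(out / "depth.csv")
    neuronal = labels["major_class"].isin(["excitatory", "inhibitory"])
    enr = sp.region_enrichment(labels.loc[neuronal, "subtype"],
                               obs.loc[neuronal, "region"],
                               obs.loc[neuronal, "slice"])
    enr.to_csv(out / "enrichment.csv")
    files.append(out / "enrichment.csv")
    pos = [adata.obs.index.get_loc(i) for i in labels.index]
    deg = sp.region_deg(norm[pos], list(adata.var_names),
                        obs["region"].to_numpy(),
                        alpha=block.get("alpha", 0.01),
                        fc_min=block.get("fc_min", 1.2))
    deg.to_csv(out / "deg_region.tsv", sep="\t", index=False)
    files.append(out / "deg_region.tsv")
    score, sets = sp.signature_score(norm[pos], list(adata.var_names), deg)
    pd.DataFrame({"signature": score}, index=labels.index).to_csv(
        out / "signature.csv")
    files.append(out / "signature.csv")
    prox = sp.proximity_by_region(
        obs[["x_um", "y_um"]].to_numpy(), labels["subtype"].to_numpy(),
        obs["slice"].to_numpy(), obs["region"].to_numpy(),
        k=block.get("k", 30), n_shuffles=block.get("n_shuffles", 100),
        seed=block.get("seed", seed))
    for r, res in prox.items():
        res.enrichment.to_csv(out / f"proximity_{r}.csv")
        files.append(out / f"proximity_{r}.csv")
    return files


def _stage_pain(cfg, out, seed):
    block = cfg.get("pain", {})
    tc = syn.default_tissue_config(seed=block.get("seed", seed))
    pc = syn.PainConfig(arg_suppression=block.get("arg_suppression", 0.5),
                        n_pairs=block.get("n_pairs", 3),
                        planted_degs={"L5_ET_1": {"Gria1": 1.8, "Kcnn3": 0.5}},
                        seed=block.get("seed", seed))
    import anndata as ad
    sham, sni = syn.generate_pain_pair(tc, pc)
    both = ad.concat([sham, sni], index_unique=None)
    qcm.qc_pipeline(both, doublets=False, seed=seed)
    use = both.obs["qc_pass"].to_numpy()
    Xlog = np.asarray(both.X)[use]
    genes = list(both.var_names)
    scores = pn.arg_score(Xlog, genes)
    pd.DataFrame({"arg_score": scores}, index=both.obs.index[use]).to_csv(
        out / "arg_scores.csv")
    tests = pn.compare_arg_paired(scores, both.obs["truth_subtype"][use],
                                  both.obs["condition"][use],
                                  both.obs["pair_id"][use])
    tests.to_csv(out / "arg_subtype_tests.csv")
    pert = pn.perturbation_score(Xlog, both.obs["truth_subtype"][use],
                                 both.obs["condition"][use],
                                 n_subsample=block.get("n_subsample", 100),
                                 seed=seed)
    pert.to_csv(out / "perturbation.csv")
    rows = []
    for st in pc.affected_subtypes:
        mask = (both.obs["truth_subtype"][use] == st).to_numpy()
        deg = pn.lrt_deg(Xlog[mask], genes,
                         both.obs["condition"][use][mask],
                         both.obs["pair_id"][use][mask])
        deg.insert(0, "subtype", st)
        rows.append(deg)
    pd.concat(rows).to_csv(out / "deg_pain.tsv", sep="\t", index=False)
    return [out / f for f in ("arg_scores.csv", "arg_subtype_tests.csv",
                              "perturbation.csv", "deg_pain.tsv")]


_STAGE_FN = {
    "simulate": _stage_simulate,
    "codebook": _stage_codebook,
    "qc": _stage_qc,
    "cluster": _stage_cluster,
    "spatial": _stage_spatial,
    "pain": _stage_pain,
}


def run_pipeline(config: dict, out_dir, stages=None, seed: int | None = None):
    """Execute the requested stages in dependency order.

    ``stages`` defaults to the full pipeline.  Raises if a requested
    stage's upstream output is missing, naming the stage to run first.
    Writes ``manifest.json`` with per-stage parameters, output hashes,
    the seed and runtimes.
    """
    cio.validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("global", {}).get("seed", 0) if seed is None else seed)
    requested = list(STAGE_ORDER) if stages is None else list(stages)
    unknown = set(requested) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    requested = [s for s in STAGE_ORDER if s in requested]
    manifest_path = out / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else []
    done = {m["stage"] for m in manifest}
    for s in requested:
        for dep in DEPENDS[s]:
            if dep not in done and dep not in requested:
                raise RuntimeError(f"stage '{s}' requires '{dep}'; run it first")
    for s in requested:
        t0 = time.time()
        outputs = _STAGE_FN[s](config, out, seed)
        manifest = [m for m in manifest if m["stage"] != s]
        manifest.append({
            "stage": s,
            "params": config.get(s, {}),
            "seed": seed,
            "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
            "runtime_s": round(time.time() - t0, 3),
        })
        done.add(s)
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return out
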