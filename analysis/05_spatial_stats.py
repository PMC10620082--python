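#!/usr/bin/env python
"""Spatial statistics: depth profiles, regional contrasts, proximity.

Fits the pial surface from the VLMC monolayer, measures normalized
cortical depth per subtype, quantifies in/out-PFC subtype enrichment
and differential expression (Wilcoxon + Bonferroni, FC > 1.2), scores
the regional signature, and computes KNN proximity enrichment with a
shuffle null, separately in and out of the region.  Writes depth.csv,
enrichment.csv, deg_region.tsv, signature.csv, proximity_{in,out}.csv
and two figures.
"""

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from cortexmap import spatial as sp
from cortexmap.io import read_cell_table

OUT = Path(__file__).resolve().parent.parent / "results"
FIG = OUT / "figures"
FIG.mkdir(parents=True, exist_ok=True)
SEED = 0

adata = read_cell_table(OUT / "qc")
norm = np.expm1(np.load(OUT / "qc" / "lognorm.npy"))
labels = pd.read_csv(OUT / "labels.csv", index_col=0)
obs = adata.obs.loc[labels.index]
pos = [adata.obs.index.get_loc(i) for i in labels.index]
norm = norm[pos]

# --- cortical depth from the VLMC surface line ---
surf = obs.truth_subtype == "VLMC"
surfaces = {s: sp.fit_surface_line(
    obs.loc[surf & (obs["slice"] == s), ["x_um", "y_um"]].to_numpy())
    for s in obs["slice"].unique()}
depth = sp.cortical_depth(obs[["x_um", "y_um"]].to_numpy(),
                          obs["slice"].to_numpy(), surfaces)
depth.index = obs.index
depth.to_csv(OUT / "depth.csv")
med = depth.groupby(obs.truth_subtype.to_numpy())["normalized_depth"].median()
print("median normalized depth per subtype (0 = pia, 1 = deepest):")
print(med.sort_values().round(3).to_string())

fig, ax = plt.subplots(figsize=(6, 3.5))
order = med.sort_values().index
ax.violinplot([depth.normalized_depth[obs.truth_subtype.to_numpy() == s]
               for s in order], showmedians=True)
ax.set_xticks(range(1, len(order) + 1), order, rotation=45, ha="right")
ax.set_ylabel("normalized cortical depth")
fig.tight_layout()
fig.savefig(FIG / "depth_by_subtype.png", dpi=150)

# --- in/out-region subtype enrichment ---
neuronal = labels.major_class.isin(["excitatory", "inhibitory"]).to_numpy()
enr = sp.region_enrichment(labels.subtype[neuronal], obs.region[neuronal],
                           obs["slice"][neuronal])
enr.to_csv(OUT / "enrichment.csv")
print("\nlog2 in/out-PFC abundance ratio per neuronal subtype:")
print(enr["log2_ratio"].round(3).to_string())

# --- regional DEGs and the signature score ---
deg = sp.region_deg(norm, list(adata.var_names), obs.region.to_numpy())
deg.to_csv(OUT / "deg_region.tsv", sep="\t", index=False)
sig_up = deg[deg.significant & (deg.fold_change > 1)]
sig_dn = deg[deg.significant & (deg.fold_change < 1)]
print(f"\nregion DEGs: {len(sig_up)} enriched, {len(sig_dn)} depleted "
      f"(adjusted P < 0.01, FC > 1.2)")
score, sets = sp.signature_score(norm, list(adata.var_names), deg)
pd.DataFrame({"signature": score}, index=obs.index).to_csv(OUT / "signature.csv")
m_in = score[(obs.region == "in").to_numpy()].mean()
m_out = score[(obs.region == "out").to_numpy()].mean()
print(f"signature (top-10 enriched minus top-10 depleted): "
      f"in-region mean {m_in:.2f}, out {m_out:.2f}")

fig, ax = plt.subplots(figsize=(5, 4))
sc = ax.scatter(obs.x_um, obs.y_um, c=score, s=3, cmap="RdBu_r")
ax.invert_yaxis()
ax.set_xlabel("x (um)")
ax.set_ylabel("depth (um)")
fig.colorbar(sc, label="regional signature")
fig.tight_layout()
fig.savefig(FIG / "signature_map.png", dpi=150)

# --- proximity enrichment, in vs out of region ---
prox = sp.proximity_by_region(obs[["x_um", "y_um"]].to_numpy(),
                              labels.subtype.to_numpy(),
                              obs["slice"].to_numpy(),
                              obs.region.to_numpy(), k=30, n_shuffles=100,
                              seed=SEED)
for r, res in prox.items():
    res.enrichment.to_csv(OUT / f"proximity_{r}.csv")
    diag = np.diag(res.enrichment.values)
    print(f"proximity ({r}-region): median within-type log2 enrichment "
          f"{np.nanmedian(diag):.2f}")
print("-> results/{depth,enrichment,signature}.csv, deg_region.tsv, "
      "proximity_{in,out}.csv, figures/")
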