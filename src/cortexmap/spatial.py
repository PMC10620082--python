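"""Spatial statistics: cortical depth, regional enrichment/DEGs,
signature scores and KNN proximity enrichment.

Cortical depth is the shortest distance from a cell centroid to the
pial-surface polyline (fit through the surface-marker monolayer),
normalized so the deepest analyzed cell is at 1.  Regional contrasts
compare the in-PFC x-interval with the adjacent tissue.  Cell-cell
proximity enrichment counts subtype co-occurrence among each cell's 30
spatial nearest neighbors against a label-shuffle null, reported as
log2(observed/expected) with Wilcoxon p-values over per-slice statistics
and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SurfaceLine", "ProximityResult",
    "fit_surface_line", "cortical_depth", "region_enrichment",
    "region_deg", "signature_score", "proximity_enrichment",
    "proximity_by_region",
]


@dataclass
class SurfaceLine:
    """x-sorted polyline through surface-marker cells of one slice."""

    vertices: np.ndarray  # (n, 2) with x strictly increasing

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.shape[0] < 2:
            raise ValueError("surface line needs >= 2 vertices")
        if np.any(np.diff(v[:, 0]) <= 0):
            raise ValueError("surface x must be strictly increasing")
        self.vertices = v


def fit_surface_line(surface_xy: np.ndarray, smooth_window: int = 5) -> SurfaceLine:
    """Connect x-sorted surface-cell centroids, moving-average smoothed in y.

    Cells sharing an x coordinate are averaged so x stays strictly
    increasing; input order is irrelevant.
    """
    xy = np.asarray(surface_xy, dtype=float)
    if xy.shape[0] < 2:
        raise ValueError("need >= 2 surface cells to fit a surface line")
    df = pd.DataFrame(xy, columns=["x", "y"]).groupby("x", as_index=False).mean()
    x = df["x"].to_numpy()
    y = df["y"].to_numpy()
    if smooth_window and smooth_window > 1 and len(y) >= smooth_window:
        y = pd.Series(y).rolling(smooth_window, center=True, min_periods=1).mean().to_numpy()
    return SurfaceLine(np.column_stack([x, y]))


def _point_polyline_distance(points: np.ndarray, line: SurfaceLine) -> np.ndarray:
    """Minimum Euclidean distance from each point to the polyline."""
    P = np.asarray(points, dtype=float)
    V = line.vertices
    A = V[:-1]          # (m, 2) segment starts
    D = V[1:] - V[:-1]  # segment vectors
    L2 = (D ** 2).sum(axis=1)
    diff = P[:, None, :] - A[None, :, :]          # (n, m, 2)
    t = np.clip((diff * D[None]).sum(-1) / L2[None], 0.0, 1.0)
    proj = A[None] + t[..., None] * D[None]
    d = np.sqrt(((P[:, None, :] - proj) ** 2).sum(-1))
    return d.min(axis=1)


def cortical_depth(cells_xy: np.ndarray, slice_ids, surfaces: dict,
                   ) -> pd.DataFrame:
    """Per-cell depth (um) and normalized depth in [0, 1].

    ``surfaces`` maps slice id -> :class:`SurfaceLine`.  Normalization
    divides by the maximum depth over the analyzed set, so the deepest
    cell is exactly 1.
    """
    cells_xy = np.asarray(cells_xy, dtype=float)
    slice_ids = np.asarray(slice_ids)
    depth = np.empty(len(cells_xy))
    for s in pd.unique(slice_ids):
        if s not in surfaces:
            raise ValueError(f"no fitted surface for slice {s!r}")
        mask = slice_ids == s
        depth[mask] = _point_polyline_distance(cells_xy[mask], surfaces[s])
    dmax = depth.max()
    return pd.DataFrame({
        "depth_um": depth,
        "normalized_depth": depth / dmax if dmax > 0 else depth,
    })


def region_enrichment(subtype_labels, region_labels, slice_labels) -> pd.DataFrame:
    """Per-subtype log2 in/out abundance ratio.

    Within each slice the subtype count is normalized by the total cell
    count of its region; per-slice normalized proportions are averaged
    across slices before the in/out ratio is taken and log2-transformed.
    Subtypes absent from one region get an infinite sentinel and a flag.
    """
    df = pd.DataFrame({"subtype": np.asarray(subtype_labels),
                       "region": np.asarray(region_labels),
                       "slice": np.asarray(slice_labels)})
    if df["region"].nunique() < 2:
        raise ValueError("both regions must be populated")
    prop = (df.groupby(["slice", "region", "subtype"], observed=True).size()
            / df.groupby(["slice", "region"], observed=True).size())
    prop = prop.rename("prop").reset_index()
    mean_prop = (prop.groupby(["region", "subtype"], observed=True)["prop"]
                 .mean().unstack("region").fillna(0.0))
    out = pd.DataFrame(index=mean_prop.index)
    out["prop_in"] = mean_prop.get("in", 0.0)
    out["prop_out"] = mean_prop.get("out", 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["log2_ratio"] = np.log2(out["prop_in"] / out["prop_out"])
    out.loc[(out["prop_in"] > 0) & (out["prop_out"] == 0), "log2_ratio"] = np.inf
    out.loc[(out["prop_in"] == 0) & (out["prop_out"] > 0), "log2_ratio"] = -np.inf
    out["infinite"] = ~np.isfinite(out["log2_ratio"])
    return out


def region_deg(X_norm: np.ndarray, genes, region_labels, alpha: float = 0.01,
               fc_min: float = 1.2) -> pd.DataFrame:
    """Per-gene in/out-PFC differential expression.

    Two-sided Wilcoxon rank-sum on normalized (non-log) expression,
    Bonferroni-corrected over all genes tested; fold change is the ratio
    of group means.  A gene is significant iff adjusted p < ``alpha`` and
    max(fc, 1/fc) > ``fc_min``.  Constant genes record p = 1.
    """
    X = np.asarray(X_norm, dtype=float)
    region = np.asarray(region_labels)
    in_mask = region == "in"
    out_mask = region == "out"
    if in_mask.sum() < 2 or out_mask.sum() < 2:
        raise ValueError("both regions need >= 2 cells")
    G = X.shape[1]
    pvals = np.ones(G)
    fcs = np.ones(G)
    for g in range(G):
        a, b = X[in_mask, g], X[out_mask, g]
        ma, mb = a.mean(), b.mean()
        fcs[g] = (ma + 1e-12) / (mb + 1e-12)
        if np.ptp(X[:, g]) == 0:
            pvals[g] = 1.0
            continue
        pvals[g] = mannwhitneyu(a, b, alternative="two-sided").pvalue
    p_adj = np.minimum(pvals * G, 1.0)  # Bonferroni
    out = pd.DataFrame({
        "gene": list(genes), "fold_change": fcs,
        "log2fc": np.log2(np.maximum(fcs, 1e-300)),
        "p": pvals, "p_adj": p_adj,
    })
    out["significant"] = (out["p_adj"] < alpha) & \
        (np.maximum(fcs, 1.0 / fcs) > fc_min)
    return out


def signature_score(X_norm: np.ndarray, genes, deg_table: pd.DataFrame,
                    n_top: int = 10) -> tuple[np.ndarray, dict]:
    """Regional signature: mean expression over the top enriched genes
    minus the mean over the top depleted genes (top 10 each by fold
    change among significant genes, ties broken by smaller p)."""
    sig = deg_table[deg_table["significant"]]
    enr = sig[sig["fold_change"] > 1].sort_values(
        ["fold_change", "p"], ascending=[False, True])
    dep = sig[sig["fold_change"] < 1].sort_values(
        ["fold_change", "p"], ascending=[True, True])
    if len(enr) < n_top or len(dep) < n_top:
        warnings.warn(f"fewer than {n_top} genes on one side; using all "
                      f"available ({len(enr)} enriched, {len(dep)} depleted)",
                      stacklevel=2)
    g_plus = list(enr["gene"].head(n_top))
    g_minus = list(dep["gene"].head(n_top))
    gi = {g: i for i, g in enumerate(genes)}
    X = np.asarray(X_norm, dtype=float)
    up = X[:, [gi[g] for g in g_plus]].mean(axis=1) if g_plus else np.zeros(len(X))
    dn = X[:, [gi[g] for g in g_minus]].mean(axis=1) if g_minus else np.zeros(len(X))
    return up - dn, {"enriched": g_plus, "depleted": g_minus}


@dataclass
class ProximityResult:
    """Colocalization enrichment over subtype pairs (one stratum)."""

    observed: pd.DataFrame      # summed neighbor counts O[a, b]
    expected: pd.DataFrame      # mean of the shuffle null
    enrichment: pd.DataFrame    # log2(O / E); NaN where E == 0
    pvals: pd.DataFrame
    qvals: pd.DataFrame         # BH over all tested pairs
    per_slice_observed: dict    # slice id -> O_s DataFrame


def _neighbor_counts(xy, labels, cls, k):
    """O[a, b] = count of b-labeled cells among k nearest neighbors of
    a-labeled cells (one slice)."""
    from sklearn.neighbors import NearestNeighbors

    n = len(xy)
    kk = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=kk + 1).fit(xy)
    _, idx = nn.kneighbors(xy)
    neigh = idx[:, 1:]  # drop self
    pos = {c: i for i, c in enumerate(cls)}
    lab_idx = np.asarray([pos[l] for l in labels])
    onehot_counts = np.zeros((n, len(cls)), dtype=np.int64)
    flat = lab_idx[neigh]
    for j in range(len(cls)):
        onehot_counts[:, j] = (flat == j).sum(axis=1)
    O = np.zeros((len(cls), len(cls)), dtype=np.int64)
    for a in range(len(cls)):
        O[a] = onehot_counts[lab_idx == a].sum(axis=0)
    return O, neigh, lab_idx


def proximity_enrichment(cells_xy: np.ndarray, labels, slice_ids, k: int = 30,
                         n_shuffles: int = 100, seed: int = 0) -> ProximityResult:
    """KNN colocalization enrichment with a label-permutation null.

    Neighbors are computed per slice (2D; slices are far apart along the
    anterior-posterior axis) and counts summed across slices.  The null
    permutes subtype labels within each slice, preserving composition.
    Per-pair p-values compare the per-slice observed counts against the
    pooled per-slice shuffled counts (two-sided Wilcoxon rank-sum),
    BH-adjusted over all pairs.
    """
    if k < 1 or n_shuffles < 1:
        raise ValueError("k and n_shuffles must be >= 1")
    xy = np.asarray(cells_xy, dtype=float)
    labels = np.asarray(labels)
    slice_ids = np.asarray(slice_ids)
    cls = sorted(pd.unique(labels))
    m = len(cls)
    rng = np.random.default_rng(seed)

    slices = pd.unique(slice_ids)
    O_slices, null_slices = {}, {}
    for s in slices:
        mask = slice_ids == s
        if mask.sum() < 2:
            continue
        O_s, neigh, lab_idx = _neighbor_counts(xy[mask], labels[mask], cls, k)
        O_slices[s] = O_s
        nulls = np.zeros((n_shuffles, m, m), dtype=np.int64)
        for t in range(n_shuffles):
            perm = rng.permutation(lab_idx)
            flat = perm[neigh]
            counts = np.zeros((len(perm), m), dtype=np.int64)
            for j in range(m):
                counts[:, j] = (flat == j).sum(axis=1)
            for a in range(m):
                nulls[t, a] = counts[perm == a].sum(axis=0)
        null_slices[s] = nulls

    O = np.sum([O_slices[s] for s in O_slices], axis=0)
    E = np.sum([null_slices[s].mean(axis=0) for s in null_slices], axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        enr = np.log2(O / E)
    enr[E == 0] = np.nan

    pv = np.full((m, m), np.nan)
    obs_stack = np.stack([O_slices[s] for s in O_slices])       # (S, m, m)
    null_stack = np.concatenate([null_slices[s] for s in null_slices])  # (S*T, m, m)
    for a in range(m):
        for b in range(m):
            o = obs_stack[:, a, b]
            nl = null_stack[:, a, b]
            if np.ptp(np.concatenate([o, nl])) == 0:
                pv[a, b] = 1.0
                continue
            pv[a, b] = mannwhitneyu(o, nl, alternative="two-sided").pvalue
    flat = pv.ravel()
    tested = ~np.isnan(flat)
    qflat = np.full_like(flat, np.nan)
    if tested.sum():
        qflat[tested] = multipletests(flat[tested], method="fdr_bh")[1]
    qv = qflat.reshape(pv.shape)

    def df(M):
        return pd.DataFrame(M, index=cls, columns=cls)

    return ProximityResult(
        observed=df(O), expected=df(E), enrichment=df(enr),
        pvals=df(pv), qvals=df(qv),
        per_slice_observed={s: df(O_slices[s]) for s in O_slices})


def proximity_by_region(cells_xy, labels, slice_ids, region_labels, k: int = 30,
                        n_shuffles: int = 100, seed: int = 0) -> dict:
    """Proximity enrichment computed separately for in- and out-region cells."""
    region = np.asarray(region_labels)
    out = {}
    for r in ("in", "out"):
        mask = region == r
        if mask.sum() < 2:
            warnings.warn(f"region {r!r} has < 2 cells; skipped", stacklevel=2)
            continue
        out[r] = proximity_enrichment(
            np.asarray(cells_xy)[mask], np.asarray(labels)[mask],
            np.asarray(slice_ids)[mask], k=k, n_shuffles=n_shuffles, seed=seed)
    return out
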