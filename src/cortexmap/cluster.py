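"""Scaling, PC selection, KNN graph, Leiden, and two-round clustering.

The component-selection rule is a parallel-analysis-style shuffle test:
every gene column of the scaled matrix is independently permuted
(breaking gene-gene covariance while preserving marginals), PCA is run
on each of 10 shuffled matrices, and only components of the real data
whose eigenvalue exceeds the mean first shuffled eigenvalue are kept.

Clustering is two-round: Leiden on a KNN graph over batch-corrected PCs
(k = 10, resolution 0.3) finds the major classes (excitatory /
inhibitory / non-neuronal, assigned by marker z-scores), then each class
is re-embedded and subclustered (k = 50/20/15, resolution 2).  Because
Leiden at resolution 2 fragments large homogeneous populations, the
round-2 communities are consolidated by graph connectivity: communities
that remain connected through an appreciable number of cross KNN edges
are merged (an automated analogue of post-hoc manual cluster curation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd

EXC, INH, NON = "excitatory", "inhibitory", "non_neuronal"

__all__ = [
    "PCSelection", "ClusterParams", "ClusterAssignment",
    "zscore_scale", "pca_embed", "select_significant_pcs", "correct_batches",
    "knn_graph", "leiden_cluster", "consolidate_clusters",
    "choose_k_bootstrap", "two_round_clustering",
]


def zscore_scale(X: np.ndarray) -> np.ndarray:
    """Center and scale each gene to mean 0, population (divide-by-n) sd 1.

    Constant genes map to all-zero columns.
    """
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)  # population convention
    sd_safe = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd_safe


def pca_embed(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Full PCA scores and eigenvalues (of the covariance, divide-by-n)."""
    Xc = X - X.mean(axis=0)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    return U * S, S ** 2 / X.shape[0]


@dataclass
class PCSelection:
    eigenvalues: np.ndarray      # descending
    shuffled_first_mean: float   # mean first eigenvalue over shuffles
    n_selected: int
    n_shuffles: int


def select_significant_pcs(scaled: np.ndarray, n_shuffles: int = 10,
                           seed: int = 0) -> PCSelection:
    """Keep PCs whose eigenvalue exceeds the mean first eigenvalue of
    column-shuffled data (10 shuffles by default)."""
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    scaled = np.asarray(scaled, dtype=float)
    if scaled.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    _, ev = pca_embed(scaled)
    rng = np.random.default_rng(seed)
    firsts = np.empty(n_shuffles)
    for t in range(n_shuffles):
        shuf = np.empty_like(scaled)
        for j in range(scaled.shape[1]):
            shuf[:, j] = scaled[rng.permutation(scaled.shape[0]), j]
        _, ev_s = pca_embed(shuf)
        firsts[t] = ev_s[0]
    lam_star = float(firsts.mean())
    return PCSelection(eigenvalues=ev, shuffled_first_mean=lam_star,
                       n_selected=int((ev > lam_star).sum()),
                       n_shuffles=n_shuffles)


def correct_batches(pcs: np.ndarray, batch_labels) -> np.ndarray:
    """Batch centering in PC space: subtract each batch's mean, re-add the
    global mean.  Identity with a single batch; batches with < 2 cells are
    left uncorrected with a warning."""
    pcs = np.asarray(pcs, dtype=float)
    batch_labels = np.asarray(batch_labels)
    out = pcs.copy()
    grand = pcs.mean(axis=0)
    for b in pd.unique(batch_labels):
        mask = batch_labels == b
        if mask.sum() < 2:
            warnings.warn(f"batch {b!r} has < 2 cells; left uncorrected",
                          stacklevel=2)
            continue
        out[mask] += grand - pcs[mask].mean(axis=0)
    return out


def knn_graph(pcs: np.ndarray, k: int) -> ig.Graph:
    """Undirected KNN graph: edge (i, j) iff j is among i's k nearest
    Euclidean neighbors or vice versa; self excluded; distance ties broken
    by lower cell index."""
    from sklearn.neighbors import NearestNeighbors

    pcs = np.asarray(pcs, dtype=float)
    n = pcs.shape[0]
    if k < 1 or k >= n:
        raise ValueError(f"k={k} out of range for {n} cells")
    extra = min(n, k + 6)  # headroom so ties straddling the cut are re-sorted
    nn = NearestNeighbors(n_neighbors=extra).fit(pcs)
    dist, idx = nn.kneighbors(pcs)
    edges = set()
    for i in range(n):
        order = np.lexsort((idx[i], np.round(dist[i], 12)))
        picked = 0
        for j in idx[i][order]:
            if j == i:
                continue
            edges.add((min(i, int(j)), max(i, int(j))))
            picked += 1
            if picked == k:
                break
    g = ig.Graph(n=n, edges=sorted(edges))
    return g


def leiden_cluster(graph: ig.Graph, resolution: float, seed: int = 0) -> np.ndarray:
    """Leiden community detection (modularity-style objective with the
    given resolution); deterministic per seed."""
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    part = leidenalg.find_partition(
        graph, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed)
    return np.asarray(part.membership)


def consolidate_clusters(labels: np.ndarray, graph: ig.Graph, k: int,
                         min_edge_fraction: float = 0.01) -> np.ndarray:
    """Merge over-fragmented communities by graph connectivity.

    Two communities are joined when the number of KNN edges between them
    exceeds ``min_edge_fraction * k * min(|a|, |b|)``; merged clusters are
    the connected components of this cluster-level adjacency.  Distinct
    well-separated populations share (essentially) no KNN edges, so the
    rule only reunites fragments of one population.
    """
    labels = np.asarray(labels)
    cls = np.unique(labels)
    if len(cls) < 2:
        return labels.copy()
    pos = {c: i for i, c in enumerate(cls)}
    sizes = {c: int((labels == c).sum()) for c in cls}
    cross = np.zeros((len(cls), len(cls)), dtype=np.int64)
    el = np.asarray(graph.get_edgelist())
    if len(el):
        a = labels[el[:, 0]]
        b = labels[el[:, 1]]
        for x, y in zip(a, b):
            if x != y:
                cross[pos[x], pos[y]] += 1
                cross[pos[y], pos[x]] += 1
    meta = ig.Graph(n=len(cls))
    meta_edges = []
    for i in range(len(cls)):
        for j in range(i + 1, len(cls)):
            thresh = min_edge_fraction * k * min(sizes[cls[i]], sizes[cls[j]])
            if cross[i, j] > thresh:
                meta_edges.append((i, j))
    meta.add_edges(meta_edges)
    comp = meta.connected_components().membership
    return np.asarray([comp[pos[c]] for c in labels])


def _pairwise_ari(labelings, index_sets):
    from sklearn.metrics import adjusted_rand_score

    aris = []
    for i in range(len(labelings)):
        for j in range(i + 1, len(labelings)):
            shared = np.intersect1d(index_sets[i], index_sets[j])
            if len(shared) < 2:
                continue
            li = pd.Series(labelings[i], index=index_sets[i]).loc[shared]
            lj = pd.Series(labelings[j], index=index_sets[j]).loc[shared]
            aris.append(adjusted_rand_score(li, lj))
    return aris


def choose_k_bootstrap(pcs: np.ndarray, candidate_ks, n_boot: int = 10,
                       seed: int = 0, resample_fraction: float = 0.8,
                       resolution: float = 1.0) -> int:
    """Pick k by bootstrap stability.

    For each candidate k, cluster ``n_boot`` resamples (80% of cells,
    without replacement) and compute the mean pairwise ARI between
    resample labelings restricted to shared cells; return the smallest
    candidate within one standard error of the maximum mean stability.
    """
    candidate_ks = sorted(set(int(k) for k in candidate_ks))
    if not candidate_ks:
        raise ValueError("need at least one candidate k")
    if len(candidate_ks) == 1:
        return candidate_ks[0]
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    pcs = np.asarray(pcs, dtype=float)
    n = pcs.shape[0]
    rng = np.random.default_rng(seed)
    m = max(int(round(resample_fraction * n)), 2)
    stats = {}
    for k in candidate_ks:
        labelings, idx_sets = [], []
        for b in range(n_boot):
            idx = np.sort(rng.choice(n, size=m, replace=False))
            g = knn_graph(pcs[idx], min(k, m - 1))
            labelings.append(leiden_cluster(g, resolution, seed=seed + b))
            idx_sets.append(idx)
        aris = _pairwise_ari(labelings, idx_sets)
        stats[k] = (float(np.mean(aris)), float(np.std(aris) / np.sqrt(len(aris))))
    best_k = max(stats, key=lambda k: stats[k][0])
    best_mean, best_se = stats[best_k]
    for k in candidate_ks:  # ascending: smallest k within 1 SE of the best
        if stats[k][0] >= best_mean - best_se:
            return k
    return best_k


@dataclass(frozen=True)
class ClusterParams:
    marker_sets: dict                    # major class -> marker gene tuple
    k_round1: int = 10
    resolution_round1: float = 0.3
    k_round2: dict = field(default_factory=lambda: {EXC: 50, INH: 20, NON: 15})
    resolution_round2: float = 2.0
    n_shuffles: int = 10
    seed: int = 0
    consolidate: bool = True
    min_edge_fraction: float = 0.01
    doublet_marker_z: float = 0.5        # round-1 doublet-cluster cut


@dataclass
class ClusterAssignment:
    """Two-level labels with the parameters that produced them.

    ``major_class``/``subtype`` are aligned to the clustered cells' obs
    index; cells in removed doublet-like clusters carry the label
    ``"removed"``.
    """

    labels: pd.DataFrame        # columns: major_class, subtype
    params: ClusterParams
    n_pcs_round1: int
    n_pcs_round2: dict


def _marker_class_scores(Z: np.ndarray, genes: list[str], marker_sets: dict,
                         cluster_labels: np.ndarray) -> pd.DataFrame:
    gi = {g: i for i, g in enumerate(genes)}
    rows = {}
    for c in np.unique(cluster_labels):
        mask = cluster_labels == c
        rows[c] = {
            mc: float(np.mean([Z[mask, gi[g]].mean() for g in ms if g in gi]))
            for mc, ms in marker_sets.items()}
    return pd.DataFrame(rows).T


def two_round_clustering(adata, params: ClusterParams) -> ClusterAssignment:
    """Major classes then subtypes, with the published per-round settings.

    Round 1 clusters all usable cells and maps each cluster to the major
    class whose marker set scores highest (mean z-score); clusters
    scoring above ``doublet_marker_z`` for two or more marker sets are
    removed as doublet-like.  Round 2 re-embeds each major class and
    subclusters it; classes with fewer cells than k skip subclustering
    with a warning.
    """
    use = np.ones(adata.n_obs, bool)
    if "qc_pass" in adata.obs:
        use &= adata.obs["qc_pass"].to_numpy()
    if "doublet_flag" in adata.obs:
        use &= ~adata.obs["doublet_flag"].to_numpy()
    X = np.asarray(adata.X, dtype=float)[use]
    genes = list(adata.var_names)
    batches = adata.obs["batch"].to_numpy()[use] if "batch" in adata.obs \
        else np.zeros(use.sum())

    Z = zscore_scale(X)
    sel1 = select_significant_pcs(Z, params.n_shuffles, seed=params.seed)
    scores, _ = pca_embed(Z)
    P = scores[:, :max(sel1.n_selected, 2)]
    P = correct_batches(P, batches)
    g1 = knn_graph(P, params.k_round1)
    lab1 = leiden_cluster(g1, params.resolution_round1, seed=params.seed)
    if params.consolidate:
        lab1 = consolidate_clusters(lab1, g1, params.k_round1,
                                    params.min_edge_fraction)

    cls_scores = _marker_class_scores(Z, genes, params.marker_sets, lab1)
    major = np.empty(len(lab1), dtype=object)
    removed_clusters = []
    for c in np.unique(lab1):
        row = cls_scores.loc[c]
        if (row > params.doublet_marker_z).sum() >= 2:
            removed_clusters.append(c)
            major[lab1 == c] = "removed"
        else:
            major[lab1 == c] = row.idxmax()

    subtype = np.empty(len(lab1), dtype=object)
    subtype[major == "removed"] = "removed"
    n_pcs_round2 = {}
    for mc in params.marker_sets:
        mask = major == mc
        n_mc = int(mask.sum())
        k2 = params.k_round2.get(mc, 15)
        if n_mc == 0:
            continue
        if n_mc <= k2:
            warnings.warn(f"major class {mc}: {n_mc} cells <= k={k2}; "
                          "skipping subclustering", stacklevel=2)
            subtype[mask] = f"{mc}_0"
            n_pcs_round2[mc] = 0
            continue
        Zm = zscore_scale(X[mask])
        selm = select_significant_pcs(Zm, params.n_shuffles, seed=params.seed)
        scm, _ = pca_embed(Zm)
        Pm = scm[:, :max(selm.n_selected, 2)]
        Pm = correct_batches(Pm, batches[mask])
        gm = knn_graph(Pm, k2)
        labm = leiden_cluster(gm, params.resolution_round2, seed=params.seed)
        if params.consolidate:
            labm = consolidate_clusters(labm, gm, k2, params.min_edge_fraction)
        n_pcs_round2[mc] = selm.n_selected
        for c in np.unique(labm):
            subtype[np.where(mask)[0][labm == c]] = f"{mc}_{c}"

    labels = pd.DataFrame({"major_class": major, "subtype": subtype},
                          index=adata.obs.index[use])
    return ClusterAssignment(labels=labels, params=params,
                             n_pcs_round1=sel1.n_selected,
                             n_pcs_round2=n_pcs_round2)
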