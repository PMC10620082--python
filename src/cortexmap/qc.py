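"""Cell-level quality control, normalization and log transform.

Filters follow the published MERFISH preprocessing: segmented cells with
body volume outside [100, 4000] um^3, total counts below 10 or above the
98% quantile of the run, or fewer than 10 detected genes are removed;
survivors are scaled so each cell's total equals a fixed target (500)
and then log(1+x)-transformed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np

from .cluster import zscore_scale

__all__ = ["QCParams", "filter_cells", "normalize_counts", "log_transform",
           "flag_doublets", "qc_pipeline"]


@dataclass(frozen=True)
class QCParams:
    volume_min: float = 100.0
    volume_max: float = 4000.0
    counts_min: float = 10.0
    counts_quantile_max: float = 0.98
    features_min: int = 10
    norm_target: float = 500.0
    # the quantile filter is unstable at toy sizes; disable below this n
    quantile_min_cells: int = 50

    def __post_init__(self):
        if self.volume_min >= self.volume_max:
            raise ValueError("volume_min must be < volume_max")
        if not (0 < self.counts_quantile_max <= 1):
            raise ValueError("counts_quantile_max must be in (0, 1]")


def filter_cells(adata: ad.AnnData, params: QCParams = QCParams(),
                 frozen_quantile: float | None = None) -> ad.AnnData:
    """Set ``obs["qc_pass"]`` per the volume/counts/features rules.

    The high-count threshold is the linear-interpolation sample quantile
    of total counts over *all* cells of the run, computed once and frozen
    (pass ``frozen_quantile`` to reuse a previously computed value, which
    makes refiltering idempotent).  With fewer than
    ``params.quantile_min_cells`` cells the quantile rule is disabled.
    """
    if "volume_um3" not in adata.obs:
        raise ValueError("missing required obs column: volume_um3")
    counts = np.asarray(adata.layers.get("counts", adata.X))
    total = counts.sum(axis=1)
    n_features = (counts > 0).sum(axis=1)
    volume = adata.obs["volume_um3"].to_numpy()

    ok = (volume >= params.volume_min) & (volume <= params.volume_max)
    ok &= total >= params.counts_min
    if frozen_quantile is not None:
        hi = frozen_quantile
    elif adata.n_obs >= params.quantile_min_cells:
        hi = float(np.quantile(total, params.counts_quantile_max))
    else:
        hi = None
    if hi is not None:
        ok &= total <= hi
        adata.uns["qc_counts_quantile"] = hi
    ok &= n_features >= params.features_min

    adata.obs["qc_pass"] = ok
    adata.uns["qc_removed"] = {
        "volume": int(((volume < params.volume_min) | (volume > params.volume_max)).sum()),
        "counts_low": int((total < params.counts_min).sum()),
        "counts_high": 0 if hi is None else int((total > hi).sum()),
        "features": int((n_features < params.features_min).sum()),
        "total_removed": int((~ok).sum()),
    }
    return adata


def normalize_counts(adata: ad.AnnData, norm_target: float = 500.0) -> ad.AnnData:
    """Scale each qc-passing cell so its total equals ``norm_target``.

    Failing cells keep raw counts and are excluded downstream; the raw
    matrix is preserved in ``layers["counts"]``.
    """
    if "counts" not in adata.layers:
        adata.layers["counts"] = np.asarray(adata.X).copy()
    counts = np.asarray(adata.layers["counts"], dtype=float)
    qc = adata.obs["qc_pass"].to_numpy() if "qc_pass" in adata.obs \
        else np.ones(adata.n_obs, bool)
    total = counts.sum(axis=1)
    if np.any(qc & (total <= 0)):
        raise ValueError("zero-total cell passed QC; filter first")
    X = counts.copy()
    scale = np.where(qc & (total > 0), norm_target / np.maximum(total, 1e-300), 1.0)
    X *= scale[:, None]
    adata.X = X
    adata.uns["norm_target"] = float(norm_target)
    return adata


def log_transform(adata: ad.AnnData) -> ad.AnnData:
    """Elementwise natural log(1 + x) of the normalized matrix."""
    X = np.asarray(adata.X, dtype=float)
    if np.any(X < 0):
        raise ValueError("negative values: log transform expects normalized counts")
    adata.layers["normalized"] = X.copy()
    adata.X = np.log1p(X)
    adata.uns["log1p"] = True
    return adata


def flag_doublets(adata: ad.AnnData, flag_rate: float = 0.02,
                  n_clusters: int = 8, seed: int = 0) -> ad.AnnData:
    """Flag cells better explained as a mixture of two subtype centroids.

    A stand-in occupying the doublet-removal slot of the pipeline: cells
    are provisionally clustered (k-means on log-normalized expression),
    and each cell scored by the margin between its distance to the best
    single centroid and to the best pairwise centroid average.  The top
    ``flag_rate`` fraction by score is flagged.  With all-tied scores
    (degenerate input) nothing is flagged.
    """
    from sklearn.cluster import KMeans

    X = np.asarray(adata.X, dtype=float)
    qc = adata.obs["qc_pass"].to_numpy() if "qc_pass" in adata.obs \
        else np.ones(adata.n_obs, bool)
    flags = np.zeros(adata.n_obs, dtype=bool)
    Xq = X[qc]
    k = min(n_clusters, max(Xq.shape[0] // 20, 2))
    if Xq.shape[0] < 4 or np.unique(Xq, axis=0).shape[0] < 2:
        warnings.warn("fewer than 2 provisional clusters; no doublet flags",
                      stacklevel=2)
        adata.obs["doublet_flag"] = flags
        return adata
    Z = zscore_scale(Xq)
    km = KMeans(n_clusters=k, random_state=seed, n_init=5).fit(Z)
    cents = km.cluster_centers_
    d_single = np.min(
        ((Z[:, None, :] - cents[None, :, :]) ** 2).sum(-1), axis=1)
    pair_cents = np.array([(cents[i] + cents[j]) / 2
                           for i in range(k) for j in range(i + 1, k)])
    d_pair = np.min(
        ((Z[:, None, :] - pair_cents[None, :, :]) ** 2).sum(-1), axis=1)
    score = d_single - d_pair  # positive: mixture fits better
    if np.ptp(score) == 0:
        adata.obs["doublet_flag"] = flags
        return adata
    cutoff = np.quantile(score, 1 - flag_rate)
    flags[np.where(qc)[0]] = score > cutoff
    adata.obs["doublet_flag"] = flags
    adata.obs["doublet_score"] = 0.0
    adata.obs.loc[adata.obs.index[qc], "doublet_score"] = score
    return adata


def qc_pipeline(adata: ad.AnnData, params: QCParams = QCParams(),
                doublets: bool = True, seed: int = 0) -> ad.AnnData:
    """filter -> normalize -> log -> doublet flag, in the published order."""
    filter_cells(adata, params)
    normalize_counts(adata, params.norm_target)
    log_transform(adata)
    if doublets:
        flag_doublets(adata, seed=seed)
    else:
        adata.obs["doublet_flag"] = False
    return adata
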