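"""Dataset integration: co-embedding, cluster correspondence, projection
SVM and weighted-kNN expression imputation.

Two datasets (e.g. imaging-based counts and reference scRNA-seq) are
co-embedded by joint z-scaling and PCA on shared genes with
dataset-of-origin centering; cluster correspondence is measured by the
composition of each cluster's nearest 30 cross-dataset neighbors (the
two directional matrices averaged); projection targets are inferred by a
multiclass RBF SVM (gamma 0.01, cost 10) trained on reference cells; and
panel-limited profiles are extended by distance-weighted k-nearest-
neighbor transfer of reference expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import correct_batches, pca_embed, zscore_scale

__all__ = [
    "CorrespondenceMatrix", "ProjectionModel",
    "coembed", "correspondence_matrix", "train_projection_svm",
    "predict_projection", "impute_expression_knn",
]


@dataclass
class CorrespondenceMatrix:
    """Bidirectional neighbor-composition fractions between cluster sets.

    ``m_ab`` rows are clusters of A over clusters of B (each row the
    B-cluster composition of the pooled cross-neighbors of that A
    cluster, summing to 1); ``m_ba`` likewise; ``m_avg`` is
    ``(m_ab + m_ba.T) / 2``.
    """

    m_ab: pd.DataFrame
    m_ba: pd.DataFrame
    m_avg: pd.DataFrame


def coembed(table_a, table_b, n_pcs: int = 30) -> tuple[np.ndarray, np.ndarray]:
    """Joint embedding of two tables on shared genes.

    The union matrix (log-normalized values) restricted to shared genes
    is z-scaled jointly, projected by PCA, and batch-centered with
    dataset-of-origin as the batch; the first ``n_pcs`` corrected PCs are
    returned along with a boolean mask marking rows from A.
    """
    shared = [g for g in table_a.var_names if g in set(table_b.var_names)]
    if len(shared) < 2:
        raise ValueError("fewer than 2 shared genes")
    Xa = np.asarray(table_a[:, shared].X, dtype=float)
    Xb = np.asarray(table_b[:, shared].X, dtype=float)
    X = np.vstack([Xa, Xb])
    from_a = np.zeros(len(X), dtype=bool)
    from_a[: len(Xa)] = True
    Z = zscore_scale(X)
    scores, _ = pca_embed(Z)
    P = scores[:, : min(n_pcs, scores.shape[1])]
    P = correct_batches(P, np.where(from_a, "A", "B"))
    return P, from_a


def correspondence_matrix(embedding: np.ndarray, from_a: np.ndarray,
                          labels_a, labels_b, k: int = 30) -> CorrespondenceMatrix:
    """Cluster correspondence via nearest cross-dataset neighbors.

    For each cluster of B, the k nearest A-cells of each member cell are
    pooled and the A-cluster fractions tabulated (a row of M_BA, summing
    to 1); symmetrically for M_AB.  Empty clusters yield zero rows with a
    warning.
    """
    from sklearn.neighbors import NearestNeighbors

    if k < 1:
        raise ValueError("k must be >= 1")
    emb = np.asarray(embedding, dtype=float)
    from_a = np.asarray(from_a, dtype=bool)
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    Pa, Pb = emb[from_a], emb[~from_a]
    cls_a = sorted(pd.unique(labels_a))
    cls_b = sorted(pd.unique(labels_b))

    def direction(P_query, labels_query, cls_query, P_ref, labels_ref, cls_ref):
        kk = min(k, len(P_ref))
        nn = NearestNeighbors(n_neighbors=kk).fit(P_ref)
        _, idx = nn.kneighbors(P_query)
        M = pd.DataFrame(0.0, index=cls_query, columns=cls_ref)
        for c in cls_query:
            mask = labels_query == c
            if mask.sum() == 0:
                warnings.warn(f"cluster {c!r} has 0 cells; zero row", stacklevel=3)
                continue
            pooled = labels_ref[idx[mask].ravel()]
            frac = pd.Series(pooled).value_counts(normalize=True)
            for r, v in frac.items():
                M.loc[c, r] = v
        return M

    m_ba = direction(Pb, labels_b, cls_b, Pa, labels_a, cls_a)  # B rows x A cols
    m_ab = direction(Pa, labels_a, cls_a, Pb, labels_b, cls_b)  # A rows x B cols
    m_avg = (m_ab + m_ba.T) / 2.0
    return CorrespondenceMatrix(m_ab=m_ab, m_ba=m_ba, m_avg=m_avg)


@dataclass
class ProjectionModel:
    """Fitted multiclass projection classifier with held-out performance."""

    svc: object
    classes: list
    auc_macro: float
    per_class_auc: dict
    train_idx: np.ndarray
    test_idx: np.ndarray


def train_projection_svm(embedding: np.ndarray, reference_labels,
                         train_fraction: float = 0.7, seed: int = 0,
                         gamma: float = 0.01, cost: float = 10.0,
                         min_class_size: int = 5) -> ProjectionModel:
    """RBF SVM over reference cells with one-vs-rest ROC on the test split.

    Classes with fewer than ``min_class_size`` cells are excluded with a
    warning.  The macro AUC averages the per-class one-vs-rest AUCs.
    """
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import train_test_split
    from sklearn.svm import SVC

    emb = np.asarray(embedding, dtype=float)
    y = np.asarray(reference_labels)
    counts = pd.Series(y).value_counts()
    small = counts[counts < min_class_size].index.tolist()
    if small:
        warnings.warn(f"classes excluded (< {min_class_size} cells): {small}",
                      stacklevel=2)
    keep = ~np.isin(y, small)
    emb, y = emb[keep], y[keep]
    if pd.Series(y).nunique() < 2:
        raise ValueError("need >= 2 classes with enough cells")
    idx = np.arange(len(y))
    tr, te = train_test_split(idx, train_size=train_fraction, random_state=seed,
                              stratify=y)
    svc = SVC(kernel="rbf", gamma=gamma, C=cost, decision_function_shape="ovr",
              random_state=seed)
    svc.fit(emb[tr], y[tr])
    scores = svc.decision_function(emb[te])
    classes = list(svc.classes_)
    if scores.ndim == 1:
        scores = np.column_stack([-scores, scores])
    per_class = {}
    for j, c in enumerate(classes):
        truth = (y[te] == c).astype(int)
        if truth.min() == truth.max():
            continue
        per_class[c] = float(roc_auc_score(truth, scores[:, j]))
    auc_macro = float(np.mean(list(per_class.values()))) if per_class else float("nan")
    return ProjectionModel(svc=svc, classes=classes, auc_macro=auc_macro,
                           per_class_auc=per_class, train_idx=tr, test_idx=te)


def predict_projection(model: ProjectionModel, embedding: np.ndarray,
                       query_idx=None) -> np.ndarray:
    """Predicted projection target per query cell (``"w/o"`` allowed)."""
    emb = np.asarray(embedding, dtype=float)
    if query_idx is not None:
        emb = emb[np.asarray(query_idx)]
    n_features = model.svc.n_features_in_
    if emb.shape[1] != n_features:
        raise ValueError(
            f"embedding has {emb.shape[1]} dims; model expects {n_features}")
    return model.svc.predict(emb)


def impute_expression_knn(query_emb: np.ndarray, ref_emb: np.ndarray,
                          ref_expression: np.ndarray, k: int = 30,
                          eps: float = 1e-9) -> np.ndarray:
    """Distance-weighted kNN transfer of reference expression.

    Each query cell receives the 1/(d+eps)-weighted average of its k
    nearest reference cells' full expression vectors (including genes
    absent from the query panel).  If the reference is smaller than k,
    k is reduced with a warning.
    """
    from sklearn.neighbors import NearestNeighbors

    if k < 1:
        raise ValueError("k must be >= 1")
    Q = np.asarray(query_emb, dtype=float)
    R = np.asarray(ref_emb, dtype=float)
    E = np.asarray(ref_expression, dtype=float)
    if len(R) < k:
        warnings.warn(f"reference has {len(R)} cells < k={k}; using k={len(R)}",
                      stacklevel=2)
        k = len(R)
    nn = NearestNeighbors(n_neighbors=k).fit(R)
    dist, idx = nn.kneighbors(Q)
    w = 1.0 / (dist + eps)
    w /= w.sum(axis=1, keepdims=True)
    return np.einsum("qk,qkg->qg", w, E[idx])
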