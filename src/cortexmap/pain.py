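"""Chronic-pain analysis: ARG activity scores, paired condition tests,
per-subtype perturbation separability and logistic-regression DEGs.

The ARG (activity-regulated gene) score of a cell is the mean of the
per-gene z-scores of a five-gene immediate-early-gene panel, computed
over all cells pooled across conditions (paired slices are imaged
together, so contrasts are within-run).  Differential expression between
conditions uses, per gene, a logistic regression of condition on
expression with batch covariates (C ~ E + S) tested against the nested
null (C ~ 1 + S) by likelihood ratio, chi-square df 1, with Bonferroni
correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import ARG_PANEL_FOS, ARG_PANEL_FOSB

__all__ = [
    "ARG_PANEL_FOS", "ARG_PANEL_FOSB",
    "arg_score", "compare_arg_paired", "perturbation_score", "lrt_deg",
]


def arg_score(X: np.ndarray, genes, panel=ARG_PANEL_FOSB) -> np.ndarray:
    """Per-cell ARG score: mean over the panel of per-gene z-scores.

    z-scores use the population (divide-by-n) standard deviation over all
    cells; a zero-variance panel gene contributes 0 with a warning.  The
    default panel is the five-gene list with Fosb; pass
    :data:`ARG_PANEL_FOS` for the variant with Fos.
    """
    gi = {g: i for i, g in enumerate(genes)}
    missing = [g for g in panel if g not in gi]
    if missing:
        raise ValueError(f"panel genes not in table: {missing}")
    X = np.asarray(X, dtype=float)
    zs = []
    for g in panel:
        col = X[:, gi[g]]
        sd = col.std()
        if sd == 0:
            warnings.warn(f"panel gene {g} has zero variance; z set to 0",
                          stacklevel=2)
            zs.append(np.zeros(len(col)))
        else:
            zs.append((col - col.mean()) / sd)
    return np.mean(zs, axis=0)


def compare_arg_paired(scores: np.ndarray, subtype_labels, condition_labels,
                       pair_ids) -> pd.DataFrame:
    """Per-subtype paired comparison of ARG scores between conditions.

    ARG scores are averaged per mouse pair and condition; a two-tailed
    paired t-test runs across pairs.  With identical paired means p = 1
    by convention; with < 2 pairs only the effect is reported.
    """
    df = pd.DataFrame({"score": np.asarray(scores, dtype=float),
                       "subtype": np.asarray(subtype_labels),
                       "condition": np.asarray(condition_labels),
                       "pair": np.asarray(pair_ids)})
    conds = sorted(df["condition"].unique())
    if len(conds) != 2:
        raise ValueError(f"expected exactly 2 conditions, got {conds}")
    ctrl, treat = ("sham", "SNI") if set(conds) == {"sham", "SNI"} else conds
    rows = []
    for st, sub in df.groupby("subtype", observed=True):
        means = sub.groupby(["pair", "condition"], observed=True)["score"] \
            .mean().unstack("condition")
        means = means.dropna()
        if len(means) == 0:
            continue
        diff = means[treat] - means[ctrl]
        row = {"subtype": st, "n_pairs": len(means),
               "mean_diff": float(diff.mean()),
               "direction": "down" if diff.mean() < 0 else "up"}
        if len(means) >= 2:
            if np.allclose(diff, 0):
                row["t"], row["p"] = 0.0, 1.0
            else:
                t, p = stats.ttest_rel(means[treat], means[ctrl])
                row["t"], row["p"] = float(t), float(p)
        else:
            row["t"], row["p"] = np.nan, np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("subtype")


def perturbation_score(X: np.ndarray, subtype_labels, condition_labels,
                       n_subsample: int = 100, n_folds: int = 3,
                       n_repeats: int = 10, seed: int = 0) -> pd.DataFrame:
    """Cross-validated condition-separability AUC per subtype.

    For each subtype, ``n_subsample`` cells per condition are drawn
    (class-balanced), an L2-regularized linear classifier is trained with
    ``n_folds``-fold cross-validation on normalized expression, and the
    mean held-out one-vs-one AUC over folds and ``n_repeats`` repeats is
    reported.  Subtypes with insufficient cells are skipped with a
    warning.  An AUC near 0.5 means the conditions are transcriptionally
    indistinguishable in that subtype.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import StratifiedKFold

    X = np.asarray(X, dtype=float)
    subtype_labels = np.asarray(subtype_labels)
    condition_labels = np.asarray(condition_labels)
    conds = sorted(pd.unique(condition_labels))
    if len(conds) != 2:
        raise ValueError(f"expected exactly 2 conditions, got {conds}")
    rng = np.random.default_rng(seed)
    rows = []
    for st in sorted(pd.unique(subtype_labels)):
        idx_by_cond = [np.where((subtype_labels == st) &
                                (condition_labels == c))[0] for c in conds]
        if min(len(ix) for ix in idx_by_cond) < n_subsample:
            warnings.warn(f"subtype {st!r}: fewer than {n_subsample} cells "
                          "per condition; skipped", stacklevel=2)
            continue
        aucs = []
        for _ in range(n_repeats):
            pick = np.concatenate([rng.choice(ix, n_subsample, replace=False)
                                   for ix in idx_by_cond])
            Xi = X[pick]
            yi = (condition_labels[pick] == conds[1]).astype(int)
            skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                  random_state=int(rng.integers(2 ** 31)))
            for tr, te in skf.split(Xi, yi):
                clf = LogisticRegression(max_iter=1000)
                clf.fit(Xi[tr], yi[tr])
                aucs.append(roc_auc_score(yi[te], clf.decision_function(Xi[te])))
        rows.append({"subtype": st, "auc": float(np.mean(aucs)),
                     "n_folds": n_folds, "n_repeats": n_repeats})
    if not rows:
        return pd.DataFrame(columns=["auc", "n_folds", "n_repeats"],
                            index=pd.Index([], name="subtype"))
    out = pd.DataFrame(rows).set_index("subtype")
    return out.sort_values("auc", ascending=False)


def _logit_loglik(X, y, beta):
    eta = X @ beta
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _fit_logit_ridge(X, y, ridge: float = 1e-4, max_iter: int = 100):
    """Newton/IRLS with a small ridge on non-intercept terms (fallback for
    perfect separation, where the unpenalized MLE diverges)."""
    n, p = X.shape
    beta = np.zeros(p)
    pen = np.full(p, ridge)
    pen[0] = 0.0  # no penalty on the intercept
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        grad = X.T @ (y - mu) - pen * beta
        H = (X * W[:, None]).T @ X + np.diag(pen)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    return beta


def lrt_deg(X: np.ndarray, genes, condition_labels, batch_labels,
            alpha: float = 0.05, ridge_fallback: float = 1e-4) -> pd.DataFrame:
    """Per-gene logistic-regression likelihood-ratio DEG test.

    For gene expression E, condition C and batch S, the full model
    C ~ E + S is compared against C ~ 1 + S; the statistic
    2*(l_full - l_null) is referred to chi-square with 1 df, and p-values
    are Bonferroni-corrected over the genes tested.  Constant genes give
    a zero statistic and p = 1.  On perfect separation the fit falls back
    to a small-ridge penalized Newton solve and the gene is flagged.
    """
    import statsmodels.api as sm

    X = np.asarray(X, dtype=float)
    cond = np.asarray(condition_labels)
    conds = sorted(pd.unique(cond))
    if len(conds) != 2:
        raise ValueError(f"expected exactly 2 conditions, got {conds}")
    y = (cond == conds[1]).astype(float)
    batches = pd.get_dummies(pd.Series(np.asarray(batch_labels)),
                             drop_first=True, dtype=float).to_numpy()
    n = len(y)
    base = np.column_stack([np.ones(n), batches])

    def fit_ll(D):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(y, D).fit(disp=0, maxiter=200)
                if not res.mle_retvals.get("converged", True) or \
                        not np.all(np.isfinite(res.params)):
                    raise ValueError("non-convergence")
                return float(res.llf), False
            except Exception:
                beta = _fit_logit_ridge(D, y, ridge_fallback)
                return _logit_loglik(D, y, beta), True

    ll_null, _ = fit_ll(base)
    rows = []
    G = X.shape[1]
    for g in range(G):
        e = X[:, g]
        if np.ptp(e) == 0:
            rows.append({"gene": genes[g], "lrt_stat": 0.0, "p": 1.0,
                         "ridge_fallback": False})
            continue
        D = np.column_stack([np.ones(n), e, batches])
        ll_full, fb = fit_ll(D)
        lam = max(2.0 * (ll_full - ll_null), 0.0)
        rows.append({"gene": genes[g], "lrt_stat": lam,
                     "p": float(stats.chi2.sf(lam, df=1)),
                     "ridge_fallback": fb})
    out = pd.DataFrame(rows)
    out["p_adj"] = np.minimum(out["p"] * G, 1.0)
    out["significant"] = out["p_adj"] < alpha
    return out
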