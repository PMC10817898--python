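"""Evaluation statistics and benchmark scorers.

Covers the permutation Kolmogorov-Smirnov test (within-cell expression
shuffles, empirical p-values), ROC AUC with the delta-AUC aggregation used to
compare scoring methods, the simple baseline scorers (scaled additive, PC1
projection, kNN-imputed additive, multi-unit GLM summarization), and the
bootstrap-lasso model relating activity scores to electrophysiological
features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp
from sklearn.decomposition import PCA
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LassoCV, LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import cross_val_predict
from sklearn.neighbors import NearestNeighbors

from .io import CountMatrix

__all__ = [
    "auc",
    "KSResult",
    "ks_permutation_test",
    "scaled_additive",
    "pc1_baseline",
    "knn_impute",
    "imputed_additive",
    "multiunit_glm_score",
    "delta_auc_summary",
    "residualize_by_type",
    "LassoResult",
    "lasso_bootstrap",
]


def auc(scores, labels) -> float:
    """Probability that a random positive outscores a random negative, ties
    counted one half (midrank AUC)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("need exactly two classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# Permutation KS test
# ---------------------------------------------------------------------------


@dataclass
class KSResult:
    statistic: float
    p_value: float
    n_perm: int
    n_a: int
    n_b: int
    perm_statistics: np.ndarray


def ks_permutation_test(scores_a, scores_b, counts: CountMatrix, scorer,
                        n_perm: int = 1000, seed: int = 0) -> KSResult:
    """Two-sample KS test with an expression-permutation null.

    `counts` holds the cells of group A followed by group B (columns ordered
    to match `scores_a` then `scores_b`); `scorer` maps a CountMatrix to
    per-cell scores. Each permutation shuffles expression values *within*
    each cell (across genes), re-scores, and recomputes D, so the null
    preserves every cell's count distribution while destroying gene identity.
    Empirical p = (#{D_perm >= D_obs} + 1) / (n_perm + 1).
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if len(scores_a) < 2 or len(scores_b) < 2:
        raise ValueError("both groups need at least 2 cells")
    n_a = len(scores_a)
    if counts.n_cells != n_a + len(scores_b):
        raise ValueError("counts must contain the cells of both groups")
    d_obs = float(ks_2samp(scores_a, scores_b).statistic)
    rng = np.random.default_rng(seed)
    x = counts.dense()
    d_perm = np.empty(n_perm)
    for p in range(n_perm):
        # independent within-cell (per-column) permutations, vectorized
        order = np.argsort(rng.random(x.shape), axis=0)
        shuffled = np.take_along_axis(x, order, axis=0)
        perm_counts = CountMatrix(shuffled, counts.gene_ids, counts.cell_ids)
        s = np.asarray(scorer(perm_counts), dtype=float)
        d_perm[p] = ks_2samp(s[:n_a], s[n_a:]).statistic
    p_val = (np.sum(d_perm >= d_obs) + 1) / (n_perm + 1)
    return KSResult(
        statistic=d_obs, p_value=float(p_val), n_perm=n_perm,
        n_a=n_a, n_b=len(scores_b), perm_statistics=d_perm,
    )


# ---------------------------------------------------------------------------
# Baseline scorers
# ---------------------------------------------------------------------------


def scaled_additive(norm_targets: np.ndarray) -> np.ndarray:
    """Min-max scale each target gene to [0, 1] across cells, then sum per
    cell. `norm_targets` is cells x targets log-normalized expression;
    zero-range genes contribute 0."""
    x = np.atleast_2d(np.asarray(norm_targets, dtype=float))
    if x.shape[1] < 1:
        raise ValueError("no target genes supplied")
    lo = x.min(axis=0)
    rng_ = x.max(axis=0) - lo
    scaled = np.where(rng_ > 0, (x - lo) / np.where(rng_ > 0, rng_, 1.0), 0.0)
    return scaled.sum(axis=1)


def pc1_baseline(train_targets: np.ndarray, test_targets: np.ndarray) -> np.ndarray:
    """Project test cells onto the training PC1 of target expression.

    Centering uses training means; the sign is oriented so the score
    correlates positively with mean target expression.
    """
    train = np.asarray(train_targets, dtype=float)
    test = np.asarray(test_targets, dtype=float)
    if np.allclose(train.std(axis=0), 0):
        raise ValueError("zero-variance training targets")
    pca = PCA(n_components=1)
    train_proj = pca.fit_transform(train).ravel()
    if np.corrcoef(train_proj, train.mean(axis=1))[0, 1] < 0:
        pca.components_ = -pca.components_
    return ((test - pca.mean_) @ pca.components_[0]).ravel()


def knn_impute(normalized: np.ndarray, k: int = 15, n_pcs: int = 20,
               seed: int = 0) -> np.ndarray:
    """Simple kNN-averaging imputer (synthetic stand-in for diffusion-based
    smoothing): cells are embedded by PCA of the full normalized matrix and
    each cell's expression is replaced by the mean over its k nearest
    neighbors (self included; k = 1 is the identity)."""
    x = np.asarray(normalized, dtype=float)  # cells x genes
    n_pcs = min(n_pcs, min(x.shape) - 1)
    emb = PCA(n_components=n_pcs, random_state=seed).fit_transform(x)
    nn = NearestNeighbors(n_neighbors=min(k, x.shape[0])).fit(emb)
    _, idx = nn.kneighbors(emb)
    return x[idx].mean(axis=1)


def imputed_additive(normalized: np.ndarray, target_idx, imputer=None,
                     k: int = 15) -> np.ndarray:
    """Scaled-additive score on imputed expression. `normalized` is cells x
    genes log-normalized expression over all genes; `imputer` maps that matrix
    to a smoothed one of the same shape (default: built-in kNN averaging)."""
    x = np.asarray(normalized, dtype=float)
    smoothed = imputer(x) if imputer is not None else knn_impute(x, k=k)
    if smoothed.shape != x.shape:
        raise ValueError("imputer changed the matrix shape")
    return scaled_additive(smoothed[:, list(target_idx)])


def multiunit_glm_score(train_bottleneck: np.ndarray, train_labels,
                        test_bottleneck: np.ndarray) -> np.ndarray:
    """Summarize a k-unit bottleneck to one score: logistic regression of the
    binary stimulation label on the training bottleneck units, applied to
    test units. Falls back to a ridge-penalized fit under separation."""
    xtr = np.atleast_2d(np.asarray(train_bottleneck, dtype=float))
    xte = np.atleast_2d(np.asarray(test_bottleneck, dtype=float))
    y = np.asarray(train_labels)
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf = LogisticRegression(C=1e6, max_iter=2000).fit(xtr, y)
        except ConvergenceWarning:
            warnings.warn("separation detected; refitting with ridge penalty")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf = LogisticRegression(C=1.0, max_iter=2000).fit(xtr, y)
    return clf.predict_proba(xte)[:, 1]


def delta_auc_summary(rows: pd.DataFrame, reference: str = "bottleneck"):
    """Aggregate per-(method, dataset, grouping) AUCs against a reference.

    delta = AUC_reference - AUC_method for each (dataset, grouping); per
    dataset the deltas are averaged over groupings; the overall metric is the
    mean of those per-dataset means. Also reports the fraction of groupings
    the reference wins and the mean win/loss magnitudes.

    Returns (per_row, per_dataset, summary) DataFrames.
    """
    df = rows.copy()
    ref = df[df["method"] == reference].set_index(["dataset", "grouping"])["auc"]
    others = df[df["method"] != reference].copy()
    key = list(zip(others["dataset"], others["grouping"]))
    missing = [k for k in set(key) if k not in ref.index]
    if missing:
        raise ValueError(f"reference {reference!r} missing for {sorted(missing)}")
    others["delta_auc"] = [ref.loc[k] for k in key] - others["auc"].to_numpy()
    per_dataset = (
        others.groupby(["method", "dataset"])["delta_auc"].mean().reset_index()
    )
    summary_rows = []
    for method, sub in others.groupby("method"):
        d = sub["delta_auc"].to_numpy()
        per_ds = per_dataset[per_dataset["method"] == method]["delta_auc"]
        summary_rows.append(
            {
                "method": method,
                "mean_delta_auc": float(per_ds.mean()),
                "win_fraction": float((d > 0).mean()),
                "mean_win": float(d[d > 0].mean()) if (d > 0).any() else 0.0,
                "mean_loss": float(d[d < 0].mean()) if (d < 0).any() else 0.0,
            }
        )
    return others, per_dataset, pd.DataFrame(summary_rows)


# ---------------------------------------------------------------------------
# Electrophysiology model
# ---------------------------------------------------------------------------


def residualize_by_type(values, type_labels):
    """Residuals of a least-squares fit on type indicators — i.e. values minus
    their type means. Singleton types are dropped with a warning.

    Returns (residuals, keep_mask); residuals are NaN where dropped.
    """
    v = np.asarray(values, dtype=float)
    t = pd.Series(np.asarray(type_labels, dtype=object))
    sizes = t.groupby(t).transform("size").to_numpy()
    keep = sizes >= 2
    if (~keep).any():
        warnings.warn(f"{int((~keep).sum())} cells in singleton types dropped")
    res = np.full_like(v, np.nan, dtype=float)
    sub = pd.Series(v[keep]).groupby(t[keep].to_numpy())
    res[keep] = v[keep] - sub.transform("mean").to_numpy()
    return res, keep


@dataclass
class LassoResult:
    table: pd.DataFrame  # feature, mean_coef, se, ci_low, ci_high, p, significant
    alpha: float
    cv_prediction_corr: float
    n_cells: int
    n_boot: int


def lasso_bootstrap(features: pd.DataFrame, scores, type_labels,
                    n_boot: int = 10000, z_outlier: float = 3.0,
                    k_folds: int = 10, seed: int = 0,
                    missing_cell_threshold: int = 500,
                    weight_scheme: str = "bayesian") -> LassoResult:
    """Bootstrap significance of lasso coefficients predicting activity from
    electrophysiological features.

    Pipeline: drop features missing in >= `missing_cell_threshold` cells,
    then cells with any remaining missing value; residualize scores and
    features by neuron type; drop |z| > `z_outlier` outlier cells; pick the
    penalty by k-fold cross-validation; refit `n_boot` times with random
    per-sample weights (Bayesian bootstrap Exp(1) weights by default, or a
    shuffled fixed weight vector with weight_scheme='shuffle'). A feature is
    significant when mean +/- 1.96 * SD of its bootstrap coefficients
    excludes 0; the empirical p counts bootstraps where the coefficient was
    zero or of opposite sign.
    """
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable intervals")
    X = features.copy()
    keep_feats = X.columns[X.isna().sum(axis=0) < missing_cell_threshold]
    X = X[keep_feats]
    cell_ok = ~X.isna().any(axis=1).to_numpy()
    X = X.loc[cell_ok]
    y = np.asarray(scores, dtype=float)[cell_ok]
    t = np.asarray(type_labels)[cell_ok]

    y_res, keep = residualize_by_type(y, t)
    X_res = np.column_stack(
        [residualize_by_type(X[c].to_numpy(), t)[0] for c in X.columns]
    )
    X_res, y_res = X_res[keep], y_res[keep]

    sd = X_res.std(axis=0)
    sd[sd == 0] = 1.0
    z = (X_res - X_res.mean(axis=0)) / sd
    inlier = (np.abs(z) <= z_outlier).all(axis=1)
    z, y_res = z[inlier], y_res[inlier]
    n = len(y_res)

    cv = LassoCV(cv=k_folds, random_state=seed, alphas=50).fit(z, y_res)
    alpha = float(cv.alpha_)
    preds = cross_val_predict(Lasso(alpha=alpha), z, y_res, cv=k_folds)
    cv_corr = float(np.corrcoef(preds, y_res)[0, 1])

    rng = np.random.default_rng(seed)
    base_w = rng.exponential(1.0, n)
    coefs = np.empty((n_boot, z.shape[1]))
    for b in range(n_boot):
        if weight_scheme == "bayesian":
            w = rng.exponential(1.0, n)
        elif weight_scheme == "shuffle":
            w = rng.permutation(base_w)
        else:
            raise ValueError(f"unknown weight_scheme {weight_scheme!r}")
        w = w / w.mean()
        coefs[b] = Lasso(alpha=alpha).fit(z, y_res, sample_weight=w).coef_
    mean = coefs.mean(axis=0)
    se = coefs.std(axis=0)
    lo, hi = mean - 1.96 * se, mean + 1.96 * se
    opposite = np.where(
        mean[None, :] >= 0, coefs <= 0, coefs >= 0
    )
    p = (opposite.sum(axis=0) + 1) / (n_boot + 1)
    table = pd.DataFrame(
        {
            "feature": list(X.columns),
            "mean_coef": mean,
            "se": se,
            "ci_low": lo,
            "ci_high": hi,
            "p": p,
            "significant": (lo > 0) | (hi < 0),
        }
    ).set_index("feature")
    return LassoResult(
        table=table, alpha=alpha, cv_prediction_corr=cv_corr,
        n_cells=n, n_boot=n_boot,
    )
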