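"""Univariate and embedded feature selection for two-class studies.

Four selectors are provided:

* point-biserial correlation (PBC) — Pearson correlation of each feature
  against the 0/1-coded class label, with the classical t-based p-value;
* Welch two-sample t-test;
* ReliefF — neighborhood-based weights that reward features separating
  a sample from its nearest misses more than from its nearest hits
  (sensitive to feature interactions);
* LASSO — the features with nonzero coefficients of an L1-penalized
  logistic regression at a cross-validated penalty.

All selectors return scores for every feature plus an ordered selected
subset (by |score| descending, ties broken by canonical name order).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegressionCV
from sklearn.preprocessing import StandardScaler

from .errors import LabelError
from .study import FeatureTable

__all__ = [
    "SelectionResult",
    "encode_labels",
    "pbc_scores",
    "ttest_select",
    "relieff_scores",
    "lasso_select",
    "select_features",
]


@dataclass
class SelectionResult:
    method: str
    scores: pd.Series
    pvalues: pd.Series | None
    selected: list[str]
    params: dict = field(default_factory=dict)


def encode_labels(labels, positive: str | None = None) -> np.ndarray:
    """Encode a two-class label vector as 0/1 (positive class -> 1).

    Without an explicit positive class the lexicographically *smaller*
    label is coded 1, which maps the conventional ("high", "low") pair
    to high = 1.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise LabelError(f"need exactly 2 classes, got {list(classes)}")
    pos = positive if positive is not None else sorted(classes)[0]
    if pos not in classes:
        raise LabelError(f"positive class {pos!r} not among {list(classes)}")
    return (labels == pos).astype(int)


def _ordered_selection(scores: pd.Series, candidates: list[str]) -> list[str]:
    """Order candidate features by |score| descending, name ascending."""
    return sorted(candidates, key=lambda f: (-abs(scores[f]), f))


def _is_constant(X: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Flag features whose spread is pure floating-point rounding noise."""
    scale = np.abs(X).max(axis=0)
    return s <= np.maximum(scale, 1.0) * 1e-12


def pbc_scores(
    table: FeatureTable, labels, alpha: float = 0.05, top_k: int = 2
) -> SelectionResult:
    """Point-biserial correlation of each feature with the class label.

    r_pb equals the Pearson correlation against the 0/1 label; its
    p-value comes from t = r*sqrt((n-2)/(1-r^2)) on n-2 df.  Constant
    features score 0 with p = 1.  Selection keeps features with
    p < alpha, ranked by |r|, capped at ``top_k``.
    """
    y = encode_labels(labels)
    n = len(y)
    n1 = int(y.sum())
    n0 = n - n1
    X = table.data[table.feature_names].to_numpy(dtype=float)
    mean1 = X[y == 1].mean(axis=0)
    mean0 = X[y == 0].mean(axis=0)
    s = X.std(axis=0)  # population SD over the pooled sample
    constant = _is_constant(X, s)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (mean1 - mean0) / s * np.sqrt(n1 * n0 / n ** 2)
    r = np.where(constant, 0.0, r)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = np.where(
        np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    )
    p = np.where(constant, 1.0, p)
    scores = pd.Series(r, index=table.feature_names)
    pvals = pd.Series(p, index=table.feature_names)
    candidates = pvals[pvals < alpha].index.tolist()
    selected = _ordered_selection(scores, candidates)[:top_k]
    return SelectionResult("pbc", scores, pvals, selected,
                           {"alpha": alpha, "top_k": top_k})


def ttest_select(table: FeatureTable, labels, alpha: float = 0.05) -> SelectionResult:
    """Welch two-sample t-test per feature; select p < alpha."""
    y = encode_labels(labels)
    X = table.data[table.feature_names].to_numpy(dtype=float)
    a = X[y == 1]
    b = X[y == 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, equal_var=False)
    constant = _is_constant(X, X.std(axis=0))
    t = np.where(np.isfinite(t) & ~constant, t, 0.0)
    p = np.where(np.isfinite(p) & ~constant, p, 1.0)
    scores = pd.Series(t, index=table.feature_names)
    pvals = pd.Series(p, index=table.feature_names)
    candidates = pvals[pvals < alpha].index.tolist()
    selected = _ordered_selection(scores, candidates)
    return SelectionResult("ttest", scores, pvals, selected, {"alpha": alpha})


def relieff_scores(
    table: FeatureTable, labels, k_neighbors: int = 10, top_k: int = 2
) -> SelectionResult:
    """ReliefF weights with every sample as an anchor (m = n).

    Features are min-max scaled to [0, 1]; for each sample the k nearest
    hits (same class) and k nearest misses (other class, weighted by the
    prior odds of that class) pull the weight down and up respectively.
    Deterministic: no sampling is involved.
    """
    y = encode_labels(labels)
    feats = table.feature_names
    X = table.data[feats].to_numpy(dtype=float)
    n, d = X.shape
    span = X.max(axis=0) - X.min(axis=0)
    span_safe = np.where(span == 0, 1.0, span)
    Xs = (X - X.min(axis=0)) / span_safe
    Xs[:, span == 0] = 0.0

    dist = np.sqrt(((Xs[:, None, :] - Xs[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(dist, np.inf)

    priors = {c: float((y == c).mean()) for c in (0, 1)}
    w = np.zeros(d)
    for i in range(n):
        same = np.flatnonzero((y == y[i]))
        same = same[same != i]
        hits = same[np.argsort(dist[i, same], kind="stable")[:k_neighbors]]
        if len(hits):
            w -= np.abs(Xs[hits] - Xs[i]).mean(axis=0)
        other = 1 - y[i]
        cand = np.flatnonzero(y == other)
        misses = cand[np.argsort(dist[i, cand], kind="stable")[:k_neighbors]]
        if len(misses):
            factor = priors[other] / (1.0 - priors[y[i]])
            w += factor * np.abs(Xs[misses] - Xs[i]).mean(axis=0)
    w /= n
    scores = pd.Series(w, index=feats)
    positive = scores[scores > 0].index.tolist()
    selected = _ordered_selection(scores, positive)[:top_k]
    return SelectionResult("relieff", scores, None, selected,
                           {"k_neighbors": k_neighbors, "top_k": top_k})


def lasso_select(
    table: FeatureTable, labels, n_folds: int = 5, seed: int = 0
) -> SelectionResult:
    """L1-penalized logistic selection at a cross-validated penalty.

    Features are standardized; the penalty grid is searched by
    ``n_folds``-fold cross-validated deviance and features with nonzero
    coefficients at the chosen penalty are selected.
    """
    y = encode_labels(labels)
    feats = table.feature_names
    X = StandardScaler().fit_transform(table.data[feats].to_numpy(dtype=float))
    model = LogisticRegressionCV(
        Cs=12,
        cv=n_folds,
        penalty="l1",
        solver="liblinear",
        scoring="neg_log_loss",
        random_state=seed,
        max_iter=2000,
    )
    model.fit(X, y)
    coefs = pd.Series(model.coef_.ravel(), index=feats)
    candidates = coefs[coefs != 0].index.tolist()
    selected = _ordered_selection(coefs, candidates)
    return SelectionResult("lasso", coefs, None, selected,
                           {"n_folds": n_folds, "C": float(model.C_[0]), "seed": seed})


_METHODS = {
    "pbc": pbc_scores,
    "ttest": ttest_select,
    "relieff": relieff_scores,
    "lasso": lasso_select,
}


def select_features(table: FeatureTable, labels, method: str = "pbc", **kwargs) -> SelectionResult:
    """Dispatch to a selector by name (pbc | ttest | relieff | lasso)."""
    if method not in _METHODS:
        raise ValueError(f"unknown selection method {method!r}; choose from {sorted(_METHODS)}")
    return _METHODS[method](table, labels, **kwargs)
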