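"""Canonical variate analysis, cross-validated classification, and shape
regression for axis visualization."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

logger = logging.getLogger(__name__)

__all__ = ["CvaResult", "cva", "loo_classification", "shape_regression"]


@dataclass
class CvaResult:
    """Canonical variate analysis of group-structured scores.

    Axes (columns of ``axes``) are scaled so the pooled within-group variance
    is 1 on every axis; ``eigenvalues`` are the between/within variance
    ratios, ``variance_fractions`` their shares of the total.  The confusion
    matrix and correct rates come from leave-one-out cross-validation of a
    pooled-covariance linear discriminant.
    """

    axes: np.ndarray
    scores: np.ndarray
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    group_order: list[str]
    confusion_matrix: pd.DataFrame
    correct_rate: float
    correct_rate_by_group: pd.Series
    correct_rate_group_averaged: float


def _scatter_matrices(X: np.ndarray, y: np.ndarray, groups: list[str]):
    p = X.shape[1]
    grand = X.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for g in groups:
        sub = X[y == g]
        c = sub - sub.mean(axis=0)
        W += c.T @ c
        d = (sub.mean(axis=0) - grand)[:, None]
        B += len(sub) * (d @ d.T)
    return B, W


def cva(scores: np.ndarray, groups) -> CvaResult:
    """Canonical variate analysis on (typically PC) scores.

    Solves the generalized eigenproblem ``B v = lambda W v`` for the between-
    and pooled within-group covariance matrices, keeping
    ``min(n_groups - 1, p)`` axes ordered by decreasing eigenvalue.
    """
    X = np.asarray(scores, float)
    y = np.asarray(groups)
    order = sorted(pd.unique(y))
    g = len(order)
    if g < 2:
        raise ValueError("CVA needs at least 2 groups")
    n, p = X.shape
    B, W = _scatter_matrices(X, y, order)
    W_cov = W / (n - g)
    B_cov = B / (g - 1)
    try:
        evals, evecs = linalg.eigh(B_cov, W_cov)
    except linalg.LinAlgError as exc:
        raise ValueError("singular within-group covariance; use fewer PCs") from exc
    idx = np.argsort(evals)[::-1]
    n_axes = min(g - 1, p)
    evals = np.maximum(evals[idx][:n_axes], 0.0)
    axes = evecs[:, idx][:, :n_axes]  # scipy normalizes v' W_cov v = I
    cva_scores = (X - X.mean(axis=0)) @ axes
    fractions = evals / evals.sum() if evals.sum() > 0 else np.full(n_axes, np.nan)

    confusion, rate, by_group, group_avg = loo_classification(X, y)
    return CvaResult(
        axes=axes,
        scores=cva_scores,
        eigenvalues=evals,
        variance_fractions=fractions,
        group_order=order,
        confusion_matrix=confusion,
        correct_rate=rate,
        correct_rate_by_group=by_group,
        correct_rate_group_averaged=group_avg,
    )


def _lda_assign(train_X, train_y, test_x, groups):
    """Classify one observation by smallest Mahalanobis distance to group
    means under the pooled within-group covariance; ties break to the
    lexicographically first group."""
    p = train_X.shape[1]
    W = np.zeros((p, p))
    means = {}
    n = 0
    for g in groups:
        sub = train_X[train_y == g]
        means[g] = sub.mean(axis=0)
        c = sub - means[g]
        W += c.T @ c
        n += len(sub)
    cov = W / (n - len(groups))
    inv = np.linalg.pinv(cov)
    best, best_d = None, np.inf
    for g in groups:  # groups sorted -> deterministic lexicographic tie-break
        d = test_x - means[g]
        dist = float(d @ inv @ d)
        if dist < best_d - 1e-12 or best is None:
            best, best_d = g, dist
    return best


def loo_classification(scores: np.ndarray, groups):
    """Leave-one-out cross-validated linear-discriminant classification.

    For each specimen the discriminant (group means + pooled covariance) is
    refit on the remaining specimens.  Groups of size 1 are excluded with a
    warning.  Returns (confusion matrix with true groups as rows, overall
    specimen-pooled correct rate, per-group correct rates, group-averaged
    correct rate).
    """
    X = np.asarray(scores, float)
    y = np.asarray(groups)
    counts = pd.Series(y).value_counts()
    singletons = sorted(counts[counts < 2].index)
    if singletons:
        logger.warning("loo_classification: excluding singleton group(s) %s", singletons)
        keep = ~np.isin(y, singletons)
        X, y = X[keep], y[keep]
    order = sorted(pd.unique(y))
    if len(order) < 2:
        raise ValueError("need at least 2 groups with >= 2 specimens")
    confusion = pd.DataFrame(0, index=order, columns=order)
    idx_all = np.arange(len(y))
    for i in idx_all:
        mask = idx_all != i
        pred = _lda_assign(X[mask], y[mask], X[i], order)
        confusion.loc[y[i], pred] += 1
    correct = np.diag(confusion.to_numpy()).sum()
    rate = correct / len(y)
    by_group = pd.Series(
        {g: confusion.loc[g, g] / confusion.loc[g].sum() for g in order}, name="correct_rate"
    )
    return confusion, float(rate), by_group, float(by_group.mean())


def shape_regression(
    axis_scores: np.ndarray, tangent: np.ndarray, magnification: float = 1.0
) -> np.ndarray:
    """Least-squares slope of each tangent coordinate on an axis score.

    Returns per-landmark displacement vectors ``(k, 2)`` describing the shape
    change per unit score, optionally multiplied by a display magnification.
    """
    s = np.asarray(axis_scores, float)
    Y = np.asarray(tangent, float)
    if s.ndim != 1 or len(s) != Y.shape[0]:
        raise ValueError("axis_scores must be one value per specimen")
    sc = s - s.mean()
    var = float(sc @ sc)
    if var == 0:
        raise ValueError("zero-variance axis scores")
    slopes = (sc @ (Y - Y.mean(axis=0))) / var
    return magnification * slopes.reshape(-1, 2)
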