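"""Penalized selection of gene products discriminating transport mode.

A linear model with elastic-net penalty is fitted to the 0/1 transport
labels (0 = carrier, 1 = pneumatic tube) over the complete-case
gene-product intensity matrix:

    min_b  1/(2n) ||y - X b - b0||^2
           + lambda * (alpha ||b||_1 + (1 - alpha)/2 ||b||_2^2)

``alpha = 1`` is the pure Lasso (sparsest selection), ``alpha = 0.5`` the
elastic net (correlated features share weight). The penalty strength
``lambda`` is chosen by leave-one-out cross-validation of the
misclassification error (predicted class = fitted response >= 0.5), with
ties broken toward the larger lambda (the sparser model). Features are
z-scored inside each training fold; nonzero coefficients, split by sign,
are the transport marker candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, enet_path

__all__ = [
    "LassoFit",
    "complete_case_filter",
    "lambda_max",
    "elastic_net_fit",
    "loocv_lambda",
    "select_markers",
    "default_lambda_path",
]


@dataclass(frozen=True)
class LassoFit:
    """A fitted penalized linear classifier of transport mode."""

    alpha: float  # elastic-net mixing: 1.0 pure Lasso, 0.5 elastic net
    lam: float  # penalty strength
    intercept: float
    coefficients: pd.Series  # per gene product, on the original scale
    lambda_path: Optional[np.ndarray] = None
    cv_errors: Optional[np.ndarray] = None  # per-lambda LOOCV misclassification


def complete_case_filter(gene_matrix: pd.DataFrame) -> pd.DataFrame:
    """Drop gene products (rows) with any missing intensity.

    Only fully observed gene products enter the classifier; raises when
    nothing survives.
    """
    kept = gene_matrix.dropna(axis=0, how="any")
    if kept.shape[0] == 0:
        raise ValueError("no gene product is complete across all observations")
    return kept


def _standardize(X: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe, mu, sd_safe


def lambda_max(X: np.ndarray, y: np.ndarray, alpha: float) -> float:
    """Smallest penalty at which all coefficients are zero:
    ``max |x_j . (y - mean y)| / (n * alpha)`` on standardized features."""
    Xs, _, _ = _standardize(np.asarray(X, dtype=float))
    yc = y - y.mean()
    return float(np.max(np.abs(Xs.T @ yc)) / (len(y) * alpha))


def default_lambda_path(
    X: np.ndarray, y: np.ndarray, alpha: float, n_lambda: int = 100, ratio: float = 1e-3
) -> np.ndarray:
    """100 log-spaced penalties from lambda_max down to ratio*lambda_max."""
    lmax = lambda_max(X, y, alpha)
    return np.geomspace(lmax, ratio * lmax, n_lambda)


def elastic_net_fit(
    gene_matrix: pd.DataFrame,
    labels: Sequence[int],
    alpha: float,
    lam: float,
) -> LassoFit:
    """Fit the penalized linear model at one (alpha, lambda).

    ``gene_matrix`` is gene-product by observation (complete cases);
    ``labels`` are 0 (carrier) / 1 (pneumatic tube) per observation.
    Features are z-scored internally by cyclic coordinate descent;
    returned coefficients are on the original intensity scale.
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    X = gene_matrix.to_numpy(dtype=float).T  # observations x features
    y = np.asarray(labels, dtype=float)
    if X.shape[0] != y.size:
        raise ValueError("label count must match observation count")
    if np.isnan(X).any():
        raise ValueError("matrix must be complete; run complete_case_filter first")
    Xs, mu, sd = _standardize(X)
    if lam == 0:
        lam = 1e-12  # plain least squares limit; keep the solver's path
    model = ElasticNet(
        alpha=lam,
        l1_ratio=alpha,
        fit_intercept=True,
        max_iter=100_000,
        tol=1e-7,
    )
    model.fit(Xs, y)
    coef_std = model.coef_
    coef = coef_std / sd
    intercept = float(model.intercept_ - np.sum(coef * mu))
    return LassoFit(
        alpha=alpha,
        lam=float(lam),
        intercept=intercept,
        coefficients=pd.Series(coef, index=gene_matrix.index, name="coefficient"),
    )


def loocv_lambda(
    gene_matrix: pd.DataFrame,
    labels: Sequence[int],
    alpha: float,
    lambda_path: Optional[np.ndarray] = None,
) -> LassoFit:
    """Choose lambda by leave-one-out misclassification error.

    For every lambda on the path the model is refitted n times on n-1
    observations (fold-internal standardization, no leakage) and the
    held-out response is classified at 0.5. The lambda minimizing the
    mean error wins, ties broken toward the larger lambda (the sparser
    model); the returned fit is refitted on all observations at the
    chosen lambda and carries the path and error curve.
    """
    y = np.asarray(labels, dtype=float)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("labels must contain both classes")
    n = y.size
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 observations")
    X = gene_matrix.to_numpy(dtype=float).T
    if lambda_path is None:
        lambda_path = default_lambda_path(X, y, alpha)
    lambda_path = np.asarray(lambda_path, dtype=float)
    errors = np.zeros((lambda_path.size, n))
    desc = np.argsort(-lambda_path, kind="mergesort")  # solver wants descending
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        Xt, mu, sd = _standardize(X[train])
        yt = y[train]
        x_held = (X[i] - mu) / sd
        _, coefs, _ = enet_path(
            Xt, yt - yt.mean(), l1_ratio=alpha,
            alphas=np.maximum(lambda_path[desc], 1e-12),
            max_iter=100_000, tol=1e-7,
        )
        for pos, k in enumerate(desc):
            pred = float(yt.mean() + x_held @ coefs[:, pos])
            errors[k, i] = float((pred >= 0.5) != bool(y[i]))
    mean_err = errors.mean(axis=1)
    # ties toward the larger lambda: path is descending, take first minimum
    order = np.argsort(-lambda_path, kind="mergesort")
    best = order[int(np.argmin(mean_err[order]))]
    fit = elastic_net_fit(gene_matrix, labels, alpha, float(lambda_path[best]))
    return LassoFit(
        alpha=fit.alpha,
        lam=fit.lam,
        intercept=fit.intercept,
        coefficients=fit.coefficients,
        lambda_path=lambda_path,
        cv_errors=mean_err,
    )


def select_markers(fit: LassoFit, tol: float = 0.0) -> Tuple[List[str], List[str]]:
    """Nonzero-coefficient gene products split by sign, ordered by
    decreasing |coefficient| (positive set: higher in pneumatic-tube
    samples; negative: higher in carrier samples)."""
    coef = fit.coefficients
    nz = coef[np.abs(coef) > tol]
    ordered = nz.reindex(np.abs(nz).sort_values(ascending=False, kind="mergesort").index)
    positive = [g for g, c in ordered.items() if c > 0]
    negative = [g for g, c in ordered.items() if c < 0]
    return positive, negative
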