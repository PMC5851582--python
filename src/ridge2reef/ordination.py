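"""Constrained ordination of reef indicators on environmental drivers.

With a Euclidean resemblance measure, distance-based redundancy analysis
reduces to classical redundancy analysis (RDA): the indicator matrix Y is
regressed on the driver matrix X, and the fitted values are eigen-decomposed.
Per-axis percentages of *fitted* variation are eigenvalues over their sum;
percentages of *total* variation scale them by the fraction of Y's variance
that the constraint captures.

Drivers with pairwise |r| above a threshold (default 0.7) are greedily
pruned in column order (the later column of an offending pair is dropped).
Indicators are expected variance-stabilized (sqrt benthic, fourth-root fish);
both matrices are normalized (z-scored) internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["OrdinationResult", "dbrda", "prune_correlated"]


@dataclass
class OrdinationResult:
    scores: np.ndarray                # sample scores, (n, n_axes)
    pct_fitted: np.ndarray            # per-axis % of fitted variation (sums to 100)
    pct_total: np.ndarray             # per-axis % of total variation
    loadings: pd.DataFrame            # driver → axis loadings (correlations)
    retained_drivers: list[str]
    fitted_total_ratio: float         # (Σ eigenvalues) / total variance of Y
    good_fit: bool                    # fitted variation > 70 % of total


def prune_correlated(X: pd.DataFrame, threshold: float = 0.7) -> list[str]:
    """Greedy pruning of later columns with |r| > threshold to a kept column."""
    kept: list[str] = []
    with np.errstate(invalid="ignore", divide="ignore"):
        for col in X.columns:
            if any(abs(np.corrcoef(X[col], X[k])[0, 1]) > threshold for k in kept):
                continue
            kept.append(col)
    return kept


def _zscore(a: np.ndarray) -> np.ndarray:
    sd = a.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant column cannot be normalized")
    return (a - a.mean(axis=0)) / sd


def dbrda(
    Y: pd.DataFrame,
    X: pd.DataFrame,
    corr_threshold: float = 0.7,
) -> OrdinationResult:
    """Redundancy analysis of indicators Y constrained by drivers X."""
    if len(Y) != len(X):
        raise ValueError("Y and X must have the same number of samples")
    retained = prune_correlated(X, corr_threshold)
    Xm = _zscore(X[retained].to_numpy(dtype=float))
    Ym = _zscore(Y.to_numpy(dtype=float))
    n, p = Xm.shape
    if n <= p:
        raise ValueError(f"need more samples ({n}) than drivers ({p}) after pruning")
    # fitted values of the multivariate regression Y ~ X
    B, *_ = np.linalg.lstsq(Xm, Ym, rcond=None)
    Yhat = Xm @ B
    # eigen-decomposition of the fitted covariance via SVD of Yhat
    U, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
    eig = s**2 / (n - 1)
    n_axes = int(np.sum(eig > 1e-12 * max(eig.max(), 1.0)))
    eig = eig[:n_axes]
    scores = (U[:, :n_axes] * s[:n_axes])
    total_var = float(np.sum(Ym.var(axis=0, ddof=1)))
    fitted_var = float(eig.sum())
    pct_fitted = 100.0 * eig / fitted_var
    pct_total = 100.0 * eig / total_var
    loadings = pd.DataFrame(
        {f"axis{k + 1}": [float(np.corrcoef(Xm[:, j], scores[:, k])[0, 1])
                          for j in range(p)]
         for k in range(n_axes)},
        index=retained,
    )
    return OrdinationResult(
        scores=scores,
        pct_fitted=pct_fitted,
        pct_total=pct_total,
        loadings=loadings,
        retained_drivers=retained,
        fitted_total_ratio=fitted_var / total_var,
        good_fit=(fitted_var / total_var) > 0.70,
    )
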