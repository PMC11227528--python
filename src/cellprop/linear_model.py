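"""Cluster-wise ordinary least squares fits and condition contrasts.

Each cluster's transformed proportions are regressed on the shared design
matrix (one OLS fit per cluster, analogous to gene-wise fits in differential
expression).  The fit keeps, per cluster, the coefficient vector, the
unscaled coefficient standard deviations (square roots of the diagonal of
(X'X)^-1), the residual standard deviation sigma and the residual degrees of
freedom — the sufficient statistics for empirical-Bayes moderation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cell_table import DesignMatrix, ValidationError

__all__ = ["LinearFit", "ContrastFit", "fit_clusterwise_ols", "make_contrast"]


@dataclass
class LinearFit:
    coefficients: pd.DataFrame  # clusters x terms
    stdev_unscaled: pd.DataFrame  # clusters x terms
    sigma: pd.Series  # per-cluster residual SD (NaN when df_residual == 0)
    df_residual: int
    cov_unscaled: np.ndarray  # (terms x terms) = (X'X)^-1
    design: DesignMatrix

    @property
    def clusters(self) -> list[str]:
        return list(self.coefficients.index)


@dataclass
class ContrastFit:
    """Condition contrasts of a :class:`LinearFit`.

    ``effects`` holds one column per contrast (a single difference for two
    conditions, the k-1 differences against the first condition otherwise).
    ``cov_unscaled`` is the contrast-space (r x r) unscaled covariance
    L (X'X)^-1 L'; multiplied by sigma^2 it gives the contrast covariance.
    """

    effects: pd.DataFrame  # clusters x contrasts
    stdev_unscaled: pd.Series  # per-contrast unscaled SD (shared across clusters)
    cov_unscaled: np.ndarray  # contrasts x contrasts
    sigma: pd.Series
    df_residual: int

    @property
    def n_contrasts(self) -> int:
        return self.effects.shape[1]


def fit_clusterwise_ols(y: pd.DataFrame, design: DesignMatrix) -> LinearFit:
    """Fit one OLS model per cluster column of ``y`` against ``design``.

    Raises on rank-deficient designs (silent pseudo-inverse aliasing would
    corrupt contrasts).  When there are exactly as many samples as model terms
    the fit is saturated: coefficients are returned with ``df_residual = 0``
    and undefined (NaN) sigma, with a warning.
    """
    X = design.values
    if list(y.index) != list(design.frame.index):
        if set(y.index) != set(design.frame.index):
            raise ValidationError("response and design rows do not match")
        y = y.loc[design.frame.index]
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValidationError(
            f"design matrix is rank deficient (rank {rank} < {p} terms): {design.terms}"
        )
    if n < p:
        raise ValidationError(f"fewer samples ({n}) than model terms ({p})")

    Y = y.to_numpy(dtype=float)
    coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    df_residual = n - rank
    rss = np.einsum("ij,ij->j", resid, resid)
    if df_residual > 0:
        sigma = np.sqrt(rss / df_residual)
    else:
        warnings.warn(
            "saturated fit (residual df = 0): no variance estimate possible",
            stacklevel=2,
        )
        sigma = np.full(Y.shape[1], np.nan)
    cov_unscaled = np.linalg.inv(X.T @ X)
    su = np.sqrt(np.diag(cov_unscaled))

    clusters = list(y.columns)
    return LinearFit(
        coefficients=pd.DataFrame(coef.T, index=clusters, columns=design.terms),
        stdev_unscaled=pd.DataFrame(
            np.tile(su, (len(clusters), 1)), index=clusters, columns=design.terms
        ),
        sigma=pd.Series(sigma, index=clusters, name="sigma"),
        df_residual=int(df_residual),
        cov_unscaled=cov_unscaled,
        design=design,
    )


def make_contrast(fit: LinearFit, conditions: list[str]) -> ContrastFit:
    """Build condition contrasts from a group-means fit.

    Two conditions give the single difference ``conditions[1] - conditions[0]``
    with unscaled SD sqrt(v1 + v2 - 2*v12); more give the k-1 independent
    differences of each later condition against the first, kept jointly for
    the moderated F test.
    """
    conditions = list(conditions)
    terms = fit.design.terms
    unknown = [c for c in conditions if c not in terms]
    if unknown:
        raise ValidationError(f"unknown condition term(s): {unknown}")
    if len(conditions) < 2:
        raise ValidationError("need at least two conditions to contrast")
    if len(set(conditions)) != len(conditions):
        raise ValidationError(f"conditions to contrast must be distinct: {conditions}")

    p = len(terms)
    idx = [terms.index(c) for c in conditions]
    L = np.zeros((p, len(conditions) - 1))
    names = []
    for j, i2 in enumerate(idx[1:]):
        L[i2, j] = 1.0
        L[idx[0], j] = -1.0
        names.append(f"{conditions[j + 1]}-{conditions[0]}")

    effects = fit.coefficients.to_numpy() @ L
    cov_c = L.T @ fit.cov_unscaled @ L
    su = np.sqrt(np.diag(cov_c))
    return ContrastFit(
        effects=pd.DataFrame(effects, index=fit.clusters, columns=names),
        stdev_unscaled=pd.Series(su, index=names, name="stdev_unscaled"),
        cov_unscaled=cov_c,
        sigma=fit.sigma,
        df_residual=fit.df_residual,
    )
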