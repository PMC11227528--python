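"""Empirical-Bayes variance moderation and the moderated t / F tests.

With only a handful of replicates per condition, the per-cluster residual
variances s_k^2 are noisy.  Assuming the true variances follow a scaled
inverse chi-square prior with d0 degrees of freedom and location s0^2, the
marginal distribution of s_k^2 is a scaled F, and the posterior mean variance
is the precision-weighted blend

    s~_k^2 = (d0 * s0^2 + df_k * s_k^2) / (d0 + df_k).

(d0, s0^2) are estimated from all clusters jointly by the method of moments
on log variances (the limma fitFDist procedure): subtract the known sampling
moments of log chi-square via digamma/trigamma terms, and solve the trigamma
equation for d0 with a Newton iteration.  Moderated statistics replace s_k
by s~_k and gain the prior degrees of freedom: t has d0 + df_k df, F has
(r, d0 + df_k) df.  d0 = +infinity (no excess dispersion between clusters)
is represented exactly and uses the normal / chi-square limiting forms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .linear_model import ContrastFit

__all__ = [
    "VariancePrior",
    "EBayesStats",
    "fit_variance_prior",
    "squeeze_var",
    "moderated_t_test",
    "moderated_f_test",
    "bh_adjust",
]

ALPHA = 0.05  # significance threshold on BH-adjusted p-values


@dataclass
class VariancePrior:
    """Scaled-F prior for residual variances: d0 (df, may be inf) and s0^2."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError("prior df d0 must be positive (or +inf)")
        if not (self.s0_sq > 0):
            raise ValueError("prior variance s0_sq must be positive")


@dataclass
class EBayesStats:
    post_var: pd.Series  # posterior (squeezed) variances s~^2
    statistic: pd.Series  # moderated t or F
    df_total: float  # d0 + df_residual (capped at pooled residual df)
    p_value: pd.Series
    p_adjusted: pd.Series
    kind: str  # "t" or "F"

    @property
    def significant(self) -> pd.Series:
        return self.p_adjusted < ALPHA


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the inverse scale)."""
    if x <= 0:
        raise ValueError("trigamma inverse requires a positive argument")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if -dif / y < 1e-8:
            break
    return float(y)


def fit_variance_prior(sigma_sq, df) -> VariancePrior:
    """Moment-fit the scaled-F prior (d0, s0^2) to per-cluster variances.

    Works on z = log(sigma_sq): the sampling mean and variance of z given the
    true variance are digamma(df/2) - log(df/2) and trigamma(df/2); whatever
    dispersion of z exceeds the sampling part is attributed to the prior and
    inverted through the trigamma function to get d0.  No excess dispersion
    (or a single cluster) yields d0 = +inf.
    """
    sigma_sq = np.asarray(sigma_sq, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), sigma_sq.shape)
    if (df <= 0).any():
        raise ValueError("all residual df must be positive to fit the prior")
    n = sigma_sq.size
    if n < 2:
        warnings.warn(
            "fewer than 2 clusters: no between-cluster information, using d0=inf",
            stacklevel=2,
        )
        s0 = float(sigma_sq[0]) if n == 1 and sigma_sq[0] > 0 else 1.0
        return VariancePrior(d0=math.inf, s0_sq=s0)

    x = np.maximum(sigma_sq, 0.0)
    m = np.median(x)
    if m == 0:
        warnings.warn(
            "more than half of the residual variances are exactly zero; the "
            "empirical-Bayes moderation is unreliable",
            stacklevel=2,
        )
        m = 1.0
    elif (x == 0).any():
        warnings.warn("zero sample variances detected, offset away from zero", stacklevel=2)
    x = np.maximum(x, m * 1e-5)

    z = np.log(x)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = np.sum((e - emean) ** 2) / (n - 1)
    evar -= np.mean(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = math.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    else:
        # no dispersion beyond sampling noise: the variances are exchangeable
        # draws around a common value, best located by their plain mean
        d0 = math.inf
        s0_sq = float(x.mean())
    return VariancePrior(d0=d0, s0_sq=s0_sq)


def squeeze_var(sigma_sq, df, prior: VariancePrior):
    """Posterior variances: (d0*s0^2 + df*s^2) / (d0 + df); s0^2 when d0=inf."""
    sigma_sq = np.asarray(sigma_sq, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), sigma_sq.shape)
    if math.isinf(prior.d0):
        return np.full_like(sigma_sq, prior.s0_sq)
    if prior.d0 == 0:
        return sigma_sq.copy()
    return (prior.d0 * prior.s0_sq + df * sigma_sq) / (prior.d0 + df)


def _df_total(df_residual: float, d0: float, n_clusters: int) -> float:
    """Total df = df + d0, capped at the pooled residual df across clusters.

    The cap reflects that the prior itself was estimated from the clusters'
    pooled information: even a formally infinite d0 cannot contribute more
    degrees of freedom than the n_clusters * df_residual residuals it was fit
    on.  d0 = inf therefore yields the pooled df (the normal limit applies
    only if that, too, is infinite).
    """
    pooled = n_clusters * df_residual
    if math.isinf(d0):
        return pooled
    return min(df_residual + d0, pooled)


def moderated_t_test(contrast: ContrastFit, prior: VariancePrior) -> EBayesStats:
    """Moderated t-test for a single condition contrast.

    t_k = effect_k / (stdev_unscaled * s~_k), referred to a Student t with
    d0 + df_residual degrees of freedom (standard normal when d0 = inf).
    """
    if contrast.n_contrasts != 1:
        raise ValueError(
            f"moderated t-test needs exactly one contrast, got {contrast.n_contrasts}"
        )
    if contrast.df_residual <= 0 and not math.isinf(prior.d0):
        raise ValueError("non-positive residual df: cannot test a saturated fit")
    clusters = contrast.effects.index
    effect = contrast.effects.iloc[:, 0].to_numpy()
    su = float(contrast.stdev_unscaled.iloc[0])
    s2 = contrast.sigma.to_numpy() ** 2
    post = squeeze_var(s2, contrast.df_residual, prior)
    denom = su * np.sqrt(post)
    t = np.zeros_like(effect)
    nz = denom > 0
    t[nz] = effect[nz] / denom[nz]
    t[~nz & (effect != 0)] = np.sign(effect[~nz & (effect != 0)]) * np.inf
    df_total = _df_total(contrast.df_residual, prior.d0, len(clusters))
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        if df_total <= 0:
            raise ValueError("total degrees of freedom must be positive")
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p_adj = bh_adjust(p)
    return EBayesStats(
        post_var=pd.Series(post, index=clusters, name="post_var"),
        statistic=pd.Series(t, index=clusters, name="t"),
        df_total=df_total,
        p_value=pd.Series(p, index=clusters, name="p_value"),
        p_adjusted=pd.Series(p_adj, index=clusters, name="p_adjusted"),
        kind="t",
    )


def moderated_f_test(contrast: ContrastFit, prior: VariancePrior) -> EBayesStats:
    """Moderated F-test over the joint k-1 condition contrasts (ANOVA).

    F_k = (b_k' C^-1 b_k) / (r * s~_k^2) with C the unscaled contrast
    covariance and r the number of contrasts; referred to F(r, d0 + df).
    """
    r = contrast.n_contrasts
    if r < 1:
        raise ValueError("moderated F-test needs at least one contrast")
    if contrast.df_residual <= 0 and not math.isinf(prior.d0):
        raise ValueError("non-positive residual df: cannot test a saturated fit")
    cond = np.linalg.cond(contrast.cov_unscaled)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError("singular unscaled contrast covariance")
    clusters = contrast.effects.index
    B = contrast.effects.to_numpy()
    Cinv = np.linalg.inv(contrast.cov_unscaled)
    quad = np.einsum("ki,ij,kj->k", B, Cinv, B)
    s2 = contrast.sigma.to_numpy() ** 2
    post = squeeze_var(s2, contrast.df_residual, prior)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(post > 0, quad / (r * np.where(post > 0, post, 1.0)), 0.0)
    df_total = _df_total(contrast.df_residual, prior.d0, len(clusters))
    if math.isinf(df_total):
        p = stats.chi2.sf(r * F, r)
    else:
        p = stats.f.sf(F, r, df_total)
    p_adj = bh_adjust(p)
    return EBayesStats(
        post_var=pd.Series(post, index=clusters, name="post_var"),
        statistic=pd.Series(F, index=clusters, name="F"),
        df_total=df_total,
        p_value=pd.Series(p, index=clusters, name="p_value"),
        p_adjusted=pd.Series(p_adj, index=clusters, name="p_adjusted"),
        kind="F",
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
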