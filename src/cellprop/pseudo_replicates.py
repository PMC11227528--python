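"""Bootstrap pseudo-replicates for unreplicated composition data.

When a condition has a single sample, no between-replicate variance exists
and the linear-model test cannot run.  The bootstrap engine manufactures
pseudo-replicates by randomly *partitioning* each condition's cells
("bootstrapping without replacement": every cell is used exactly once per
iteration), which preserves each condition's pooled cluster proportions
exactly while introducing sampling variance between the parts.

One iteration:
  1. find n_min, the smallest cell count across all conditions, and
     downsample every condition to n_min cells (without replacement);
  2. split each condition into n_reps disjoint pseudo-replicates; part sizes
     are drawn sequentially uniform over the remaining budget, the last part
     takes the remainder (size vectors with an empty part are redrawn, with
     an even-split fallback);
  3. run the full moderated test on the pseudo-replicated count matrix.

The iteration is repeated ``n_iterations`` times (default 100); effects are
pooled by Rubin's rule (mean of the per-iteration estimates, with the
within/between variance decomposition retained) and the final per-cluster
p-value is the median of the iterations' BH-adjusted p-values.

Internally the engine works on cluster counts: drawing m cells without
replacement from a sample is a multivariate hypergeometric draw on its
cluster counts, because cells are exchangeable within a cluster.  Cell-level
:func:`downsample_to_min` and :func:`split_into_pseudo_reps` are provided for
cell-table workflows and for checking the exact-partition property.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cell_table import CLUSTER, CONDITION, SAMPLE, CellTable, CountMatrix, ValidationError
from .empirical_bayes import (
    ALPHA,
    fit_variance_prior,
    squeeze_var,
    _df_total,
)
from .transforms import PSEUDO_COUNTS, TRANSFORMS
from scipy import stats

__all__ = [
    "BootstrapConfig",
    "PooledResult",
    "downsample_to_min",
    "split_into_pseudo_reps",
    "run_bootstrap",
    "choose_default_n_reps",
]

_MAX_SIZE_REDRAWS = 100


@dataclass
class BootstrapConfig:
    """Settings for the pseudo-replicate engine."""

    n_reps: int = 8  # pseudo-replicates per condition
    n_iterations: int = 100  # outer repetitions whose adjusted p is medianed
    seed: int | None = None
    transform: str = "arcsin"
    keep_iterations: bool = False  # retain per-iteration adjusted p-values

    def __post_init__(self) -> None:
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2 (need variance between parts)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")


@dataclass
class PooledResult:
    """Rubin-pooled bootstrap output."""

    pooled_effects: pd.Series  # per-cluster mean of iteration effect estimates
    median_p_adjusted: pd.Series
    within_var: pd.Series  # mean squared SE of the effect across iterations
    between_var: pd.Series  # variance of the effect estimates across iterations
    n_reps: int
    n_iterations: int
    per_iteration: pd.DataFrame | None = None  # iterations x clusters adjusted p

    @property
    def total_var(self) -> pd.Series:
        """Rubin total variance: W + (1 + 1/m) B."""
        m = self.n_iterations
        return self.within_var + (1.0 + 1.0 / m) * self.between_var

    @property
    def significant(self) -> pd.Series:
        return self.median_p_adjusted < ALPHA


def choose_default_n_reps(mean_cells_per_condition: int) -> int:
    """Default pseudo-replicate count as a function of dataset size.

    Few large pseudo-replicates suit small datasets (each part must still
    carry enough cells per cluster); more parts pay off once conditions hold
    tens of thousands of cells: <=5000 cells -> 4, <=25000 -> 8, above -> 10.
    """
    if mean_cells_per_condition <= 0:
        raise ValueError("cell count must be positive")
    if mean_cells_per_condition <= 5000:
        return 4
    if mean_cells_per_condition <= 25000:
        return 8
    return 10


# ---------------------------------------------------------------------------
# cell-level operations


def downsample_to_min(cells: CellTable, seed=None, min_required: int = 2) -> CellTable:
    """Reduce every sample to n_min cells, drawn uniformly without replacement.

    n_min is the smallest sample size across all conditions; downsampling
    equalizes sample sizes before splitting so that no pseudo-replicate
    inherits a size advantage.
    """
    rng = np.random.default_rng(seed)
    sizes = cells.data.groupby(SAMPLE, sort=False).size()
    n_min = int(sizes.min())
    if n_min < min_required:
        raise ValidationError(
            f"smallest sample has {n_min} cells; cannot split into {min_required} "
            "pseudo-replicates"
        )
    parts = []
    for sample in cells.samples:
        idx = cells.data.index[cells.data[SAMPLE] == sample].to_numpy()
        keep = rng.choice(idx, size=n_min, replace=False)
        parts.append(cells.data.loc[np.sort(keep)])
    return CellTable(pd.concat(parts, ignore_index=True), cells.covariates)


def _draw_sizes(n_min: int, n_reps: int, rng: np.random.Generator) -> np.ndarray:
    """Pseudo-replicate sizes: sequential uniform draws over the remaining budget.

    The last part takes the remainder; vectors with an empty part are redrawn
    (bounded), falling back to an even split.
    """
    for _ in range(_MAX_SIZE_REDRAWS):
        sizes = np.empty(n_reps, dtype=int)
        remaining = n_min
        ok = True
        for i in range(n_reps - 1):
            sizes[i] = rng.integers(0, remaining + 1)
            remaining -= sizes[i]
            if sizes[i] == 0 or remaining < 1:
                ok = False
                break
        if ok:
            sizes[-1] = remaining
            if (sizes >= 1).all():
                return sizes
    base = n_min // n_reps
    sizes = np.full(n_reps, base, dtype=int)
    sizes[: n_min - base * n_reps] += 1
    return sizes


def split_into_pseudo_reps(
    sample_cells: CellTable, n_reps: int, seed=None
) -> CellTable:
    """Partition one sample's cells into n_reps disjoint pseudo-replicates.

    The union of the parts is exactly the input multiset, so the pooled
    cluster proportions are preserved exactly.
    """
    rng = np.random.default_rng(seed)
    samples = sample_cells.samples
    if len(samples) != 1:
        raise ValidationError(f"expected a single sample, got {samples}")
    sample = samples[0]
    n = len(sample_cells)
    if n_reps > n:
        raise ValidationError(f"cannot split {n} cells into {n_reps} pseudo-replicates")
    sizes = _draw_sizes(n, n_reps, rng)
    order = rng.permutation(n)
    data = sample_cells.data.iloc[order].reset_index(drop=True)
    labels = np.repeat(
        [f"{sample}_pseudo{i + 1}" for i in range(n_reps)], sizes
    )
    data = data.assign(**{SAMPLE: labels})
    return CellTable(data, sample_cells.covariates)


# ---------------------------------------------------------------------------
# count-level bootstrap engine


def _split_count_row(
    counts: np.ndarray, sizes: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Partition one count vector into len(sizes) parts without replacement."""
    parts = np.empty((len(sizes), len(counts)), dtype=np.int64)
    remaining = counts.astype(np.int64).copy()
    for i, s in enumerate(sizes[:-1]):
        part = rng.multivariate_hypergeometric(remaining, int(s))
        remaining -= part
        parts[i] = part
    parts[-1] = remaining
    return parts


def _pseudo_rep_counts(
    cond_counts: np.ndarray, n_reps: int, rng: np.random.Generator
) -> np.ndarray:
    """One bootstrap draw: downsample each condition to n_min, then split.

    Returns an array of shape (n_conditions * n_reps, n_clusters); rows are
    grouped by condition.
    """
    totals = cond_counts.sum(axis=1)
    n_min = int(totals.min())
    if n_min < n_reps:
        raise ValidationError(
            f"smallest condition has {n_min} cells; cannot split into {n_reps} parts"
        )
    out = np.empty((cond_counts.shape[0] * n_reps, cond_counts.shape[1]), dtype=np.int64)
    for c in range(cond_counts.shape[0]):
        row = cond_counts[c].astype(np.int64)
        if totals[c] > n_min:
            row = rng.multivariate_hypergeometric(row, n_min)
        sizes = _draw_sizes(n_min, n_reps, rng)
        out[c * n_reps : (c + 1) * n_reps] = _split_count_row(row, sizes, rng)
    return out


def _test_pseudo_counts(
    counts: np.ndarray, n_cond: int, n_reps: int, transform: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Moderated test on a pseudo-replicated count array (group-means design).

    Returns (effects, p_adjusted, se_sq).  For two conditions the effect is
    the condition-2 minus condition-1 mean on the transformed scale and
    se_sq its squared moderated standard error; for more conditions the
    effect column is the per-cluster F numerator contrasts' first component
    and the p-values come from the moderated F.
    """
    from .empirical_bayes import bh_adjust

    pc = PSEUDO_COUNTS[transform]
    shifted = counts + pc
    props = shifted / shifted.sum(axis=1, keepdims=True)
    if transform == "logit":
        y = np.log(props / (1.0 - props))
    else:
        y = np.arcsin(np.sqrt(props))

    k = y.shape[1]
    y3 = y.reshape(n_cond, n_reps, k)
    means = y3.mean(axis=1)  # condition means = group-means OLS coefficients
    resid = y3 - means[:, None, :]
    df = n_cond * n_reps - n_cond
    sigma_sq = np.einsum("crk,crk->k", resid, resid) / df
    prior = fit_variance_prior(sigma_sq, df)
    post = squeeze_var(sigma_sq, df, prior)
    df_total = _df_total(df, prior.d0, k)

    if n_cond == 2:
        effect = means[1] - means[0]
        se_sq = (2.0 / n_reps) * post
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se_sq > 0, effect / np.sqrt(np.where(se_sq > 0, se_sq, 1.0)), 0.0)
        if math.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
    else:
        grand = means.mean(axis=0)
        ssb = n_reps * ((means - grand) ** 2).sum(axis=0)  # Wald numerator
        r = n_cond - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            F = np.where(post > 0, ssb / (r * np.where(post > 0, post, 1.0)), 0.0)
        if math.isinf(df_total):
            p = stats.chi2.sf(r * F, r)
        else:
            p = stats.f.sf(F, r, df_total)
        effect = means[1] - means[0]
        se_sq = (2.0 / n_reps) * post
    return effect, bh_adjust(p), se_sq


def run_bootstrap(
    counts: CountMatrix,
    config: BootstrapConfig,
) -> PooledResult:
    """Run the full pseudo-replicate analysis on merged (one sample per
    condition) count data and pool the iterations.

    Each iteration re-randomizes the downsampling and the split, using an
    independent child stream spawned from ``config.seed`` so results are
    reproducible regardless of execution order.
    """
    conds = list(pd.unique(counts.conditions))
    if len(conds) < 2:
        raise ValidationError("need at least two conditions")
    per_cond = counts.conditions.value_counts()
    if (per_cond > 1).any():
        raise ValidationError(
            "run_bootstrap expects one (merged) sample per condition; merge "
            "replicates first"
        )
    mat = np.asarray(
        [counts.counts.loc[(counts.conditions == c).values].to_numpy()[0] for c in conds],
        dtype=np.int64,
    )
    n_min = int(mat.sum(axis=1).min())
    if n_min < config.n_reps:
        raise ValidationError(
            f"smallest condition has {n_min} cells; cannot split into "
            f"{config.n_reps} pseudo-replicates"
        )

    clusters = counts.clusters
    m = config.n_iterations
    children = np.random.SeedSequence(config.seed).spawn(m)
    effects = np.empty((m, len(clusters)))
    p_adj = np.empty((m, len(clusters)))
    se_sq = np.empty((m, len(clusters)))
    for i in range(m):
        rng = np.random.default_rng(children[i])
        try:
            pseudo = _pseudo_rep_counts(mat, config.n_reps, rng)
            effects[i], p_adj[i], se_sq[i] = _test_pseudo_counts(
                pseudo, len(conds), config.n_reps, config.transform
            )
        except Exception as err:  # annotate which iteration failed
            raise RuntimeError(f"bootstrap iteration {i} failed: {err}") from err

    pooled = effects.mean(axis=0)
    within = se_sq.mean(axis=0)
    between = effects.var(axis=0, ddof=1) if m > 1 else np.zeros(len(clusters))
    median_p = np.median(p_adj, axis=0)
    return PooledResult(
        pooled_effects=pd.Series(pooled, index=clusters, name="effect"),
        median_p_adjusted=pd.Series(median_p, index=clusters, name="p_adjusted"),
        within_var=pd.Series(within, index=clusters, name="within_var"),
        between_var=pd.Series(between, index=clusters, name="between_var"),
        n_reps=config.n_reps,
        n_iterations=m,
        per_iteration=(
            pd.DataFrame(p_adj, columns=clusters) if config.keep_iterations else None
        ),
    )
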