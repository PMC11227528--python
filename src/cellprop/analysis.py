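"""Top-level proportion-analysis runner.

``run_analysis`` accepts a cell table or a precomputed count matrix, decides
between the direct (replicated) path and the bootstrap (pseudo-replicate)
path, runs the moderated test and returns a :class:`ResultsTable`.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .cell_table import (
    CellTable,
    CountMatrix,
    ValidationError,
    design_from_samples,
    tabulate_counts,
)
from .empirical_bayes import (
    ALPHA,
    fit_variance_prior,
    moderated_f_test,
    moderated_t_test,
)
from .linear_model import fit_clusterwise_ols, make_contrast
from .pseudo_replicates import (
    BootstrapConfig,
    _pseudo_rep_counts,
    choose_default_n_reps,
    run_bootstrap,
)
from .results import LOW_COUNT_FRACTION, ResultsTable
from .transforms import to_proportions, transform_counts

__all__ = ["test_composition", "run_analysis"]


def test_composition(
    counts: CountMatrix,
    transform: str = "arcsin",
    conditions: list[str] | None = None,
    covariates: pd.DataFrame | None = None,
):
    """Direct (replicated) moderated test on a sample x cluster count matrix.

    Transforms proportions, fits the cluster-wise OLS against the group-means
    design, squeezes the residual variances and applies the moderated t
    (two conditions) or moderated F (more).  Returns the per-cluster table
    with effects, statistics and BH-adjusted p-values.
    """
    if conditions is not None:
        counts = counts.restrict_conditions(conditions)
        levels = list(conditions)
    else:
        levels = counts.condition_levels
    design = design_from_samples(counts.conditions, covariates)
    y = transform_counts(counts.counts, transform)
    fit = fit_clusterwise_ols(y, design)
    contrast = make_contrast(fit, levels)
    prior = fit_variance_prior(fit.sigma.to_numpy() ** 2, fit.df_residual)
    if contrast.n_contrasts == 1:
        stats_ = moderated_t_test(contrast, prior)
        effect = contrast.effects.iloc[:, 0]
    else:
        stats_ = moderated_f_test(contrast, prior)
        effect = contrast.effects.iloc[:, 0]  # first difference, for reference
    out = pd.DataFrame(
        {
            "effect": effect,
            "statistic": stats_.statistic,
            "p_value": stats_.p_value,
            "p_adjusted": stats_.p_adjusted,
            "significant": stats_.significant,
        }
    )
    out.attrs["kind"] = stats_.kind
    out.attrs["design_terms"] = design.terms
    return out


def _merge_counts(counts: CountMatrix) -> CountMatrix:
    conds = list(pd.unique(counts.conditions))
    merged = pd.DataFrame(
        [counts.counts.loc[(counts.conditions == c).values].sum(axis=0) for c in conds],
        index=conds,
    ).astype(int)
    return CountMatrix(merged, pd.Series(conds, index=conds))


def _mean_props(counts: CountMatrix) -> pd.DataFrame:
    """Per-condition mean of the samples' raw cluster proportions."""
    props = to_proportions(counts.counts)
    props = props.assign(__cond=counts.conditions.values)
    return props.groupby("__cond", sort=False).mean()


def run_analysis(
    data,
    transform: str = "arcsin",
    conditions: list[str] | None = None,
    n_reps: int | None = None,
    n_iterations: int = 100,
    seed: int | None = None,
    force_bootstrap: bool = False,
) -> ResultsTable:
    """Run the full proportion analysis.

    ``data`` is a :class:`CellTable` or :class:`CountMatrix`.  When every
    condition has at least two samples the direct replicated path is taken
    (deterministic, no randomness); otherwise samples are merged per
    condition and the bootstrap pseudo-replicate path runs ``n_iterations``
    times with ``n_reps`` pseudo-replicates (chosen from the dataset size
    when not given).  Mixed replication (some conditions replicated, some
    not) merges everything with a warning.
    """
    if isinstance(data, CellTable):
        if conditions is not None:
            data = data.restrict_conditions(conditions)
        counts = tabulate_counts(data)
        covariates = data.sample_covariates() if data.covariates else None
    elif isinstance(data, CountMatrix):
        counts = data.restrict_conditions(conditions) if conditions is not None else data
        covariates = None
    else:
        raise TypeError(f"expected CellTable or CountMatrix, got {type(data).__name__}")

    levels = conditions if conditions is not None else counts.condition_levels
    if len(levels) < 2:
        raise ValidationError(f"need at least 2 conditions, got {levels}")

    samples_per_cond = counts.conditions.value_counts()
    replicated = bool((samples_per_cond.loc[levels] >= 2).all())
    if not replicated and not force_bootstrap:
        if (samples_per_cond.loc[levels] >= 2).any():
            warnings.warn(
                "mixed replication: some conditions lack replicates; merging all "
                "samples per condition and bootstrapping pseudo-replicates",
                stacklevel=2,
            )
    mode = "replicated" if (replicated and not force_bootstrap) else "bootstrapped"

    cluster_totals = counts.counts.sum(axis=0)
    low_count = cluster_totals / cluster_totals.sum() < LOW_COUNT_FRACTION

    if mode == "replicated":
        table = test_composition(counts, transform, levels, covariates)
        kind = table.attrs["kind"]
        design_terms = table.attrs["design_terms"]
        sample_props = to_proportions(counts.counts)
        sample_conditions = counts.conditions
        metadata = {
            "mode": "replicated",
            "transform": transform,
            "statistic": kind,
            "conditions": ",".join(levels),
            "design_terms": ",".join(design_terms),
            "n_reps": "",
            "n_iterations": "",
            "seed": "" if seed is None else seed,
        }
    else:
        merged = _merge_counts(counts.restrict_conditions(levels))
        if n_reps is None:
            n_reps = choose_default_n_reps(int(merged.counts.sum(axis=1).mean()))
        config = BootstrapConfig(
            n_reps=n_reps, n_iterations=n_iterations, seed=seed, transform=transform
        )
        pooled = run_bootstrap(merged, config)
        table = pd.DataFrame(
            {
                "effect": pooled.pooled_effects,
                "statistic": np.nan,
                "p_value": np.nan,
                "p_adjusted": pooled.median_p_adjusted,
                "significant": pooled.significant,
            }
        )
        counts = merged
        # one representative pseudo-replicate split, for plotting only
        rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(n_iterations + 1)[-1])
        mat = merged.counts.to_numpy(dtype=np.int64)
        pseudo = _pseudo_rep_counts(mat, n_reps, rng)
        pseudo_ids = [
            f"{cond}_pseudo{i + 1}" for cond in merged.samples for i in range(n_reps)
        ]
        sample_props = to_proportions(
            pd.DataFrame(pseudo, index=pseudo_ids, columns=merged.clusters)
        )
        sample_conditions = pd.Series(
            np.repeat(merged.conditions.values, n_reps), index=pseudo_ids
        )
        metadata = {
            "mode": "bootstrapped",
            "transform": transform,
            "statistic": "median adjusted p over iterations",
            "conditions": ",".join(levels),
            "design_terms": ",".join(levels),
            "n_reps": n_reps,
            "n_iterations": n_iterations,
            "seed": "" if seed is None else seed,
        }

    mean_props = _mean_props(counts)
    for cond in reversed(levels):
        table.insert(0, f"prop_{cond}", mean_props.loc[cond])
    table["low_count"] = low_count
    table.index.name = "cluster"

    return ResultsTable(
        table=table,
        metadata=metadata,
        sample_props=sample_props,
        sample_conditions=sample_conditions,
    )
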