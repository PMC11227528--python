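"""Benchmark harness: score runs against simulation truth, sweep parameters.

Scoring follows the usual confusion-matrix conventions on per-cluster calls
against the scenario's changed mask: accuracy = (TP + TN) / clusters, FPR =
FP / negatives, sensitivity = TP / positives, and auROC is the probability
that a randomly chosen changed cluster outranks a randomly chosen unchanged
one (ties counting one half).

``run_benchmark`` sweeps replicate counts, transforms, analysis modes and
(optionally) dataset sizes, simulating ``n_sims`` datasets per combination
and emitting one tidy row per simulation x combination x metric.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .analysis import test_composition
from .empirical_bayes import ALPHA
from .pseudo_replicates import BootstrapConfig, run_bootstrap
from .simulate import make_changed_scenario, make_null_scenario, merge_replicates, simulate_dataset

__all__ = [
    "score_accuracy",
    "score_rates",
    "compute_auroc",
    "run_benchmark",
    "summarize_benchmark",
]

REPS_GRID = (2, 3, 4, 5, 8, 10, 14)

_SCENARIOS = {"null": make_null_scenario, "changed": make_changed_scenario}


def _as_bool(x) -> np.ndarray:
    return np.asarray(x, dtype=bool)


def score_accuracy(calls, truth) -> float:
    """(TP + TN) / number of clusters."""
    calls, truth = _as_bool(calls), _as_bool(truth)
    if calls.shape != truth.shape:
        raise ValueError("calls and truth must have equal length")
    return float((calls == truth).mean())


def score_rates(calls, truth) -> tuple[float, float]:
    """(false positive rate, sensitivity)."""
    calls, truth = _as_bool(calls), _as_bool(truth)
    if calls.shape != truth.shape:
        raise ValueError("calls and truth must have equal length")
    pos, neg = truth.sum(), (~truth).sum()
    if pos == 0 or neg == 0:
        raise ValueError("need at least one positive and one negative cluster")
    fpr = float((calls & ~truth).sum() / neg)
    sens = float((calls & truth).sum() / pos)
    return fpr, sens


def compute_auroc(scores, truth) -> float:
    """Probability a changed cluster outranks an unchanged one (Mann-Whitney)."""
    truth = _as_bool(truth)
    scores = np.asarray(scores, dtype=float)
    if truth.all() or not truth.any():
        raise ValueError("need both classes to compute an auROC")
    return float(roc_auc_score(truth, scores))


def _analyze_one(dataset, mode: str, transform: str, bootstrap_reps: int,
                 n_iterations: int, seed: int):
    """Run one dataset through the requested path; return (calls, scores)."""
    if mode == "replicated":
        res = test_composition(dataset.counts, transform)
        p_adj = res["p_adjusted"]
    elif mode == "unreplicated":
        merged = merge_replicates(dataset)
        pooled = run_bootstrap(
            merged.counts,
            BootstrapConfig(
                n_reps=bootstrap_reps,
                n_iterations=n_iterations,
                seed=seed,
                transform=transform,
            ),
        )
        p_adj = pooled.median_p_adjusted
    else:
        raise ValueError(f"unknown mode {mode!r}")
    p_adj = p_adj.loc[dataset.changed_mask.index]
    return (p_adj < ALPHA).to_numpy(), (1.0 - p_adj).to_numpy()


def run_benchmark(
    scenario: str = "null",
    modes=("replicated",),
    transforms=("arcsin",),
    n_reps_grid=REPS_GRID,
    bootstrap_reps_grid=None,
    n_sims: int = 100,
    target_cells=(20_000,),
    n_iterations: int = 100,
    seed: int = 0,
    out=None,
) -> pd.DataFrame:
    """Sweep the grid, simulate and score; return the tidy long-format table.

    ``bootstrap_reps_grid=None`` splits merged data into as many
    pseudo-replicates as were simulated (the like-for-like comparison);
    passing a grid instead sweeps the pseudo-replicate count on datasets
    simulated with the ``n_reps_grid`` replicate counts (the parameter
    optimization setting).  ``target_cells`` may hold several dataset sizes.
    """
    if scenario not in _SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {sorted(_SCENARIOS)}")
    make_scenario = _SCENARIOS[scenario]
    if np.isscalar(target_cells):
        target_cells = (target_cells,)

    rows = []
    combos = list(itertools.product(target_cells, n_reps_grid, modes, transforms))
    for combo_idx, (cells, n_reps, mode, transform) in enumerate(combos):
        sc = make_scenario(n_reps, target_cells_per_condition=int(cells))
        truth = sc.changed_mask.to_numpy()
        has_both = truth.any() and (~truth).any()
        boot_grid = (
            (n_reps,) if bootstrap_reps_grid is None or mode == "replicated"
            else tuple(bootstrap_reps_grid)
        )
        for sim in range(n_sims):
            rng = np.random.default_rng([seed, combo_idx, sim])
            dataset = simulate_dataset(sc, rng)
            for boot_reps in boot_grid:
                run_seed = int(
                    np.random.default_rng([seed, combo_idx, sim, boot_reps]).integers(2**31)
                )
                calls, _ = _analyze_one(dataset, mode, transform, boot_reps, n_iterations, run_seed)
                base = {
                    "scenario": scenario,
                    "target_cells": int(cells),
                    "n_reps": n_reps,
                    "bootstrap_reps": boot_reps if mode == "unreplicated" else np.nan,
                    "mode": mode,
                    "transform": transform,
                    "sim": sim,
                }
                rows.append({**base, "metric": "accuracy", "value": score_accuracy(calls, truth)})
                if has_both:
                    fpr, sens = score_rates(calls, truth)
                    rows.append({**base, "metric": "fpr", "value": fpr})
                    rows.append({**base, "metric": "sensitivity", "value": sens})

    tidy = pd.DataFrame(rows)
    if out is not None:
        tidy.to_csv(out, sep="\t", index=False)
    return tidy


def summarize_benchmark(tidy: pd.DataFrame) -> pd.DataFrame:
    """Mean metric value per grid combination (one row per combination x metric)."""
    keys = ["scenario", "target_cells", "n_reps", "bootstrap_reps", "mode", "transform", "metric"]
    return (
        tidy.groupby(keys, dropna=False, sort=False)["value"]
        .mean()
        .reset_index()
        .rename(columns={"value": "mean_value"})
    )
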