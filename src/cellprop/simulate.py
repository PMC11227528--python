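"""Hierarchical benchmark simulator for cell-type composition data.

Datasets are generated from the three-level model commonly used to benchmark
proportion tests:

  I.   the total cell count of each replicate, n_j ~ NegBin(mean=mu, size=nb_dispersion);
  II.  the per-replicate cluster proportions, p_ij ~ Beta(a_i, b_i), with
       (a_i, b_i) set by moments so that E[p_ij] is the scenario's true
       proportion and the dispersion parameter phi controls the
       between-replicate spread: a = p (1/phi - 1), b = (1-p)(1/phi - 1);
  III. the per-cluster cell counts ~ Binomial(n_j, p_ij).

The binomial draws are independent across clusters, so a replicate's
realized total is close to, but not exactly, n_j; proportions are computed
from the realized totals downstream, which keeps the noise structure
exchangeable across clusters.  (Forcing the row sum back to n_j by letting
one cluster absorb the residual would give that cluster the summed variance
of all the others and make it systematically anti-conservative.)  An exact
multinomial mode — normalize the drawn p_ij and draw one multinomial per
replicate — is available behind a flag for strictly fixed row totals.

Two canonical scenarios are provided, each targeting ~20,000 cells per
condition split over ``n_reps`` replicates (mu = target / n_reps,
nb_dispersion = 20): a 5-cluster null with identical proportions in both
conditions, and a 7-cluster scenario with 3 changed clusters, the smallest
("Changed3") below 2% of all cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cell_table import CLUSTER, CONDITION, SAMPLE, CellTable, CountMatrix

__all__ = [
    "SimScenario",
    "SimulatedDataset",
    "simulate_dataset",
    "make_null_scenario",
    "make_changed_scenario",
    "merge_replicates",
    "NULL_PROPS",
    "CHANGED_PROPS_A",
    "CHANGED_PROPS_B",
    "CHANGED_CLUSTERS",
]

#: null scenario: five equal clusters in both conditions
NULL_PROPS = (0.2, 0.2, 0.2, 0.2, 0.2)

#: changed scenario: 3 of 7 clusters shift between conditions; the changed
#: block is compositionally balanced so the stable clusters keep identical
#: true proportions; Changed3 holds <2% of all cells (1.2% vs 2.4%, mean 1.8%).
CHANGED_CLUSTERS = (
    "Changed1",
    "Changed2",
    "Changed3",
    "Stable1",
    "Stable2",
    "Stable3",
    "Stable4",
)
CHANGED_PROPS_A = (0.300, 0.100, 0.012, 0.065, 0.100, 0.170, 0.253)
CHANGED_PROPS_B = (0.165, 0.223, 0.024, 0.065, 0.100, 0.170, 0.253)

DEFAULT_NB_DISPERSION = 20.0
DEFAULT_BETA_SPREAD = 0.01
DEFAULT_TARGET_CELLS = 20_000


@dataclass
class SimScenario:
    """Generating truth for one benchmark dataset family."""

    clusters: tuple[str, ...]
    true_props: dict[str, np.ndarray]  # condition -> proportion vector
    mu: float  # NB mean cells per replicate
    nb_dispersion: float = DEFAULT_NB_DISPERSION
    beta_spread: float = DEFAULT_BETA_SPREAD
    n_reps_per_condition: int = 2
    seed: int | None = None
    name: str = "scenario"

    def __post_init__(self) -> None:
        self.clusters = tuple(self.clusters)
        self.true_props = {c: np.asarray(v, dtype=float) for c, v in self.true_props.items()}
        if len(self.true_props) < 2:
            raise ValueError("a scenario needs at least two conditions")
        for cond, v in self.true_props.items():
            if v.shape != (len(self.clusters),):
                raise ValueError(f"proportion vector for {cond!r} has wrong length")
            if not np.isclose(v.sum(), 1.0, atol=1e-9):
                raise ValueError(f"true proportions for {cond!r} must sum to 1")
            if ((v <= 0) | (v >= 1)).any():
                raise ValueError(
                    "true proportions must lie strictly inside (0, 1): the beta "
                    "distribution is undefined at 0 and 1"
                )
        if not 0 <= self.beta_spread < 1:
            raise ValueError("beta_spread must lie in [0, 1)")
        if self.n_reps_per_condition < 1:
            raise ValueError("need at least one replicate per condition")

    @property
    def conditions(self) -> list[str]:
        return list(self.true_props)

    @property
    def changed_mask(self) -> pd.Series:
        """True for clusters whose true proportion differs between conditions."""
        mat = np.stack([self.true_props[c] for c in self.conditions])
        changed = ~np.all(np.isclose(mat, mat[0], atol=1e-12), axis=0)
        return pd.Series(changed, index=list(self.clusters), name="changed")


@dataclass
class SimulatedDataset:
    counts: CountMatrix
    changed_mask: pd.Series

    def to_cell_table(self) -> CellTable:
        """Expand counts to one row per cell (for cell-level pipelines)."""
        frames = []
        counts = self.counts.counts
        for sample in counts.index:
            row = counts.loc[sample]
            n = int(row.sum())
            frames.append(
                pd.DataFrame(
                    {
                        SAMPLE: sample,
                        CLUSTER: np.repeat(row.index.to_numpy(), row.to_numpy()),
                        CONDITION: self.counts.conditions[sample],
                    }
                )
            )
        return CellTable(pd.concat(frames, ignore_index=True))


def _beta_params(p: np.ndarray, phi: float) -> tuple[np.ndarray, np.ndarray]:
    nu = 1.0 / phi - 1.0
    return p * nu, (1.0 - p) * nu


def simulate_dataset(
    scenario: SimScenario,
    rng: np.random.Generator | int | None = None,
    exact_multinomial: bool = False,
) -> SimulatedDataset:
    """Draw one dataset from the scenario's NB -> beta -> binomial hierarchy."""
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    k = len(scenario.clusters)
    rows, sample_ids, sample_conds = [], [], []
    size = scenario.nb_dispersion
    p_nb = size / (size + scenario.mu)
    for cond in scenario.conditions:
        props = scenario.true_props[cond]
        for j in range(scenario.n_reps_per_condition):
            n_j = int(rng.negative_binomial(size, p_nb))
            if scenario.beta_spread > 0:
                a, b = _beta_params(props, scenario.beta_spread)
                p_ij = rng.beta(a, b)
            else:
                p_ij = props.copy()
            if exact_multinomial:
                counts = rng.multinomial(n_j, p_ij / p_ij.sum())
            else:
                counts = rng.binomial(n_j, p_ij)
            rows.append(counts)
            sample_ids.append(f"{cond}_rep{j + 1}")
            sample_conds.append(cond)

    counts = pd.DataFrame(np.asarray(rows), index=sample_ids, columns=list(scenario.clusters))
    counts.index.name = SAMPLE
    counts.columns.name = CLUSTER
    conditions = pd.Series(sample_conds, index=sample_ids, name=CONDITION)
    return SimulatedDataset(CountMatrix(counts, conditions), scenario.changed_mask)


def make_null_scenario(
    n_reps: int,
    target_cells_per_condition: int = DEFAULT_TARGET_CELLS,
    seed: int | None = None,
) -> SimScenario:
    """Two conditions, five equal clusters, no true change (specificity test)."""
    props = np.asarray(NULL_PROPS)
    return SimScenario(
        clusters=tuple(f"C{i + 1}" for i in range(len(props))),
        true_props={"cond1": props, "cond2": props.copy()},
        mu=target_cells_per_condition / n_reps,
        n_reps_per_condition=n_reps,
        seed=seed,
        name="null",
    )


def make_changed_scenario(
    n_reps: int,
    target_cells_per_condition: int = DEFAULT_TARGET_CELLS,
    seed: int | None = None,
) -> SimScenario:
    """Two conditions, seven clusters, three changed (sensitivity test)."""
    return SimScenario(
        clusters=CHANGED_CLUSTERS,
        true_props={
            "cond1": np.asarray(CHANGED_PROPS_A),
            "cond2": np.asarray(CHANGED_PROPS_B),
        },
        mu=target_cells_per_condition / n_reps,
        n_reps_per_condition=n_reps,
        seed=seed,
        name="changed",
    )


def merge_replicates(dataset: SimulatedDataset) -> SimulatedDataset:
    """Sum counts over replicates, leaving one (merged) sample per condition."""
    counts = dataset.counts.counts
    conds = dataset.counts.conditions
    levels = list(pd.unique(conds))
    merged = pd.DataFrame(
        [counts.loc[(conds == c).values].sum(axis=0) for c in levels],
        index=levels,
    ).astype(int)
    merged.index.name = SAMPLE
    merged.columns.name = CLUSTER
    conditions = pd.Series(levels, index=levels, name=CONDITION)
    return SimulatedDataset(CountMatrix(merged, conditions), dataset.changed_mask.copy())
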