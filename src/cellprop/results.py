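"""Results container, TSV round trip and proportion plots."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cell_table import ValidationError

__all__ = ["ResultsTable", "write_results", "read_results", "plot_proportions"]

#: clusters holding less than this fraction of all cells get a caution flag
LOW_COUNT_FRACTION = 0.02

#: fixed column order of the results table
RESULT_COLUMNS = (
    "effect",
    "statistic",
    "p_value",
    "p_adjusted",
    "significant",
    "low_count",
)


@dataclass
class ResultsTable:
    """Per-cluster proportion-analysis results plus run metadata.

    ``table`` has one row per cluster: the mean observed proportion per
    condition (``prop_<condition>`` columns), the transformed-scale effect,
    the moderated statistic (NaN in bootstrap mode, where the reported
    p-value is a median over iterations rather than a single test), raw and
    BH-adjusted p-values, the significance flag (adjusted p < 0.05) and a
    ``low_count`` caution flag for clusters below 2% of all cells.
    """

    table: pd.DataFrame
    metadata: dict
    sample_props: pd.DataFrame | None = None
    sample_conditions: pd.Series | None = None

    @property
    def clusters(self) -> list[str]:
        return list(self.table.index)

    @property
    def significant_clusters(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def write_results(results: ResultsTable, path) -> None:
    """Write the results table as TSV with metadata in commented header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for key in sorted(results.metadata):
            fh.write(f"# {key}: {results.metadata[key]}\n")
        # %.17g round-trips float64 exactly
        results.table.to_csv(fh, sep="\t", index_label="cluster", float_format="%.17g")


def read_results(path) -> ResultsTable:
    """Read a results TSV written by :func:`write_results`."""
    path = Path(path)
    metadata = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("# "):
                break
            skip += 1
            key, _, value = line[2:].rstrip("\n").partition(": ")
            metadata[key] = value
    table = pd.read_csv(
        path, sep="\t", skiprows=skip, index_col="cluster", float_precision="round_trip"
    )
    return ResultsTable(table=table, metadata=metadata)


def plot_proportions(results: ResultsTable, path, props: pd.DataFrame | None = None,
                     conditions: pd.Series | None = None):
    """One box-plot panel per cluster: per-condition sample proportions.

    ``props``/``conditions`` default to the sample proportions stored on the
    results (pseudo-replicate proportions in bootstrap mode, marked as
    simulated in the panel).  Each panel is annotated with the cluster's
    BH-adjusted p-value.  The figure is written to ``path`` (format from the
    extension, e.g. .png or .svg).
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    import seaborn as sns

    if props is None:
        props = results.sample_props
        conditions = results.sample_conditions
    if props is None or conditions is None:
        raise ValidationError("no sample proportions available to plot")
    missing = [c for c in results.clusters if c not in props.columns]
    if missing:
        raise ValidationError(f"proportion matrix lacks cluster(s): {missing}")

    simulated = str(results.metadata.get("mode", "")) == "bootstrapped"
    clusters = results.clusters
    n = len(clusters)
    ncols = min(n, 4)
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.0 * ncols, 3.0 * nrows), squeeze=False)
    long = props.copy()
    long["__cond"] = conditions.loc[props.index].values
    for ax, cluster in zip(axes.ravel(), clusters):
        sns.boxplot(x="__cond", y=cluster, data=long, ax=ax, color="#c6dbef")
        sns.stripplot(
            x="__cond", y=cluster, data=long, ax=ax, color="#d95f02" if simulated else "#333333",
            size=4, marker="s" if simulated else "o",
        )
        padj = results.table.loc[cluster, "p_adjusted"]
        label = f"{cluster}\nadj p = {padj:.3g}"
        if simulated:
            label += " (pseudo-replicates)"
        ax.set_title(label, fontsize=9)
        ax.set_xlabel("")
        ax.set_ylabel("proportion")
    for ax in axes.ravel()[n:]:
        ax.set_visible(False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)
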