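"""Cell annotation tables, sample x cluster count matrices and design matrices.

The entry point of a proportion analysis is a table with one row per cell,
carrying at least a sample (replicate) label, a cluster / cell-type label and
an experimental condition label.  Samples are nested in conditions: every
sample belongs to exactly one condition.  From this table we tabulate a
samples x clusters count matrix and build the design matrix for the
cluster-wise linear models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CellTable",
    "CountMatrix",
    "DesignMatrix",
    "read_cell_table",
    "tabulate_counts",
    "build_design",
]

# canonical internal column names
SAMPLE = "sample"
CLUSTER = "cluster"
CONDITION = "condition"


class ConfigurationError(ValueError):
    """A required column or option is missing or inconsistent."""


class ValidationError(ValueError):
    """The data violate an invariant of the analysis (e.g. sample nesting)."""


@dataclass
class CellTable:
    """One row per cell with sample, cluster and condition labels.

    ``data`` uses the canonical column names ``sample``, ``cluster`` and
    ``condition``; any further columns listed in ``covariates`` are per-sample
    covariates.  Label order is first appearance in the input, never sorted.
    """

    data: pd.DataFrame
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.covariates = tuple(self.covariates)
        missing = [c for c in (SAMPLE, CLUSTER, CONDITION) if c not in self.data.columns]
        if missing:
            raise ConfigurationError(f"cell table lacks required columns: {missing}")
        for cov in self.covariates:
            if cov not in self.data.columns:
                raise ConfigurationError(f"covariate column not found: {cov!r}")
        core = self.data[[SAMPLE, CLUSTER, CONDITION]]
        if core.isna().any().any():
            bad = core.columns[core.isna().any()].tolist()
            raise ValidationError(
                f"cells with missing labels in column(s) {bad}; proportion analysis "
                "is sensitive to denominator changes, drop or fix them explicitly"
            )
        # samples nested in conditions
        n_cond = self.data.groupby(SAMPLE, sort=False)[CONDITION].nunique()
        offenders = n_cond.index[n_cond > 1].tolist()
        if offenders:
            raise ValidationError(
                f"sample(s) mapped to more than one condition: {offenders}"
            )

    @property
    def samples(self) -> list[str]:
        return list(pd.unique(self.data[SAMPLE]))

    @property
    def clusters(self) -> list[str]:
        return list(pd.unique(self.data[CLUSTER]))

    @property
    def conditions(self) -> list[str]:
        return list(pd.unique(self.data[CONDITION]))

    @property
    def sample_conditions(self) -> pd.Series:
        """Sample -> condition map, in first-appearance sample order."""
        sub = self.data.drop_duplicates(SAMPLE, keep="first")
        return pd.Series(sub[CONDITION].values, index=sub[SAMPLE].values, name=CONDITION)

    def sample_covariates(self) -> pd.DataFrame:
        """Per-sample covariate values; covariates must be constant within sample."""
        if not self.covariates:
            return pd.DataFrame(index=pd.Index(self.samples, name=SAMPLE))
        for cov in self.covariates:
            nun = self.data.groupby(SAMPLE, sort=False)[cov].nunique(dropna=False)
            bad = nun.index[nun > 1].tolist()
            if bad:
                raise ValidationError(
                    f"covariate {cov!r} varies within sample(s) {bad}; covariates "
                    "are per-sample in this model"
                )
        sub = self.data.drop_duplicates(SAMPLE, keep="first")
        out = sub.set_index(SAMPLE)[list(self.covariates)]
        return out.loc[self.samples]

    def restrict_conditions(self, conditions: list[str]) -> "CellTable":
        unknown = [c for c in conditions if c not in self.conditions]
        if unknown:
            raise ConfigurationError(f"unknown condition(s): {unknown}")
        mask = self.data[CONDITION].isin(conditions)
        return CellTable(self.data.loc[mask].reset_index(drop=True), self.covariates)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class CountMatrix:
    """Samples x clusters cell counts plus the sample -> condition map."""

    counts: pd.DataFrame  # integer, samples x clusters
    conditions: pd.Series  # index: sample ids, values: condition labels

    def __post_init__(self) -> None:
        if not self.counts.index.equals(pd.Index(self.conditions.index)):
            self.conditions = self.conditions.loc[self.counts.index]
        if (np.asarray(self.counts) < 0).any():
            raise ValidationError("negative cell counts")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def clusters(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def condition_levels(self) -> list[str]:
        return list(pd.unique(self.conditions))

    def restrict_conditions(self, conditions: list[str]) -> "CountMatrix":
        unknown = [c for c in conditions if c not in self.condition_levels]
        if unknown:
            raise ConfigurationError(f"unknown condition(s): {unknown}")
        keep = self.conditions.isin(conditions)
        return CountMatrix(self.counts.loc[keep.values], self.conditions.loc[keep.values])

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, CONDITION, self.conditions.values)
        out.to_csv(path, sep="\t", index_label=SAMPLE)


@dataclass
class DesignMatrix:
    """Samples x terms numeric design with group-means condition coding.

    The first ``len(condition_terms)`` columns are 0/1 condition indicators
    (one per condition level, no intercept), so coefficients are condition
    means; covariate columns follow as nuisance terms.
    """

    frame: pd.DataFrame
    condition_terms: tuple[str, ...]
    covariate_terms: tuple[str, ...] = ()

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def terms(self) -> list[str]:
        return list(self.frame.columns)


def read_cell_table(
    path,
    sample_col: str,
    cluster_col: str,
    cond_col: str,
    covariate_cols: list[str] | None = None,
) -> CellTable:
    """Read a per-cell annotation table from delimited text or an .h5ad file.

    For ``.h5ad`` only the observation (per-cell metadata) table is read.
    Delimiter is inferred from the extension (``.csv`` -> comma, otherwise tab).
    Labels are coerced to strings; category order is first appearance.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    covariate_cols = list(covariate_cols or [])
    if path.suffix == ".h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path, backed="r")
        try:
            obs = adata.obs.copy()
        finally:
            if adata.isbacked and adata.file is not None:
                adata.file.close()
        frame = obs.reset_index(drop=True)
    else:
        sep = "," if path.suffix == ".csv" else "\t"
        frame = pd.read_csv(path, sep=sep)

    rename = {sample_col: SAMPLE, cluster_col: CLUSTER, cond_col: CONDITION}
    for arg, col in (("sample_col", sample_col), ("cluster_col", cluster_col), ("cond_col", cond_col)):
        if col not in frame.columns:
            raise ConfigurationError(f"{arg}={col!r} not found in {path.name} columns")
    for cov in covariate_cols:
        if cov not in frame.columns:
            raise ConfigurationError(f"covariate column {cov!r} not found in {path.name}")
    frame = frame[[sample_col, cluster_col, cond_col, *covariate_cols]].rename(columns=rename)
    for col in (SAMPLE, CLUSTER, CONDITION):
        frame[col] = frame[col].astype(str)
    return CellTable(frame, tuple(covariate_cols))


def tabulate_counts(cells: CellTable) -> CountMatrix:
    """Tabulate cells into a samples x clusters count matrix.

    Entry (s, k) is the number of cells of sample s in cluster k; clusters
    absent from a sample get 0.  Row and column order follow first appearance.
    """
    if len(cells) == 0:
        raise ValidationError("no cells")
    samples = cells.samples
    clusters = cells.clusters
    tab = pd.crosstab(cells.data[SAMPLE], cells.data[CLUSTER])
    tab = tab.reindex(index=samples, columns=clusters, fill_value=0).astype(int)
    tab.index.name = SAMPLE
    tab.columns.name = CLUSTER
    return CountMatrix(tab, cells.sample_conditions)


def design_from_samples(
    conditions: pd.Series,
    covariates: pd.DataFrame | None = None,
    conditions_to_compare: list[str] | None = None,
) -> DesignMatrix:
    """Build a group-means design from a sample -> condition map.

    One 0/1 indicator column per condition level (no intercept); categorical
    covariates expand to k-1 indicators against their first-appearance level,
    numeric covariates enter as given.
    """
    conditions = pd.Series(conditions)
    if conditions_to_compare is not None:
        unknown = [c for c in conditions_to_compare if c not in set(conditions)]
        if unknown:
            raise ConfigurationError(f"unknown condition(s): {unknown}")
        keep = conditions.isin(conditions_to_compare)
        conditions = conditions.loc[keep]
        if covariates is not None:
            covariates = covariates.loc[conditions.index]
        levels = [c for c in conditions_to_compare]
    else:
        levels = list(pd.unique(conditions))
    if len(levels) < 2:
        raise ConfigurationError(
            f"need at least 2 condition levels to compare, got {levels}"
        )

    cols = {}
    for lev in levels:
        cols[lev] = (conditions == lev).astype(float).values
    frame = pd.DataFrame(cols, index=conditions.index)

    covariate_terms: list[str] = []
    if covariates is not None and covariates.shape[1] > 0:
        for cov in covariates.columns:
            col = covariates[cov]
            if pd.api.types.is_numeric_dtype(col):
                frame[cov] = col.astype(float).values
                covariate_terms.append(cov)
            else:
                cov_levels = list(pd.unique(col.astype(str)))
                for lev in cov_levels[1:]:  # first level is reference
                    term = f"{cov}[{lev}]"
                    frame[term] = (col.astype(str) == lev).astype(float).values
                    covariate_terms.append(term)

    design = DesignMatrix(frame, tuple(levels), tuple(covariate_terms))
    rank = np.linalg.matrix_rank(design.values)
    if rank < design.frame.shape[1]:
        # identify a term whose removal restores full rank
        for term in reversed(design.terms):
            reduced = design.frame.drop(columns=[term]).to_numpy(dtype=float)
            if np.linalg.matrix_rank(reduced) == reduced.shape[1]:
                raise ValidationError(
                    f"design matrix is rank deficient: term {term!r} is confounded "
                    "with the other model terms"
                )
        raise ValidationError("design matrix is rank deficient")
    return design


def build_design(
    cells: CellTable,
    conditions_to_compare: list[str] | None = None,
) -> DesignMatrix:
    """Build the design matrix for a cell table (see :func:`design_from_samples`)."""
    covariates = cells.sample_covariates() if cells.covariates else None
    return design_from_samples(cells.sample_conditions, covariates, conditions_to_compare)
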