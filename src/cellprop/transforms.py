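"""Proportion matrices and variance-stabilizing transforms.

Cluster proportions are binomial fractions, so their variance depends on the
mean (heteroskedastic).  Two classical stabilizers are supported:

* ``logit``:  log(p / (1 - p)) — undefined at 0 and 1, so counts get a 0.5
  pseudo-count before normalization (the limma/propeller convention);
* ``arcsin``: arcsin(sqrt(p)) — defined on [0, 1], approximately constant
  variance 1/(4n) for binomial fractions; the package default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cell_table import CountMatrix, ValidationError

__all__ = [
    "TRANSFORMS",
    "to_proportions",
    "transform_logit",
    "transform_arcsin",
    "transform_counts",
    "PSEUDO_COUNTS",
]

TRANSFORMS = ("arcsin", "logit")

#: pseudo-count added to every cell count before normalization, per transform
PSEUDO_COUNTS = {"arcsin": 0.0, "logit": 0.5}


def to_proportions(counts, pseudo_count: float = 0.0) -> pd.DataFrame:
    """Row-normalize counts to proportions, optionally after a pseudo-count.

    Entry (s, k) = (count + pseudo_count) / sum_k(count + pseudo_count), so each
    row sums to one.
    """
    if pseudo_count < 0:
        raise ValueError("pseudo_count must be >= 0")
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    frame = pd.DataFrame(counts).astype(float)
    shifted = frame + pseudo_count
    totals = shifted.sum(axis=1)
    if (totals <= 0).any():
        bad = list(frame.index[totals <= 0])
        raise ValidationError(
            f"sample(s) with zero total count and pseudo_count=0: {bad}"
        )
    props = shifted.div(totals, axis=0)
    props.attrs["transform"] = None
    return props


def transform_logit(props: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log(p / (1 - p)); requires entries strictly inside (0, 1)."""
    p = np.asarray(props, dtype=float)
    if ((p <= 0) | (p >= 1)).any():
        raise ValidationError(
            "logit is undefined at proportions of exactly 0 or 1; normalize the "
            "counts with a pseudo-count (to_proportions(..., pseudo_count=0.5))"
        )
    out = pd.DataFrame(np.log(p / (1.0 - p)), index=props.index, columns=props.columns)
    out.attrs["transform"] = "logit"
    return out


def transform_arcsin(props: pd.DataFrame) -> pd.DataFrame:
    """Elementwise arcsin(sqrt(p)), mapping [0, 1] onto [0, pi/2]."""
    p = np.asarray(props, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("proportions outside [0, 1]")
    out = pd.DataFrame(np.arcsin(np.sqrt(p)), index=props.index, columns=props.columns)
    out.attrs["transform"] = "arcsin"
    return out


def transform_counts(counts, method: str = "arcsin") -> pd.DataFrame:
    """Counts -> transformed proportions with the method's pseudo-count rule."""
    if method not in TRANSFORMS:
        raise ValueError(f"unknown transform {method!r}; choose from {TRANSFORMS}")
    props = to_proportions(counts, pseudo_count=PSEUDO_COUNTS[method])
    return transform_logit(props) if method == "logit" else transform_arcsin(props)
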