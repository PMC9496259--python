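"""Composite scores collapsing several assay columns into one DAG concept.

When a dataset carries multiple measures of a single node (e.g. several
microarchitecture indices all reflecting trabecular quality), the measures
are standardized and projected onto their first principal component.  The
component's sign is arbitrary, so the score is oriented to correlate
positively with a designated anchor column; the anchor should be a measure
whose direction of "more of the concept" is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .stats import InsufficientDataError

__all__ = ["CompositeSpec", "CompositeResult", "composite_score"]


@dataclass(frozen=True)
class CompositeSpec:
    node: str
    columns: tuple[str, ...]
    anchor: str

    def __post_init__(self):
        if not self.columns:
            raise ValueError("composite needs at least one column")
        object.__setattr__(self, "columns", tuple(self.columns))
        if self.anchor not in self.columns:
            raise ValueError(f"anchor {self.anchor!r} must be one of the columns")


@dataclass
class CompositeResult:
    scores: pd.Series          # indexed by the complete-case rows
    explained_variance: float  # fraction carried by the first component
    loadings: pd.Series        # first-component weights on standardized columns


def composite_score(data: pd.DataFrame, spec: CompositeSpec) -> CompositeResult:
    """First-principal-component score over standardized columns.

    Columns are centred and scaled to unit variance (correlation-matrix PCA),
    so the composite is invariant to affine rescaling of any input measure.
    Rows with any missing input are dropped; the returned series is indexed by
    the retained rows.
    """
    missing = [c for c in spec.columns if c not in data.columns]
    if missing:
        raise KeyError(f"composite columns not in dataset: {missing}")
    sub = data.loc[:, list(spec.columns)].dropna()
    if len(sub) < 3:
        raise InsufficientDataError(
            f"composite {spec.node!r} needs >= 3 complete rows, got {len(sub)}"
        )
    values = sub.to_numpy(dtype=float)
    sd = values.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [c for c, s in zip(spec.columns, sd) if s == 0]
        raise InsufficientDataError(f"constant composite columns: {bad}")
    standardized = (values - values.mean(axis=0)) / sd

    if len(spec.columns) == 1:
        scores = standardized[:, 0]
        loadings = np.array([1.0])
        explained = 1.0
    else:
        _, svals, vt = np.linalg.svd(standardized, full_matrices=False)
        loadings = vt[0]
        scores = standardized @ loadings
        var = svals**2
        explained = float(var[0] / var.sum())

    anchor_idx = spec.columns.index(spec.anchor)
    anchor_corr = np.corrcoef(scores, standardized[:, anchor_idx])[0, 1]
    if anchor_corr < 0:
        scores = -scores
        loadings = -loadings

    return CompositeResult(
        scores=pd.Series(scores, index=sub.index, name=spec.node),
        explained_variance=explained,
        loadings=pd.Series(loadings, index=list(spec.columns)),
    )


def explained_variance_spectrum(data: pd.DataFrame, columns: Sequence[str]) -> np.ndarray:
    """Per-component explained-variance fractions (sums to 1)."""
    sub = data.loc[:, list(columns)].dropna().to_numpy(dtype=float)
    standardized = (sub - sub.mean(axis=0)) / sub.std(axis=0, ddof=1)
    svals = np.linalg.svd(standardized, compute_uv=False)
    var = svals**2
    return var / var.sum()
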