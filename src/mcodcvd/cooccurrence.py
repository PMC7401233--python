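"""Cause co-mention structure of CVD multiple-cause deaths via PCA.

Each premature (35-74) CVD MCOD death contributes a row of 0/1 indicators
over the tracked cause list; PCA is run on the Pearson correlation matrix
of those indicators (the phi-coefficient matrix — mention prevalences span
orders of magnitude, so covariance PCA would be dominated by the common
causes).  The scientific question is whether the five DKOLH causes load
together on one component, i.e. form a mutually correlated cluster
consistent with a shared underlying risk factor.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import DKOLH_COMPONENTS, CauseSetConfig, classify_frame
from .types import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class MentionMatrix:
    """Binary cause-mention indicators: rows = CVD MCOD deaths, columns = causes."""

    values: pd.DataFrame
    dkolh_flags: dict[str, bool]

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if not np.isin(v, (0, 1)).all():
            raise ValidationError("mention matrix entries must be 0/1")

    @property
    def causes(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    def degenerate_columns(self) -> list[str]:
        """Zero-variance columns (never or always mentioned) — unusable in PCA."""
        v = self.values
        return [c for c in v.columns if v[c].nunique() < 2]


def build_mention_matrix(
    classified: pd.DataFrame,
    config: CauseSetConfig,
    window: tuple[int, int] = (35, 75),
) -> MentionMatrix:
    """Mention indicators for CVD MCOD deaths in the age window.

    Duplicate mentions are already collapsed by classification (presence/
    absence).  Raises if the selection is empty.
    """
    lo, hi = window
    sub = classified[
        classified["cvd_mcod"] & (classified["age"] >= lo) & (classified["age"] < hi)
    ]
    if sub.empty:
        raise ValidationError(f"no CVD MCOD deaths in age window {window}")
    cols = {name: sub[f"has_{name}"].astype(int).to_numpy() for name in config.tracked}
    values = pd.DataFrame(cols, index=sub.index)
    flags = {name: name in DKOLH_COMPONENTS for name in config.tracked}
    return MentionMatrix(values, flags)


@dataclass
class PcaResult:
    """Eigenvalues (descending) and loadings of the indicator correlation matrix.

    ``loadings`` is causes x components (columns PC1, PC2, ...), each
    component sign-oriented so its largest-|loading| cause is positive.
    ``dropped`` lists degenerate causes excluded before the decomposition.
    Eigenvalues sum to the number of retained causes.
    """

    eigenvalues: np.ndarray
    loadings: pd.DataFrame
    dropped: list[str] = field(default_factory=list)

    def ranked_causes(self, component: int) -> list[str]:
        """Causes ranked by |loading| on a component (ties broken by cause order)."""
        col = self.loadings.iloc[:, component]
        order = np.argsort(-np.abs(col.to_numpy()), kind="stable")
        return [col.index[i] for i in order]


def pca_correlation(matrix: MentionMatrix) -> PcaResult:
    """PCA of the phi (Pearson) correlation matrix of mention indicators.

    Degenerate (zero-variance) columns are dropped with a warning.  The
    symmetric eigendecomposition guarantees real eigenvalues and
    orthonormal loadings.
    """
    dropped = matrix.degenerate_columns()
    if dropped:
        msg = f"dropping degenerate cause columns before PCA: {dropped}"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    keep = [c for c in matrix.causes if c not in dropped]
    if len(keep) < 2:
        raise ValidationError("PCA needs at least 2 non-degenerate cause columns")
    v = matrix.values[keep].to_numpy(dtype=float)
    corr = np.corrcoef(v, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    # orient each component: largest-|loading| entry positive (first such
    # entry in cause order on ties)
    for j in range(eigvecs.shape[1]):
        col = eigvecs[:, j]
        i = int(np.argmax(np.abs(np.round(col, 12))))
        if col[i] < 0:
            eigvecs[:, j] = -col
    loadings = pd.DataFrame(
        eigvecs, index=keep, columns=[f"PC{j + 1}" for j in range(len(keep))]
    )
    return PcaResult(eigenvalues=eigvals, loadings=loadings, dropped=dropped)


def dkolh_cluster_rank(
    result: PcaResult,
    dkolh_causes: Sequence[str] = DKOLH_COMPONENTS,
    top: int = 5,
) -> tuple[list[int], int]:
    """How many DKOLH causes sit among the top-``top`` |loadings| of each component.

    Returns (per-component counts, index of the first component achieving
    the maximum count).  A count of 5 on some component reproduces the
    clustered-causes signature; a sepsis-like component may still carry the
    largest eigenvalue.
    """
    if len(result.loadings) < top:
        raise ValidationError(f"need >= {top} causes for a top-{top} ranking")
    present = [c for c in dkolh_causes if c in result.loadings.index]
    counts = []
    for j in range(result.loadings.shape[1]):
        ranked = result.ranked_causes(j)[:top]
        counts.append(sum(1 for c in ranked if c in present))
    best = int(np.argmax(counts))
    return counts, best
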