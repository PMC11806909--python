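"""Spearman rank correlation matrices for bootstrap replicates.

Spearman's coefficient is the Pearson correlation of average (fractional)
ranks, so it is invariant under strictly increasing transforms of either
variable — the right association measure when only the ordering of
abundances is trusted.  Ties receive average ranks (the tie-corrected
convention of mainstream statistics routines).

Bootstrap resampling of sparse count data frequently produces constant
columns, for which the coefficient is undefined.  Such pairs are recorded as
0 (they can never form an edge) and the event is logged as a degeneracy
rather than silently propagating NaN into downstream thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .resample import ReplicateSet
from .tables import FeatureTable

__all__ = [
    "CorrelationMatrix",
    "spearman",
    "correlation_matrix",
    "average_correlation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric feature x feature matrix of Spearman coefficients.

    ``degenerate_features`` lists features that were constant in the source
    replicate; their off-diagonal entries are 0 by convention.
    """

    feature_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    method: str = "spearman"
    degenerate_features: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))
        object.__setattr__(self, "degenerate_features", tuple(self.degenerate_features))
        values = np.asarray(self.values, dtype=float)
        p = len(self.feature_ids)
        if values.shape != (p, p):
            raise ValueError(f"expected {p}x{p} matrix, got {values.shape}")
        if not np.allclose(values, values.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if np.any(np.abs(values) > 1 + 1e-12):
            raise ValueError("correlation values must lie in [-1, 1]")
        object.__setattr__(self, "values", values)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(), index=list(self.feature_ids), columns=list(self.feature_ids)
        )

    def write_csv(self, path: str | Path) -> None:
        """Square labeled CSV export (header row and index column)."""
        self.to_frame().to_csv(path, index=True, index_label="feature_id")


def spearman(x: Sequence[float], y: Sequence[float]) -> float | None:
    """Spearman rank correlation of two vectors; None when undefined.

    Computed as the Pearson correlation of average ranks.  Returns None if
    either vector is constant (zero rank variance).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    rx = rankdata(x)
    ry = rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    r = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    return float(np.clip(r, -1.0, 1.0))


def _spearman_matrix(table: FeatureTable) -> CorrelationMatrix:
    """Pairwise Spearman matrix of one table, zeroing degenerate pairs."""
    values = table.values
    p = values.shape[1]
    ranks = rankdata(values, axis=0)
    centered = ranks - ranks.mean(axis=0, keepdims=True)
    sd = np.sqrt((centered**2).sum(axis=0))
    constant = sd == 0

    corr = np.zeros((p, p))
    ok = ~constant
    if ok.sum() >= 1:
        sub = centered[:, ok]
        denom = np.outer(sd[ok], sd[ok])
        corr[np.ix_(ok, ok)] = (sub.T @ sub) / denom
    np.fill_diagonal(corr, 1.0)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)

    degenerate = tuple(fid for fid, c in zip(table.feature_ids, constant) if c)
    if degenerate:
        logger.warning(
            "constant column(s) in replicate: %s; their correlations set to 0",
            ", ".join(degenerate),
        )
    return CorrelationMatrix(table.feature_ids, corr, "spearman", degenerate)


def correlation_matrix(
    replicates: ReplicateSet | Iterable[FeatureTable],
) -> list[CorrelationMatrix]:
    """One Spearman correlation matrix per replicate, in replicate order."""
    tables = list(replicates)
    if not tables:
        raise ValueError("no replicates given")
    if tables[0].n_features < 2:
        raise ValueError("need at least 2 features to correlate")
    return [_spearman_matrix(t) for t in tables]


def average_correlation(matrices: Sequence[CorrelationMatrix]) -> CorrelationMatrix:
    """Element-wise mean of correlation matrices sharing a feature set.

    The averaged matrix consolidates the bootstrap replicates into the single
    consensus matrix used for network rendering; symmetry and the [-1, 1]
    bounds are preserved by linearity.
    """
    if not matrices:
        raise ValueError("no matrices to average")
    ids = matrices[0].feature_ids
    for m in matrices[1:]:
        if m.feature_ids != ids:
            raise ValueError("matrices have mismatched feature sets")
    mean = np.mean([m.values for m in matrices], axis=0)
    degenerate = tuple(sorted({f for m in matrices for f in m.degenerate_features}))
    return CorrelationMatrix(ids, mean, matrices[0].method, degenerate)
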