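"""Quantile normalization and cross-platform distribution matching.

Two operations:

* :func:`quantile_normalize` — classic within-matrix quantile
  normalization: every column is forced onto the common distribution of
  per-rank means, preserving within-column rank order.
* :func:`crossplatform_normalize` — maps each column of a target matrix
  onto the pooled empirical distribution of a reference compendium, so
  profiles from a different platform share the reference's ECDF before
  deconvolution against a signature built on that reference.

Ranks use the average-rank convention for ties in both operations, so tied
input values always receive identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def quantile_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns of an expression matrix.

    After the transform every column holds the same multiset of values:
    the per-rank means of the input's sorted columns.  Row and column
    labels are preserved; a single-column input is returned unchanged with
    a warning.  The operation is idempotent and rank-preserving.
    """
    X = expr.to_numpy(dtype=float)
    if X.shape[1] < 2:
        warnings.warn("quantile_normalize: single sample, returning input unchanged", stacklevel=2)
        return expr.copy()
    rank_means = np.sort(X, axis=0).mean(axis=1)
    n = X.shape[0]
    out = np.empty_like(X)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(X.shape[1]):
        ranks = stats.rankdata(X[:, j], method="average")
        # average ranks of ties fall between integer positions; linear
        # interpolation assigns the mean of the tied rank means
        out[:, j] = np.interp(ranks, positions, rank_means)
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


@dataclass
class ReferencePool:
    """Pooled empirical distribution of a reference expression compendium."""

    sorted_values: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.sorted_values, dtype=float).ravel()
        if v.size == 0:
            raise ValueError("reference pool is empty")
        if not np.isfinite(v).all():
            raise ValueError("reference pool contains non-finite values")
        self.sorted_values = np.sort(v)

    @classmethod
    def from_matrix(cls, expr: pd.DataFrame, source: str = "") -> "ReferencePool":
        """Pool every entry of a reference expression matrix."""
        return cls(expr.to_numpy(dtype=float).ravel(), source=source)

    def quantile(self, q: np.ndarray) -> np.ndarray:
        """Pool quantile by linear interpolation between order statistics.

        Order statistic k (1-based) of m sits at probability (k - 0.5)/m;
        probabilities outside that range clamp to the pool min/max.
        """
        m = self.sorted_values.size
        probs = (np.arange(m) + 0.5) / m
        return np.interp(q, probs, self.sorted_values)


def crossplatform_normalize(target: pd.DataFrame, pool: ReferencePool) -> pd.DataFrame:
    """Map each target column onto the reference pool's empirical distribution.

    Within each sample, a value at average-rank r of n is replaced by the
    pool quantile at (r - 0.5)/n.  Rank order within a sample is preserved
    and outputs lie within [pool min, pool max].  A constant column maps
    entirely to the pool median (with a warning).
    """
    X = target.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("crossplatform_normalize: target contains non-finite values")
    n = X.shape[0]
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.ptp(col) == 0.0:
            warnings.warn(
                f"crossplatform_normalize: sample {target.columns[j]!r} is constant; "
                "mapping all values to the pool median",
                stacklevel=2,
            )
        ranks = stats.rankdata(col, method="average")
        out[:, j] = pool.quantile((ranks - 0.5) / n)
    return pd.DataFrame(out, index=target.index, columns=target.columns)
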