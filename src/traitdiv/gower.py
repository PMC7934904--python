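"""Weighted Gower dissimilarity for mixed continuous/binary trait matrices.

The dissimilarity between species *i* and *j* is the weighted mean of
per-column contributions,

    d(i, j) = sum_c w_c * delta_c(i, j) / sum_c w_c,

where for continuous columns delta_c = |x_ic - x_jc| / range_c with the
range taken over the *full* table (so a shared trait space built from a
species union is self-consistent), and for binary columns delta_c is the
symmetric mismatch |x_ic - x_jc|.  An asymmetric binary mode (double-zero
pairs excluded from the weighted mean, Jaccard-style) is available.
All dissimilarities lie in [0, 1], with zero diagonal.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .traits import CONTINUOUS_COLUMNS, TraitTable, equal_group_weights


def _as_frame(table) -> pd.DataFrame:
    return table.data if isinstance(table, TraitTable) else pd.DataFrame(table)


def gower_matrix(
    table,
    weights: pd.Series | None = None,
    binary: str = "symmetric",
    ranges: pd.Series | None = None,
) -> pd.DataFrame:
    """Pairwise Gower dissimilarity matrix of a trait table.

    Parameters
    ----------
    table
        :class:`~traitdiv.traits.TraitTable` or DataFrame of encoded traits.
    weights
        Non-negative per-column weights aligned with the table's columns;
        defaults to equal trait-group weights.
    binary
        ``"symmetric"`` treats 0/0 and 1/1 alike (mismatch distance);
        ``"asymmetric"`` removes double-zero binary pairs from the
        weighted mean.
    ranges
        Continuous-column ranges to standardize by.  Defaults to the
        observed range in ``table``; pass the full-union ranges when
        computing distances on a subset so results match subsetting the
        full matrix.

    Zero-range continuous columns carry no information and are dropped
    from the distance (weights renormalized) with a warning.  A table with
    a single species is an error.
    """
    df = _as_frame(table)
    if len(df) < 2:
        raise ValueError("Gower dissimilarity requires at least 2 species")
    if binary not in ("symmetric", "asymmetric"):
        raise ValueError(f"unknown binary mode {binary!r}")
    if weights is None:
        weights = equal_group_weights(table)
    w = pd.Series(weights, dtype=float).reindex(df.columns)
    if w.isna().any():
        raise ValueError(f"weights missing for columns: {w.index[w.isna()].tolist()}")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")

    X = df.to_numpy(float)
    n = len(df)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for k, col in enumerate(df.columns):
        wc = w.iloc[k]
        if wc == 0:
            continue
        x = X[:, k]
        if col in CONTINUOUS_COLUMNS:
            rng = float(ranges[col]) if ranges is not None and col in ranges else float(np.ptp(x))
            if rng == 0:
                warnings.warn(
                    f"continuous column {col!r} has zero range; dropped from "
                    "Gower distance and weights renormalized",
                    stacklevel=2,
                )
                continue
            delta = np.abs(x[:, None] - x[None, :]) / rng
            pair_w = np.full((n, n), wc)
        else:
            delta = np.abs(x[:, None] - x[None, :])
            if binary == "asymmetric":
                both_zero = (x[:, None] == 0) & (x[None, :] == 0)
                pair_w = np.where(both_zero, 0.0, wc)
            else:
                pair_w = np.full((n, n), wc)
        num += pair_w * delta
        den += pair_w
    with np.errstate(invalid="ignore"):
        d = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)  # exact symmetry against fp noise
    return pd.DataFrame(d, index=df.index, columns=df.index)


def continuous_ranges(table) -> pd.Series:
    """Observed range of each continuous trait column."""
    df = _as_frame(table)
    cols = [c for c in df.columns if c in CONTINUOUS_COLUMNS]
    return pd.Series({c: float(np.ptp(df[c].to_numpy(float))) for c in cols}, name="range")


class GowerDistance(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer computing weighted Gower dissimilarities.

    Parameters
    ----------
    equalize_traits : bool, default True
        Equal per-group weighting (each of the six groups totals 1/6);
        False gives uniform per-column weights.
    binary : {"symmetric", "asymmetric"}
        Treatment of binary columns.
    weights : Series, optional
        Explicit per-column weights overriding ``equalize_traits``.

    ``fit`` learns the continuous ranges and column weights from the full
    table; ``transform`` computes the square dissimilarity matrix of any
    species subset against those fitted ranges, so subsetting commutes
    with the distance computation.
    """

    def __init__(self, equalize_traits: bool = True, binary: str = "symmetric", weights=None):
        self.equalize_traits = equalize_traits
        self.binary = binary
        self.weights = weights

    def fit(self, X, y=None) -> "GowerDistance":
        df = _as_frame(X)
        if len(df) < 2:
            raise ValueError("Gower dissimilarity requires at least 2 species")
        self.feature_names_in_ = np.asarray(df.columns, dtype=object)
        self.ranges_ = continuous_ranges(df)
        self.weights_ = (
            pd.Series(self.weights, dtype=float).reindex(df.columns)
            if self.weights is not None
            else equal_group_weights(X if isinstance(X, TraitTable) else df, self.equalize_traits)
        )
        return self

    def transform(self, X) -> pd.DataFrame:
        df = _as_frame(X)
        if list(df.columns) != list(self.feature_names_in_):
            raise ValueError("columns differ from the fitted trait table")
        return gower_matrix(df, weights=self.weights_, binary=self.binary, ranges=self.ranges_)

    def fit_transform(self, X, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)
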