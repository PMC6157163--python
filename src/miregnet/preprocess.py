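"""Expression preprocessing: presence filter, KNN imputation, quantile normalization.

The stages mirror standard microarray practice for merging heterogeneous
chips: drop features with too many lost values, impute the remainder from
their nearest feature rows, log2-transform, and quantile-normalize so
every sample column shares the same value multiset.  Cross-platform batch
correction is a documented no-op hook (:func:`batch_correct`).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionMatrix

_EPS = 1e-9  # additive guard in inverse-distance weights


def filter_presence(m: ExpressionMatrix, min_presence: float = 0.9) -> ExpressionMatrix:
    """Keep features whose fraction of observed values is strictly above ``min_presence``.

    A feature observed in exactly ``min_presence`` of the samples is
    dropped (strict inequality).  Survivor order is preserved.
    """
    if not 0 < min_presence <= 1:
        raise ValueError(f"min_presence must be in (0, 1], got {min_presence}")
    frac = 1.0 - m.data.isna().mean(axis=1)
    keep = frac > min_presence
    if not keep.any():
        raise ValueError(
            f"presence filter at {min_presence} removed every feature"
        )
    return m.copy_with(m.data.loc[keep])


def impute_knn(m: ExpressionMatrix, k: int = 3) -> ExpressionMatrix:
    """Replace each missing cell by the similarity-weighted mean of the k nearest feature rows.

    Distances are Euclidean over co-observed samples, normalized per
    co-observed count so rows with different overlap are comparable;
    neighbour weights are 1/(distance + 1e-9).  Observed cells are never
    altered.  A feature whose missing cell has no neighbour observed at
    that sample raises an error naming the feature.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    values = m.values
    if not np.isnan(values).any():
        return m
    out = values.copy()
    n_feat = values.shape[0]
    for i in range(n_feat):
        miss_cols = np.flatnonzero(np.isnan(values[i]))
        if miss_cols.size == 0:
            continue
        obs_i = ~np.isnan(values[i])
        # mean squared difference over co-observed samples, per candidate row
        dists = np.full(n_feat, np.inf)
        for j in range(n_feat):
            if j == i:
                continue
            shared = obs_i & ~np.isnan(values[j])
            if shared.sum() == 0:
                continue
            diff = values[i, shared] - values[j, shared]
            dists[j] = np.sqrt(np.mean(diff * diff))
        for col in miss_cols:
            has_value = ~np.isnan(values[:, col])
            candidates = np.flatnonzero(has_value & np.isfinite(dists))
            if candidates.size == 0:
                raise ValueError(
                    f"feature {m.feature_ids[i]!r} has no co-observed neighbour "
                    f"for sample {m.sample_ids[col]!r}"
                )
            order = candidates[np.argsort(dists[candidates], kind="stable")][:k]
            w = 1.0 / (dists[order] + _EPS)
            out[i, col] = float(np.sum(w * values[order, col]) / np.sum(w))
    frame = pd.DataFrame(out, index=m.data.index, columns=m.data.columns)
    return m.copy_with(frame)


def normalize(m: ExpressionMatrix, log2_first: bool = False) -> ExpressionMatrix:
    """Quantile-normalize sample columns (optionally log2-transforming first).

    After normalization every column carries the identical sorted value
    multiset: the across-sample mean of order statistics.  Tied values
    within a column receive the mean of the tied reference quantiles, so
    the map is deterministic and idempotent.
    """
    values = m.values
    if np.isnan(values).any():
        raise ValueError("normalize requires a fully observed matrix; impute first")
    if log2_first:
        bad = np.argwhere(values <= 0)
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"log2 transform requires positive values; feature "
                f"{m.feature_ids[i]!r}, sample {m.sample_ids[j]!r} is {values[i, j]}"
            )
        values = np.log2(values)
    reference = np.mean(np.sort(values, axis=0), axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        ranks = rankdata(values[:, j], method="average")  # 1-based, ties averaged
        out[:, j] = np.interp(ranks, np.arange(1, len(reference) + 1), reference)
    frame = pd.DataFrame(out, index=m.data.index, columns=m.data.columns)
    return m.copy_with(frame)


def batch_correct(m: ExpressionMatrix) -> ExpressionMatrix:
    """Hook for cross-platform artifact correction; currently the identity map."""
    warnings.warn(
        "batch_correct is a documented no-op hook; no cross-platform correction applied",
        stacklevel=2,
    )
    return m
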