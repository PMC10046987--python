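"""ReliefF feature ranking, top-k selection, and label correlation.

ReliefF scores each feature by how well it separates every sample from its
nearest neighbors of the other class (misses) relative to its nearest
neighbors of the same class (hits).  This two-class variant uses every
sample, Manhattan distance on min-max scaled features, and k nearest hits
and misses; the weight of feature f accumulates

    w_f += sum_misses |x_f - miss_f| - sum_hits |x_f - hit_f|

normalized by (n_samples * k), which keeps every weight in [-1, 1] on
scaled features.  Neighbor ties are broken by sample index so the ranking
is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import SingleClassError

__all__ = ["Ranking", "relieff_rank", "select_top", "pointwise_correlation"]


@dataclass(frozen=True)
class Ranking:
    """Per-feature ReliefF weights and the descending-weight permutation."""

    weights: np.ndarray
    order: np.ndarray


def _minmax_scale(X: np.ndarray) -> np.ndarray:
    lo = X.min(axis=0)
    span = np.ptp(X, axis=0)
    span[span == 0] = 1.0  # constant features scale to 0 everywhere
    return (X - lo) / span


def relieff_rank(
    X: np.ndarray, y: np.ndarray, k_neighbors: int = 10, seed: int = 0
) -> Ranking:
    """Rank features by two-class ReliefF weights (all samples used).

    Requires at least ``k_neighbors + 1`` samples in each class.  ``seed``
    is accepted for interface stability; neighbor ties are resolved by
    sample index, so the result does not depend on it.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise SingleClassError("ReliefF needs both classes present")
    counts = {c: int((y == c).sum()) for c in classes}
    if min(counts.values()) < k_neighbors + 1:
        raise ValueError(
            f"each class needs >= k_neighbors+1 = {k_neighbors + 1} samples, got {counts}"
        )
    n, p = X.shape
    S = _minmax_scale(X)
    D = cdist(S, S, metric="cityblock")
    w = np.zeros(p)
    order_all = np.arange(n)
    for i in range(n):
        same = (y == y[i]) & (order_all != i)
        diff = y != y[i]
        # stable sort on distance -> ties resolved by ascending sample index
        hits = order_all[same][np.argsort(D[i, same], kind="stable")][:k_neighbors]
        misses = order_all[diff][np.argsort(D[i, diff], kind="stable")][:k_neighbors]
        w += np.abs(S[i] - S[misses]).sum(axis=0)
        w -= np.abs(S[i] - S[hits]).sum(axis=0)
    w /= n * k_neighbors
    order = np.lexsort((np.arange(p), -w))
    return Ranking(weights=w, order=order)


def select_top(ranking: Ranking, k: int) -> np.ndarray:
    """The first k feature indices of the ranking (prefix-consistent)."""
    n = len(ranking.order)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    return ranking.order[:k].copy()


def pointwise_correlation(X: np.ndarray, y: np.ndarray):
    """Pearson (point-biserial) correlation of each feature with the label.

    Returns ``(corr, degenerate)``; constant features get correlation 0 and
    a True degeneracy flag.  Raises if the label itself is constant.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if np.ptp(y) == 0:
        raise SingleClassError("label is constant; correlation undefined")
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = float(np.sqrt((yc**2).sum()))
    degenerate = sx == 0
    sx_safe = np.where(degenerate, 1.0, sx)
    corr = (Xc * yc[:, None]).sum(axis=0) / (sx_safe * sy)
    corr[degenerate] = 0.0
    return corr, degenerate
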