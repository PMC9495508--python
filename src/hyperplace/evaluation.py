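"""Distortion metrics, outlier accounting and batching diagnostics.

Distance quality is measured as squared error, both raw and weighted by
the inverse squared true distance: the weighted form
``(d_est/d_true - 1)^2`` reads as a squared relative deviation, so a value
of 0.01 means the estimate is off by about 10%.  Pairs whose weighted SE
exceeds 100 (strictly) are counted as outliers; the median of weighted SE
is reported alongside means because outliers dominate the mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np

__all__ = [
    "DistortionReport",
    "weighted_se",
    "distortion_report",
    "split_small_large",
    "cobatch_never_probability",
    "cobatch_never_probability_exact",
]

OUTLIER_THRESHOLD = 100.0


@dataclass(frozen=True)
class DistortionReport:
    """Summary of distance distortion over a set of evaluated pairs."""

    mse: float
    weighted_mse: float
    weighted_median_se: float
    n_pairs: int
    outlier_fraction: float

    def __post_init__(self) -> None:
        if not 0 <= self.outlier_fraction <= 1:
            raise ValueError("outlier_fraction must be in [0, 1]")

    def __str__(self) -> str:
        return (
            f"pairs evaluated      {self.n_pairs}\n"
            f"MSE                  {self.mse:.6g}\n"
            f"weighted MSE         {self.weighted_mse:.6g}\n"
            f"weighted median SE   {self.weighted_median_se:.6g}\n"
            f"outlier fraction     {self.outlier_fraction:.6g}"
        )


def weighted_se(d_est: float, d_true: float) -> float:
    """Squared error weighted by the inverse squared true distance."""
    if d_true <= 0:
        raise ValueError("true distance must be positive")
    return (d_est - d_true) ** 2 / d_true**2


def distortion_report(
    d_est: np.ndarray,
    d_true: np.ndarray,
    outlier_threshold: float = OUTLIER_THRESHOLD,
    drop_outliers_for_mse: bool = False,
) -> DistortionReport:
    """Distortion metrics over all matching entries of two distance sets.

    Inputs are arrays of the same shape (a matrix or a flat list of pair
    distances); every entry is one evaluated pair, and all true distances
    must be positive.  Outliers (weighted SE strictly above the threshold)
    always enter the median and the outlier fraction; they are excluded
    from the two MSE figures only when ``drop_outliers_for_mse`` is set.
    """
    est = np.asarray(d_est, dtype=float).ravel()
    true = np.asarray(d_true, dtype=float).ravel()
    if est.shape != true.shape:
        raise ValueError("estimate and truth must have matching shapes")
    if est.size == 0:
        raise ValueError("no pairs to evaluate")
    if np.any(true <= 0):
        raise ValueError("true distances must be positive on evaluated pairs")
    se = (est - true) ** 2
    wse = se / true**2
    is_outlier = wse > outlier_threshold
    keep = ~is_outlier if drop_outliers_for_mse else np.ones_like(is_outlier)
    if not np.any(keep):
        raise ValueError("all pairs are outliers; nothing left for MSE")
    return DistortionReport(
        mse=float(np.mean(se[keep])),
        weighted_mse=float(np.mean(wse[keep])),
        weighted_median_se=float(np.median(wse)),
        n_pairs=int(est.size),
        outlier_fraction=float(np.mean(is_outlier)),
    )


def split_small_large(
    d_true: np.ndarray,
    k: int = 5,
    symmetric: bool = False,
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Partition pairs into each row's k smallest true distances vs the rest.

    For a query x backbone table, row i's k smallest entries are its small
    pairs.  With ``symmetric`` (a square matrix of within-set distances) a
    pair counts as small if it is among the k smallest for either
    endpoint; the diagonal is skipped.  Ties break towards the smaller
    column index (lexicographic order of positions).
    """
    if hasattr(d_true, "values") and not isinstance(d_true, np.ndarray):
        d_true = d_true.values  # QueryDistanceTable
    elif hasattr(d_true, "matrix"):
        d_true, symmetric = d_true.matrix, True  # TreeDistances
    D = np.asarray(d_true, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    nrow, ncol = D.shape
    small: set[tuple[int, int]] = set()
    for i in range(nrow):
        cols = [j for j in range(ncol) if not (symmetric and i == j)]
        cols.sort(key=lambda j: (D[i, j], j))
        for j in cols[:k]:
            small.add((min(i, j), max(i, j)) if symmetric else (i, j))
    if symmetric:
        all_pairs = {(i, j) for i in range(nrow) for j in range(i + 1, ncol)}
    else:
        all_pairs = {(i, j) for i in range(nrow) for j in range(ncol)}
    large = sorted(all_pairs - small)
    return sorted(small), large


def cobatch_never_probability(N: int, B: int, epochs: int) -> float:
    """Chance a fixed pair never shares a batch across ``epochs`` epochs.

    Uses the per-epoch co-occurrence approximation B/N, i.e. returns
    (1 - B/N)^epochs.  See :func:`cobatch_never_probability_exact` for the
    exact partition probability.
    """
    if not 2 <= B <= N:
        raise ValueError("need 2 <= B <= N")
    if epochs < 0:
        raise ValueError("epochs must be >= 0")
    return float((1.0 - B / N) ** epochs)


def cobatch_never_probability_exact(N: int, B: int, epochs: int) -> float:
    """Exact version under uniform random partition into batches of size B.

    For a partition of N items into groups of size B (last group smaller
    when B does not divide N), a fixed pair lands in the same group with
    probability sum_g n_g (n_g - 1) / (N (N - 1)).
    """
    if not 2 <= B <= N:
        raise ValueError("need 2 <= B <= N")
    if epochs < 0:
        raise ValueError("epochs must be >= 0")
    sizes = [B] * (N // B)
    if N % B:
        sizes.append(N % B)
    p_same = sum(s * (s - 1) for s in sizes) / (N * (N - 1))
    return float((1.0 - p_same) ** epochs)
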