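"""Empirical-copula (rank) transform and median splitting.

The rank transform maps each column of a sample matrix to the fixed grid
``{(2i - 1) / (2N) : i = 1..N}`` by replacing each value with its
(1-based) rank shifted by 1/2 and divided by N.  This is the empirical
analogue of plugging each coordinate into its own CDF: the result is a
sample from the copula of the joint distribution, supported on
``[0, 1]^D`` with every marginal a permutation of the same equispaced
grid.  The half-step offset keeps the extreme samples off {0, 1}, which
would otherwise artificially shrink the support.

Median splitting divides copula samples at ``u_k = 1/2`` along a chosen
dimension (the empirical median of every copula dimension) and linearly
rescales that dimension of each half back onto [0, 1].  The copula
entropy is the exact average of the entropies of the two halves, which
is the recursion step of the estimator.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rank_transform", "split_at_median", "copula_grid"]


def copula_grid(n: int) -> np.ndarray:
    """The rank grid {(2i-1)/(2N)} that every copula column permutes."""
    return (2.0 * np.arange(1, n + 1) - 1.0) / (2.0 * n)


def _column_ranks(col: np.ndarray) -> np.ndarray:
    # stable sort => ties keep original row order
    order = np.argsort(col, kind="stable")
    ranks = np.empty(col.size, dtype=np.float64)
    ranks[order] = np.arange(1, col.size + 1, dtype=np.float64)
    return ranks


def rank_transform(X) -> np.ndarray:
    """Rank-transform each column of an N x D sample matrix.

    Each value is replaced by ``(rank - 1/2) / N`` where rank is its
    1-based position in increasing column order; ties are broken by
    original row order (stable sort).  The output columns are exact
    permutations of :func:`copula_grid`.

    Because ranks are invariant under strictly increasing per-column
    maps, the transform is idempotent and invariant to monotone
    reparametrisations of the data.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError("expected an N x D matrix")
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("input must be finite")
    U = np.empty_like(X)
    for k in range(X.shape[1]):
        U[:, k] = (_column_ranks(X[:, k]) - 0.5) / n
    return U


def split_at_median(U, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Split copula samples at u_k = 1/2 along dimension ``k`` (0-based).

    Returns ``(left, right)`` where left holds the rows with
    ``u_k <= 1/2`` and right the rest.  In each half, dimension k is
    rescaled back onto (0, 1) (left: ``2 u_k``; right: ``2 u_k - 1``)
    while all other dimensions pass through unchanged.  For even N the
    halves have exactly N/2 rows each; for odd N the middle grid point
    (u_k = 1/2 exactly) goes left.
    """
    U = np.asarray(U, dtype=float)
    if U.ndim != 2:
        raise ValueError("expected an N x D matrix")
    if not 0 <= k < U.shape[1]:
        raise ValueError(f"dimension index {k} out of range for D={U.shape[1]}")
    mask = U[:, k] <= 0.5
    left = U[mask].copy()
    right = U[~mask].copy()
    left[:, k] = 2.0 * left[:, k]
    right[:, k] = 2.0 * right[:, k] - 1.0
    return left, right
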