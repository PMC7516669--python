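"""One- and two-dimensional building-block entropy estimators.

Two families of 1D estimators are provided, matching the two situations
that arise in the copula decomposition:

* :func:`spacing_entropy` — an m-spacing (order-statistics) estimator for
  samples whose support is unknown or unbounded.  Used for the raw
  marginals at the top level of the recursion.
* :func:`histogram_entropy_unit` — a plug-in histogram estimator for
  samples known to live on [0, 1].  Used for the marginals of copula
  samples, whose support is [0, 1] by construction.

:func:`histogram_entropy_2d` is the 2D analogue on the unit square; it
backs the mutual-information independence test.

All entropies are in nats.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma

from .exceptions import DegenerateInputError

__all__ = [
    "spacing_entropy",
    "histogram_entropy_unit",
    "histogram_entropy_2d",
    "auto_spacing_m",
    "auto_bins_1d",
    "auto_bins_2d",
]

#: default exponents for the sample-size driven resolution rules:
#: m = N^(1/3) spacings, B = N^0.4 bins in 1D, B2 = N^0.2 bins per axis in 2D
SPACING_M_EXPONENT = 1.0 / 3.0
BIN_EXPONENT_1D = 0.4
BIN_EXPONENT_2D = 0.2


def auto_spacing_m(n: int, exponent: float = SPACING_M_EXPONENT) -> int:
    """Default spacing half-window m = round(N^exponent), kept feasible."""
    return max(1, min(int(round(n**exponent)), (n - 1) // 2))


def auto_bins_1d(n: int, exponent: float = BIN_EXPONENT_1D) -> int:
    """Default 1D bin count B = round(N^exponent), at least 2."""
    return max(2, int(round(n**exponent)))


def auto_bins_2d(n: int, exponent: float = BIN_EXPONENT_2D) -> int:
    """Default per-axis 2D bin count B2 = round(N^exponent), at least 2."""
    return max(2, int(round(n**exponent)))


def _as_vector(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} must be finite")
    return x


def spacing_entropy(x, m: int | str = "auto") -> float:
    """m-spacing entropy estimate of a 1D sample (nats).

    Uses symmetric windows of order statistics, ``x[(i+m)] - x[(i-m)]``,
    with indices clamped to the sample range at the edges, and a
    digamma bias correction so that the estimate is asymptotically
    unbiased (for the uniform distribution the expected value is
    ``ln(N+1) - psi(N+1) -> 0``)::

        H = (1/N) sum_i [ ln((N+1) * (x_(hi) - x_(lo))) - psi(hi - lo) ]

    where ``hi = min(i+m, N)`` and ``lo = max(i-m, 1)`` (1-based).

    Parameters
    ----------
    x : array_like
        Sample values; any support.
    m : int or "auto"
        Spacing half-window.  ``"auto"`` uses ``round(N**(1/3))``.

    Raises
    ------
    ValueError
        If ``N < 3``, values are non-finite, or ``N < 2m + 1``.
    DegenerateInputError
        If all values are identical (the plug-in answer is -inf).
    """
    x = _as_vector(x, "x")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    if m == "auto":
        m = auto_spacing_m(n)
    else:
        m = int(m)
        if m < 1:
            raise ValueError("m must be >= 1")
        if n < 2 * m + 1:
            raise ValueError(f"need N >= 2m+1 = {2 * m + 1}, got {n}")
    xs = np.sort(x)
    if xs[0] == xs[-1]:
        raise DegenerateInputError("all sample values are identical")
    idx = np.arange(n)
    lo = np.clip(idx - m, 0, n - 1)
    hi = np.clip(idx + m, 0, n - 1)
    span = xs[hi] - xs[lo]
    with np.errstate(divide="ignore"):
        terms = np.log((n + 1) * span) - digamma(hi - lo)
    return float(np.mean(terms))


def _unit_bin_index(u: np.ndarray, bins: int) -> np.ndarray:
    # half-open bins [left, right) with the final bin closed so u = 1 bins
    return np.minimum((u * bins).astype(np.intp), bins - 1)


def histogram_entropy_unit(u, bins: int | str = "auto") -> float:
    """Plug-in histogram entropy of a sample on [0, 1] (nats).

    ``H = -sum_b p_b ln p_b - ln B`` over B equal-width bins; this is the
    differential entropy of the piecewise-constant density fit.  The value
    lies in ``[-ln B, 0]``, with 0 attained iff all bins are equally full.

    Parameters
    ----------
    u : array_like
        Sample values in [0, 1].
    bins : int or "auto"
        Number of bins.  ``"auto"`` uses ``round(N**0.4)``.
    """
    u = _as_vector(u, "u")
    if u.size == 0:
        raise ValueError("empty sample")
    if u.min() < 0.0 or u.max() > 1.0:
        raise ValueError("values must lie in [0, 1]")
    b = auto_bins_1d(u.size) if bins == "auto" else int(bins)
    if b < 1:
        raise ValueError("bins must be >= 1")
    counts = np.bincount(_unit_bin_index(u, b), minlength=b)
    p = counts[counts > 0] / u.size
    return float(-np.sum(p * np.log(p)) - np.log(b))


def histogram_entropy_2d(u, v, bins_per_axis: int | str = "auto") -> float:
    """Plug-in 2D histogram entropy of a sample on the unit square (nats).

    ``H = -sum p ln p - 2 ln B2`` over a ``B2 x B2`` grid of equal cells;
    the value lies in ``[-2 ln B2, 0]``.

    Parameters
    ----------
    u, v : array_like
        Coordinate samples of equal length, each in [0, 1].
    bins_per_axis : int or "auto"
        Bins per axis.  ``"auto"`` uses ``max(2, round(N**0.2))``.
    """
    u = _as_vector(u, "u")
    v = _as_vector(v, "v")
    if u.size != v.size:
        raise ValueError("u and v must have equal length")
    if u.size == 0:
        raise ValueError("empty sample")
    for name, w in (("u", u), ("v", v)):
        if w.min() < 0.0 or w.max() > 1.0:
            raise ValueError(f"{name} values must lie in [0, 1]")
    b = auto_bins_2d(u.size) if bins_per_axis == "auto" else int(bins_per_axis)
    if b < 1:
        raise ValueError("bins_per_axis must be >= 1")
    flat = _unit_bin_index(u, b) * b + _unit_bin_index(v, b)
    counts = np.bincount(flat, minlength=b * b)
    p = counts[counts > 0] / u.size
    return float(-np.sum(p * np.log(p)) - 2.0 * np.log(b))
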