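"""The recursive copula-splitting entropy estimator.

Sklar's theorem factors any continuous joint density into its 1D
marginals and a copula, so the differential entropy decomposes as

    H = sum_k H_k + Hc,

with ``H_k`` the marginal entropies (estimated by 1D methods) and ``Hc``
the non-positive entropy of the copula.  ``Hc`` is estimated
recursively: rank-transform the data onto [0, 1]^D, and

* if the dimensions decompose into pairwise-independent blocks, estimate
  each block separately and add the results;
* otherwise split the copula sample at its median (exactly 1/2 in every
  dimension) along the most-correlated dimension; the copula entropy is
  the exact average of the two halves' entropies, each of which is again
  a Sklar decomposition one level down.

The recursion stops when a block is one-dimensional or the sample is
smaller than ``min_samples``.  Because every accumulated copula term is
non-positive, truncating the recursion yields an upper bound on H that
improves with depth.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np

from .copula import rank_transform, split_at_median
from .independence import (
    choose_split_dimension,
    dependency_matrix,
    find_blocks,
    spearman_matrix,
)
from .univariate import (
    auto_bins_1d,
    auto_spacing_m,
    histogram_entropy_unit,
    spacing_entropy,
)

__all__ = [
    "EstimatorConfig",
    "EntropyEstimate",
    "MutualInformationEstimate",
    "combine_halves",
    "copula_entropy_recursive",
    "estimate_entropy",
    "estimate_mutual_information",
]

logger = logging.getLogger(__name__)


@dataclass
class EstimatorConfig:
    """All tunables of the recursive estimator.

    Parameters
    ----------
    alpha : float
        Level of the pairwise dependence tests (default 0.05).
    min_samples : int
        Recursion floor: nodes with N <= min_samples return their
        marginal sum without splitting further (default 100).
    spacing_m_exponent, bin_exponent_1d, bin_exponent_2d : float
        Resolution rules m = N^(1/3), B = N^0.4 and B2 = N^0.2 for the
        spacing, 1D-histogram and 2D-histogram estimators.
    mi_cutoff_coeff, mi_cutoff_exponent : float
        Power law H2c = coeff * N^(-exponent) for the mutual-information
        independence cutoff.
    use_calibrated_cutoff : bool
        Re-derive the cutoff by Monte-Carlo simulation (seeded) instead
        of the closed-form power law.
    histogram_level0 : bool
        Use the unit-interval histogram for the level-0 marginals when
        the support is known to be [0, 1]^D (default: m-spacing, which
        needs no support information).
    max_depth : int or None
        Truncate the recursion after this many median splits (None:
        unbounded; termination is still guaranteed since N halves per
        split and blocks strictly reduce D).
    seed : int
        Seed for the optional cutoff calibration, the only stochastic
        ingredient; with ``use_calibrated_cutoff=False`` the estimator
        is a deterministic function of the data.
    """

    alpha: float = 0.05
    min_samples: int = 100
    spacing_m_exponent: float = 1.0 / 3.0
    bin_exponent_1d: float = 0.4
    bin_exponent_2d: float = 0.2
    mi_cutoff_coeff: float = -0.75
    mi_cutoff_exponent: float = 0.62
    use_calibrated_cutoff: bool = False
    calibration_reps: int = 500
    histogram_level0: bool = False
    max_depth: int | None = None
    seed: int = 0
    _cutoff_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_samples < 8:
            raise ValueError("min_samples must be >= 8")
        for name in ("spacing_m_exponent", "bin_exponent_1d", "bin_exponent_2d"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.max_depth is not None and self.max_depth < 0:
            raise ValueError("max_depth must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("_cutoff_cache")
        return d


@dataclass
class EntropyEstimate:
    """Total entropy in nats plus its decomposition and diagnostics.

    ``total = marginal_sum + copula`` holds exactly: the copula part is
    defined as the recursion total minus the level-0 marginal sum.
    """

    total: float
    marginal_sum: float
    copula: float
    max_depth: int
    n_block_splits: int
    n_leaves: int


@dataclass
class MutualInformationEstimate:
    """Mutual information between two column groups, in nats.

    ``mi`` is clipped at 0 from below; ``raw`` keeps the unclipped
    difference H(g1) + H(g2) - H(joint).  For 1D-vs-1D groups,
    ``direct`` additionally reports minus the copula component of the
    joint estimate (MI = -Hc for a bivariate copula).
    """

    mi: float
    raw: float
    h_group1: float
    h_group2: float
    h_joint: float
    direct: float | None = None


def combine_halves(h_left: float, h_right: float) -> float:
    """Exact combine rule for a median split: the average of the halves."""
    if not (np.isfinite(h_left) and np.isfinite(h_right)):
        raise ValueError("half entropies must be finite")
    return (h_left + h_right) / 2.0


class _Diagnostics:
    __slots__ = ("max_depth", "n_block_splits", "n_leaves", "marginal_sum")

    def __init__(self) -> None:
        self.max_depth = 0
        self.n_block_splits = 0
        self.n_leaves = 0
        self.marginal_sum: float | None = None


def _marginal_sum(V: np.ndarray, unit: bool, config: EstimatorConfig) -> float:
    n = V.shape[0]
    h = 0.0
    if unit:
        bins = auto_bins_1d(n, config.bin_exponent_1d)
        for k in range(V.shape[1]):
            h += histogram_entropy_unit(V[:, k], bins)
    else:
        m = auto_spacing_m(n, config.spacing_m_exponent)
        for k in range(V.shape[1]):
            h += spacing_entropy(V[:, k], m)
    return h


def _recurse(
    V: np.ndarray,
    level: int,
    unit: bool,
    config: EstimatorConfig,
    diag: _Diagnostics,
) -> float:
    n, d = V.shape
    diag.max_depth = max(diag.max_depth, level)

    # 1. marginal entropies of the input values: spacing for raw data of
    #    unknown support, unit-interval histogram once on [0, 1]
    use_hist = unit or level >= 1 or config.histogram_level0
    h = _marginal_sum(V, use_hist, config)
    if diag.marginal_sum is None:
        diag.marginal_sum = h

    # 2/3. rank-transform and stop at 1D blocks, small samples, or the
    #      configured truncation depth
    truncated = config.max_depth is not None and level >= config.max_depth
    if d == 1 or n <= config.min_samples or truncated:
        diag.n_leaves += 1
        return h
    U = rank_transform(V)

    # 4. block decomposition: pairwise-independent groups of dimensions
    #    are estimated separately at the same level
    R = spearman_matrix(U)
    A = dependency_matrix(U, config, spearman=R)
    blocks = find_blocks(A)
    if logger.isEnabledFor(logging.DEBUG):
        logger.debug(
            "level=%d N=%d D=%d blocks=%d", level, n, d, len(blocks)
        )
    if len(blocks) > 1:
        diag.n_block_splits += 1
        for b in blocks:
            h += _recurse(U[:, b], level, True, config, diag)
        return h

    # 5. median split along the most-correlated dimension; the copula
    #    entropy is the exact average of the two halves
    k = choose_split_dimension(R)
    if logger.isEnabledFor(logging.DEBUG):
        logger.debug("level=%d N=%d D=%d split_dim=%d", level, n, d, k)
    left, right = split_at_median(U, k)
    h_left = _recurse(left, level + 1, True, config, diag)
    h_right = _recurse(right, level + 1, True, config, diag)
    return h + combine_halves(h_left, h_right)


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError("expected an N x D sample matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("input must be finite")
    return X


def copula_entropy_recursive(
    V, level: int = 0, config: EstimatorConfig | None = None
) -> float:
    """Run the recursion on a sample matrix and return the total (nats).

    At ``level = 0`` the input may have arbitrary support (marginals are
    estimated by m-spacing); at ``level >= 1`` the input must lie in
    [0, 1]^D and marginals use the unit-interval histogram.
    """
    if level < 0:
        raise ValueError("level must be >= 0")
    config = config or EstimatorConfig()
    V = _as_matrix(V)
    if level >= 1 and (V.min() < 0.0 or V.max() > 1.0):
        raise ValueError("at level >= 1 all values must lie in [0, 1]")
    return _recurse(V, level, level >= 1, config, _Diagnostics())


def estimate_entropy(X, config: EstimatorConfig | None = None) -> EntropyEstimate:
    """Estimate the differential entropy of an N x D sample (nats).

    Returns the total together with the level-0 marginal sum, the copula
    component (their exact difference), and recursion diagnostics.  With
    the default configuration the result is a deterministic function of
    the data.
    """
    config = config or EstimatorConfig()
    X = _as_matrix(X)
    if X.shape[0] < 4:
        raise ValueError("need at least 4 samples")
    diag = _Diagnostics()
    total = _recurse(X, 0, False, config, diag)
    marginal = diag.marginal_sum if diag.marginal_sum is not None else total
    return EntropyEstimate(
        total=float(total),
        marginal_sum=float(marginal),
        copula=float(total - marginal),
        max_depth=diag.max_depth,
        n_block_splits=diag.n_block_splits,
        n_leaves=diag.n_leaves,
    )


def estimate_mutual_information(
    X,
    group1,
    group2,
    config: EstimatorConfig | None = None,
) -> MutualInformationEstimate:
    """Mutual information between two disjoint column groups (nats).

    Computed as ``H(g1) + H(g2) - H(joint)`` with each entropy from
    :func:`estimate_entropy`; the headline value is clipped at 0 from
    below (MI is non-negative), with the raw difference retained.
    """
    config = config or EstimatorConfig()
    X = _as_matrix(X)
    g1 = np.atleast_1d(np.asarray(group1, dtype=int))
    g2 = np.atleast_1d(np.asarray(group2, dtype=int))
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups must be nonempty")
    if np.intersect1d(g1, g2).size:
        raise ValueError("column groups must be disjoint")
    e1 = estimate_entropy(X[:, g1], config)
    e2 = estimate_entropy(X[:, g2], config)
    ej = estimate_entropy(X[:, np.concatenate([g1, g2])], config)
    raw = e1.total + e2.total - ej.total
    direct = -ej.copula if (g1.size == 1 and g2.size == 1) else None
    return MutualInformationEstimate(
        mi=max(0.0, raw),
        raw=float(raw),
        h_group1=e1.total,
        h_group2=e2.total,
        h_joint=ej.total,
        direct=direct,
    )
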