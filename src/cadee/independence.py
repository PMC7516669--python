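"""Pairwise dependence testing and block decomposition of dimensions.

The recursion stops splitting when the copula cannot be told apart from
the independent (uniform) one.  Testing full D-dimensional uniformity is
as hard as estimating the copula entropy itself, so the criterion is
relaxed to *pairwise* dependence:

1. Spearman correlation: the correlation matrix of the ranked data is
   the Pearson matrix of the copula sample; each off-diagonal entry is
   tested with the usual t statistic ``|r| sqrt((n-2)/(1-r^2))`` against
   the Student-t quantile with n-2 degrees of freedom at level alpha.
2. Mutual-information fallback: pairs that pass the correlation test can
   still be dependent (e.g. ring-shaped copulas).  Because copula
   marginals are uniform, the pair's mutual information equals its 2D
   copula entropy, so the pair is declared dependent when the plug-in 2D
   histogram entropy falls below a negative cutoff H2c.  Under the null
   the plug-in value tends to 0 from below; the default cutoff is the
   power law ``H2c(N) = -0.75 N^-0.62`` (the alpha = 0.05 null quantile),
   and :func:`calibrate_mi_cutoff` re-derives it by simulation.

Dimensions connected by declared-dependent pairs form blocks (connected
components of the dependence graph); disjoint blocks are statistically
independent and can be processed separately, reducing the dimension.
"""

from __future__ import annotations

from typing import TYPE_CHECKING

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import t as student_t

from .copula import rank_transform
from .univariate import auto_bins_2d, histogram_entropy_2d

if TYPE_CHECKING:  # pragma: no cover
    from .estimator import EstimatorConfig

__all__ = [
    "spearman_matrix",
    "correlated",
    "mi_cutoff",
    "calibrate_mi_cutoff",
    "pair_dependent",
    "dependency_matrix",
    "find_blocks",
    "choose_split_dimension",
]


def spearman_matrix(U) -> np.ndarray:
    """Spearman correlation matrix of copula (ranked) samples.

    For rank-transformed columns this is simply their Pearson
    product-moment correlation matrix.
    """
    U = np.asarray(U, dtype=float)
    if U.ndim != 2:
        raise ValueError("expected an N x D matrix")
    if U.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    if U.shape[1] == 1:
        return np.ones((1, 1))
    r = np.corrcoef(U, rowvar=False)
    return np.clip(r, -1.0, 1.0)


def correlated(r: float, n: int, alpha: float = 0.05) -> bool:
    """Two-sided t test of a (Spearman) correlation coefficient.

    True iff ``|r| sqrt((n-2)/(1-r^2))`` exceeds the Student-t quantile
    with n-2 degrees of freedom at level 1 - alpha/2 (|r| = 1 is always
    significant).
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if not -1.0 <= r <= 1.0:
        raise ValueError("correlation must lie in [-1, 1]")
    if abs(r) == 1.0:
        return True
    tstat = abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
    tcrit = student_t.ppf(1.0 - alpha / 2.0, n - 2)
    return bool(tstat > tcrit)


def mi_cutoff(n: int, coeff: float = -0.75, exponent: float = 0.62) -> float:
    """Closed-form null cutoff for the plug-in 2D copula entropy (nats).

    ``H2c = coeff * n**(-exponent)``; negative, with magnitude shrinking
    as the sample grows (the plug-in entropy of an independent copula
    sample tends to 0 from below).
    """
    if n < 10:
        raise ValueError("need n >= 10")
    return float(coeff * n ** (-exponent))


def calibrate_mi_cutoff(
    n: int,
    alpha: float = 0.05,
    reps: int = 500,
    seed: int = 0,
    bins_per_axis: int | None = None,
) -> float:
    """Monte-Carlo calibration of the 2D-entropy independence cutoff.

    Simulates ``reps`` independent pairs of uniform samples of size
    ``n``, ranks both coordinates, computes the plug-in 2D histogram
    entropy of each pair, and returns the empirical alpha-quantile of
    the resulting (negative) values, i.e. the threshold below which an
    independent pair falls with probability alpha.
    """
    if reps < 100:
        raise ValueError("need reps >= 100 for a usable quantile")
    if n < 10:
        raise ValueError("need n >= 10")
    rng = np.random.default_rng(seed)
    bins = auto_bins_2d(n) if bins_per_axis is None else bins_per_axis
    vals = np.empty(reps)
    for i in range(reps):
        u = rank_transform(rng.random((n, 2)))
        vals[i] = histogram_entropy_2d(u[:, 0], u[:, 1], bins)
    return float(np.quantile(vals, alpha))


def _pair_cutoff(n: int, config: "EstimatorConfig") -> float:
    if config.use_calibrated_cutoff:
        key = (n, config.alpha)
        if key not in config._cutoff_cache:
            config._cutoff_cache[key] = calibrate_mi_cutoff(
                n,
                alpha=config.alpha,
                reps=config.calibration_reps,
                seed=config.seed,
                bins_per_axis=auto_bins_2d(n, config.bin_exponent_2d),
            )
        return config._cutoff_cache[key]
    return mi_cutoff(n, config.mi_cutoff_coeff, config.mi_cutoff_exponent)


def pair_dependent(u, v, config: "EstimatorConfig | None" = None) -> bool:
    """Test a pair of ranked marginals for statistical dependence.

    True if the Spearman correlation is significant at level alpha;
    otherwise true iff the plug-in 2D histogram entropy of the pair
    falls below the mutual-information cutoff (both marginals of a
    copula sample are uniform, so I(X, Y) = H(X, Y) here).
    """
    from .estimator import EstimatorConfig

    if config is None:
        config = EstimatorConfig()
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.size != v.size:
        raise ValueError("u and v must have equal length")
    n = u.size
    r = float(np.corrcoef(u, v)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    if correlated(r, n, config.alpha):
        return True
    h2 = histogram_entropy_2d(u, v, auto_bins_2d(n, config.bin_exponent_2d))
    return h2 < _pair_cutoff(n, config)


def dependency_matrix(
    U,
    config: "EstimatorConfig | None" = None,
    spearman: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean D x D pairwise-dependence matrix of a copula sample.

    ``A[k, l]`` is True when dimensions k and l are declared dependent
    (diagonal True by convention); each unordered pair is tested once,
    so the matrix is symmetric by construction.  A precomputed Spearman
    matrix may be supplied to avoid recomputation.
    """
    from .estimator import EstimatorConfig

    if config is None:
        config = EstimatorConfig()
    U = np.asarray(U, dtype=float)
    n, d = U.shape
    if n < 4:
        raise ValueError("need at least 4 samples")
    A = np.eye(d, dtype=bool)
    if d == 1:
        return A
    r = spearman_matrix(U) if spearman is None else spearman
    tcrit = student_t.ppf(1.0 - config.alpha / 2.0, n - 2)
    cutoff = None
    bins2 = auto_bins_2d(n, config.bin_exponent_2d)
    for k in range(d):
        for l in range(k + 1, d):
            rkl = float(np.clip(r[k, l], -1.0, 1.0))
            if abs(rkl) == 1.0:
                dep = True
            elif abs(rkl) * np.sqrt((n - 2) / (1.0 - rkl * rkl)) > tcrit:
                dep = True
            else:
                if cutoff is None:
                    cutoff = _pair_cutoff(n, config)
                dep = histogram_entropy_2d(U[:, k], U[:, l], bins2) < cutoff
            A[k, l] = A[l, k] = dep
    return A


def find_blocks(A) -> list[np.ndarray]:
    """Connected components of the pairwise-dependence graph.

    Equivalent to reading off the support sets of a rational (0/1)
    basis of the kernel of the graph Laplacian L = A - diag(row sums).
    Blocks are returned sorted by their smallest member.
    """
    A = np.asarray(A, dtype=bool)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.array_equal(A, A.T):
        raise ValueError("dependency matrix must be symmetric")
    n_comp, labels = connected_components(csr_matrix(A), directed=False)
    blocks = [np.flatnonzero(labels == c) for c in range(n_comp)]
    blocks.sort(key=lambda b: b[0])
    return blocks


def choose_split_dimension(R) -> int:
    """Dimension with the strongest overall correlation (0-based index).

    Squares the off-diagonal entries of the correlation matrix, sums the
    rows, and returns the argmax; ties go to the smallest index.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("expected a square correlation matrix")
    scores = np.sum(R**2, axis=1) - np.diag(R) ** 2
    return int(np.argmax(scores))
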