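"""FAB F-tests for the global linear hypothesis H: theta = 0.

Model: a response vector (e.g. post-perturbation cell viability across n
cell lines) follows ``x ~ N_n(G theta, sigma^2 I)`` where G (n x p) holds
per-cell-line gene expression.  Tests are based on the self-normalized
profile ``y = x / ||x||``, which is uniform on the unit sphere under the
null, so no statistic here depends on the unknown error scale.

With the spiked prior ``theta ~ N_p(0, nu E E' + gamma I)`` and a point
mass at ``sigma_tilde_sq`` for the error variance, the FAB statistic is

    F_FAB(y) = -n log( y' (G Psi G' + sigma_tilde_sq I)^{-1} y ),

whose null quantiles come from Monte Carlo draws of uniformly distributed
unit vectors.  In the diffuse limit (nu -> inf, gamma -> 0) the FAB test
coincides with the classical global F-test on the reduced n x d design
``G E``, which is the default, tuning-free mode.
"""

from __future__ import annotations

import logging

import numpy as np
import statsmodels.api as sm
from scipy import stats

from ._linalg import as_rng
from .exceptions import DegenerateInputError, InsufficientReplicationError
from .two_sample import SpikedPrior, TestResult

logger = logging.getLogger(__name__)

__all__ = [
    "self_normalize",
    "fab_f_statistic",
    "fab_f_mc_null",
    "fab_f_test",
    "limiting_fab_f_test",
    "classical_f_test",
]


def self_normalize(x: np.ndarray) -> np.ndarray:
    """Project a response vector onto the unit sphere: ``y = x / ||x||``."""
    x = np.asarray(x, dtype=float).ravel()
    nrm = np.linalg.norm(x)
    if nrm == 0.0:
        raise DegenerateInputError("cannot self-normalize the zero vector")
    return x / nrm


def _marginal_cov(G: np.ndarray, prior: SpikedPrior, sigma_tilde_sq: float):
    # G Psi G' + s2 I assembled as nu (GE)(GE)' + gamma G G' + s2 I so the
    # spike never requires forming the p x p prior covariance.
    n = G.shape[0]
    GE = G @ prior.E
    M = prior.nu * (GE @ GE.T) + sigma_tilde_sq * np.eye(n)
    if prior.gamma > 0:
        M += prior.gamma * (G @ G.T)
    return M


def fab_f_statistic(
    y: np.ndarray, G: np.ndarray, prior: SpikedPrior, sigma_tilde_sq: float
) -> float:
    """FAB statistic ``-n log( y' (G Psi G' + sigma_tilde_sq I)^{-1} y )``
    for a unit vector y."""
    y = np.asarray(y, dtype=float).ravel()
    if abs(np.linalg.norm(y) - 1.0) > 1e-8:
        raise ValueError("y must be a unit vector; call self_normalize first")
    if sigma_tilde_sq <= 0:
        raise ValueError("sigma_tilde_sq must be positive")
    G = np.atleast_2d(np.asarray(G, dtype=float))
    n = G.shape[0]
    M = _marginal_cov(G, prior, sigma_tilde_sq)
    w, V = np.linalg.eigh(M)
    c = V.T @ y
    return -n * float(np.log(np.sum(c**2 / w)))


def fab_f_mc_null(
    G: np.ndarray,
    prior: SpikedPrior,
    sigma_tilde_sq: float,
    n_mc: int,
    seed,
) -> np.ndarray:
    """Sorted Monte Carlo sample of the null distribution of the FAB
    statistic.

    Under H the self-normalized profile is uniform on the sphere, so null
    draws are normalized standard Gaussians; a single eigendecomposition of
    the marginal covariance vectorizes all ``n_mc`` evaluations.
    """
    if n_mc < 100:
        raise ValueError("n_mc must be at least 100")
    rng = as_rng(seed)
    G = np.atleast_2d(np.asarray(G, dtype=float))
    n = G.shape[0]
    M = _marginal_cov(G, prior, sigma_tilde_sq)
    w, V = np.linalg.eigh(M)
    X = rng.standard_normal((n_mc, n))
    C = X @ V
    quad = (C**2 / w).sum(axis=1) / (C**2).sum(axis=1)
    return np.sort(-n * np.log(quad))


def fab_f_test(
    x: np.ndarray,
    G: np.ndarray,
    prior: SpikedPrior,
    sigma_tilde_sq: float | None = None,
    n_mc: int = 10_000,
    seed=None,
) -> TestResult:
    """Finite-(nu, gamma) FAB F-test with a Monte Carlo null.

    ``sigma_tilde_sq`` defaults to the sample variance of x (the point-mass
    prior location for the error variance is otherwise unidentified; the
    statistic is only weakly sensitive to it through the relative weight of
    the spike).  The p-value is ``(1 + #{null >= observed}) / (1 + n_mc)``,
    never exactly zero.
    """
    x = np.asarray(x, dtype=float).ravel()
    if sigma_tilde_sq is None:
        sigma_tilde_sq = float(np.var(x, ddof=1))
        logger.info("sigma_tilde_sq defaulted to var(x) = %.4g", sigma_tilde_sq)
    y = self_normalize(x)
    observed = fab_f_statistic(y, G, prior, sigma_tilde_sq)
    null = fab_f_mc_null(G, prior, sigma_tilde_sq, n_mc, seed)
    p = (1 + int(np.sum(null >= observed))) / (1 + n_mc)
    return TestResult(observed, p, "fab_f_mc", n_mc=n_mc)


def _global_f(x: np.ndarray, design: np.ndarray, label: str) -> TestResult:
    n, q = design.shape
    if n <= q:
        raise InsufficientReplicationError(
            f"global F-test needs n > number of regressors (n={n}, q={q})"
        )
    rank = np.linalg.matrix_rank(design)
    if rank < q:
        raise ValueError(
            f"design matrix is rank-deficient: effective rank {rank} < {q}"
        )
    fit = sm.OLS(x, design, hasconst=False).fit()
    rss = float(fit.ssr)
    if rss <= 1e-12 * float(x @ x):
        logger.warning("%s: zero residual; reporting p = 0", label)
        return TestResult(np.inf, 0.0, label, q, n - q)
    return TestResult(float(fit.fvalue), float(fit.f_pvalue), label, q, n - q)


def limiting_fab_f_test(x: np.ndarray, G: np.ndarray, E: np.ndarray) -> TestResult:
    """Diffuse-prior limit of the FAB F-test: the classical global F-test of
    H: beta = 0 in the reduced-rank regression ``x ~ N_n(G E beta, sigma^2 I)``,
    with (d, n - d) degrees of freedom and an exact F p-value."""
    x = np.asarray(x, dtype=float).ravel()
    G = np.atleast_2d(np.asarray(G, dtype=float))
    E = np.atleast_2d(np.asarray(E, dtype=float))
    if E.shape[1] >= G.shape[0]:
        raise InsufficientReplicationError(
            f"limiting test needs d < n (d={E.shape[1]}, n={G.shape[0]})"
        )
    return _global_f(x, G @ E, "fab_f_limit")


def classical_f_test(x: np.ndarray, G: np.ndarray) -> TestResult:
    """Classical global F-test of H: theta = 0 on the full design G.

    Requires n > p; in the wide regime (p close to or above n) this test is
    infeasible or nearly powerless, which is exactly the regime the
    embedding-projected test targets.
    """
    x = np.asarray(x, dtype=float).ravel()
    G = np.atleast_2d(np.asarray(G, dtype=float))
    return _global_f(x, G, "classical_f")


def mc_pvalue_from_null(null_sorted: np.ndarray, observed: float) -> float:
    """Monte Carlo p-value ``(1 + #{null >= observed}) / (1 + n_mc)``."""
    n_mc = null_sorted.size
    idx = np.searchsorted(null_sorted, observed, side="left")
    return (1 + (n_mc - idx)) / (1 + n_mc)


def mc_quantile(null_sorted: np.ndarray, alpha: float) -> float:
    """The empirical (1 - alpha) quantile of a sorted null sample."""
    return float(np.quantile(null_sorted, 1.0 - alpha))
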