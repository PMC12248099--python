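"""Shared linear-algebra helpers: guarded SPD solves and log-determinants.

All solves go through Cholesky on the symmetrized matrix; if that fails the
fallback is an eigendecomposition with eigenvalues floored at ``EIG_FLOOR``,
which is logged because it signals a nearly singular input.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import linalg

from .exceptions import NumericalError

logger = logging.getLogger(__name__)

EIG_FLOOR = 1e-12


def _sym(M: np.ndarray) -> np.ndarray:
    return (M + M.T) / 2.0


def solve_spd(M: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve M X = B for symmetric positive-definite M.

    Falls back to an eigenvalue-floored pseudo-solve when the Cholesky
    factorization fails, logging a warning with the offending eigenvalue.
    """
    Ms = _sym(np.asarray(M, dtype=float))
    try:
        c, low = linalg.cho_factor(Ms, check_finite=False)
        return linalg.cho_solve((c, low), B, check_finite=False)
    except linalg.LinAlgError:
        w, V = linalg.eigh(Ms, check_finite=False)
        logger.warning(
            "Cholesky failed (min eigenvalue %.3e); flooring spectrum at %.1e",
            w.min(), EIG_FLOOR,
        )
        w = np.maximum(w, EIG_FLOOR)
        return V @ ((V.T @ B).T / w).T


def logdet_spd(M: np.ndarray) -> float:
    """log det of a symmetric positive-definite matrix via Cholesky."""
    Ms = _sym(np.asarray(M, dtype=float))
    try:
        c = linalg.cholesky(Ms, lower=True, check_finite=False)
        return 2.0 * float(np.sum(np.log(np.diag(c))))
    except linalg.LinAlgError as exc:
        sign, ld = np.linalg.slogdet(Ms)
        if sign <= 0:
            raise NumericalError(
                "log-determinant of a non-positive-definite matrix"
            ) from exc
        logger.warning("Cholesky failed for logdet; using slogdet fallback")
        return float(ld)


def quad_form_spd(y: np.ndarray, M: np.ndarray) -> float:
    """Compute y' M^{-1} y for SPD M."""
    y = np.asarray(y, dtype=float)
    return float(y @ solve_spd(M, y))


def as_rng(seed) -> np.random.Generator:
    """Accept an int seed or an existing Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
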