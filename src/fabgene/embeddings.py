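"""Gene-embedding matrices, principal subspaces, and the alignment diagnostic.

A gene-embedding matrix places each of p genes at a point in a D-dimensional
coordinate space (for LLM-derived embeddings D is typically 1536, but any
real matrix qualifies).  The working hypothesis of the whole package is that
biologically meaningful signal vectors in gene space lie near the span of the
top left singular vectors of this matrix.  This module provides:

* loading / standardizing / rank-reducing embedding matrices,
* the principal subspace (top-k left singular vectors),
* the alignment statistic ``alpha_k = ||U_{1:k}' y||^2 / ||y||^2`` measuring
  how much of a signal vector's squared norm the first k principal axes
  capture, and
* its null reference band under Haar-random rotations, against which an
  observed alignment profile can be judged.

Under a uniformly random orthogonal basis, ``E[alpha_k] = k/p``; an observed
profile rising above the Haar band at small k indicates that the embedding
axes preferentially capture the signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._linalg import as_rng
from .exceptions import DegenerateInputError

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingMatrix",
    "PrincipalSubspace",
    "standardize_and_reduce",
    "principal_basis",
    "subspace_alignment",
    "alignment_profile",
    "sample_haar_orthogonal",
    "alignment_null_band",
]


@dataclass
class EmbeddingMatrix:
    """A gene-identified real matrix of embedding coordinates.

    Attributes
    ----------
    gene_ids : list of str
        Row labels; must be unique.
    values : ndarray of shape (p, D)
        Embedding coordinates, one row per gene.
    """

    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.gene_ids = [str(g) for g in self.gene_ids]
        p, D = self.values.shape
        if len(self.gene_ids) != p:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {p} matrix rows"
            )
        if len(set(self.gene_ids)) != p:
            raise ValueError("duplicate gene ids in embedding matrix")
        if p < 2 or D < 1:
            raise ValueError(f"embedding matrix must be at least 2x1, got {p}x{D}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("embedding matrix contains non-finite entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(self, genes: list[str]) -> "EmbeddingMatrix":
        """Rows for ``genes`` in the given order; missing genes raise KeyError."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in genes]
        return EmbeddingMatrix(list(genes), self.values[rows])


@dataclass
class PrincipalSubspace:
    """Orthonormal basis of a principal subspace with its singular values."""

    basis: np.ndarray
    singular_values: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.basis = np.atleast_2d(np.asarray(self.basis, dtype=float))
        k = self.basis.shape[1]
        if self.singular_values is None:
            self.singular_values = np.ones(k)
        self.singular_values = np.asarray(self.singular_values, dtype=float)
        if self.singular_values.shape != (k,):
            raise ValueError("one singular value per basis column required")
        if np.any(np.diff(self.singular_values) > 1e-12) or np.any(
            self.singular_values < -1e-12
        ):
            raise ValueError("singular values must be nonincreasing and >= 0")
        gram = self.basis.T @ self.basis
        if not np.allclose(gram, np.eye(k), atol=1e-8):
            raise ValueError("basis columns are not orthonormal (tol 1e-8)")

    @property
    def k(self) -> int:
        return self.basis.shape[1]

    @property
    def p(self) -> int:
        return self.basis.shape[0]


def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry of each column positive (reproducible
    across LAPACK builds)."""
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs


def standardize_and_reduce(E_raw: EmbeddingMatrix, d: int) -> EmbeddingMatrix:
    """Center+scale the columns of an embedding matrix, then keep the rank-d
    principal scores.

    Each column is centered to mean 0 and scaled to unit standard deviation
    (denominator p-1); constant columns carry no information and are dropped
    with a warning.  The output is the p x d matrix of principal scores
    ``U_d diag(s_d)``, whose column space equals that of the best rank-d
    approximation of the standardized matrix.
    """
    if d < 1:
        raise ValueError(f"d must be a positive integer, got {d}")
    X = E_raw.values
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not np.any(keep):
        raise DegenerateInputError("all embedding columns are constant")
    if not np.all(keep):
        logger.warning("dropping %d constant embedding column(s)", (~keep).sum())
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    p, D = X.shape
    if d > min(p, D):
        raise ValueError(f"d={d} exceeds min(p, D) = {min(p, D)}")
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = _fix_signs(U[:, :d]) * s[:d]
    return EmbeddingMatrix(E_raw.gene_ids, scores)


def principal_basis(E: EmbeddingMatrix, k: int) -> PrincipalSubspace:
    """Top-k left singular vectors of the embedding matrix."""
    p, D = E.shape
    if not 1 <= k <= min(p, D):
        raise ValueError(f"k={k} out of range [1, {min(p, D)}]")
    U, s, _ = np.linalg.svd(E.values, full_matrices=False)
    return PrincipalSubspace(_fix_signs(U[:, :k]), s[:k])


def subspace_alignment(U: PrincipalSubspace, y: np.ndarray, k: int) -> float:
    """Fraction of ``y``'s squared norm in the span of the first k axes."""
    y = np.asarray(y, dtype=float).ravel()
    nrm2 = float(y @ y)
    if nrm2 == 0.0:
        raise DegenerateInputError("alignment of a zero vector is undefined")
    if not 1 <= k <= U.k:
        raise ValueError(f"k={k} out of range [1, {U.k}]")
    proj = U.basis[:, :k].T @ y
    return float(proj @ proj) / nrm2


def alignment_profile(U_full: PrincipalSubspace, y: np.ndarray) -> np.ndarray:
    """Alignment ``alpha_k`` for every k = 1..p given a full orthogonal basis.

    The profile is nondecreasing and ends at 1 (Parseval).
    """
    basis = U_full.basis
    if basis.shape[0] != basis.shape[1]:
        raise ValueError(
            f"full orthogonal basis required, got shape {basis.shape}"
        )
    y = np.asarray(y, dtype=float).ravel()
    nrm2 = float(y @ y)
    if nrm2 == 0.0:
        raise DegenerateInputError("alignment of a zero vector is undefined")
    coords = basis.T @ y
    return np.cumsum(coords**2) / nrm2


def sample_haar_orthogonal(p: int, seed) -> np.ndarray:
    """Draw a p x p orthogonal matrix from the Haar (uniform) distribution.

    Uses the QR construction: factor an i.i.d. standard Gaussian matrix and
    flip column signs so R has a positive diagonal, which makes the QR map
    measure-preserving onto the orthogonal group.
    """
    if p < 1:
        raise ValueError(f"p must be positive, got {p}")
    rng = as_rng(seed)
    Z = rng.standard_normal((p, p))
    Q, R = np.linalg.qr(Z)
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    return Q * signs


def alignment_null_band(
    y: np.ndarray,
    n_reps: int,
    lower_q: float = 0.025,
    upper_q: float = 0.975,
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise quantile band of the alignment profile under Haar rotation.

    For each k, returns the empirical ``lower_q`` and ``upper_q`` quantiles of
    ``alpha_k(V)`` over ``n_reps`` independent Haar-random orthogonal V.  An
    observed profile escaping above this band at small k is evidence that the
    embedding axes are preferentially aligned with the signal.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be at least 2")
    if not 0.0 < lower_q < upper_q < 1.0:
        raise ValueError("require 0 < lower_q < upper_q < 1")
    y = np.asarray(y, dtype=float).ravel()
    nrm2 = float(y @ y)
    if nrm2 == 0.0:
        raise DegenerateInputError("alignment of a zero vector is undefined")
    p = y.size
    rng = as_rng(seed)
    profiles = np.empty((n_reps, p))
    for r in range(n_reps):
        V = sample_haar_orthogonal(p, rng)
        profiles[r] = np.cumsum((V.T @ y) ** 2) / nrm2
    lower = np.quantile(profiles, lower_q, axis=0)
    upper = np.quantile(profiles, upper_q, axis=0)
    return lower, upper
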