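"""Synthetic data generators and the two-sample power study.

The study conditions: samples of size n1 = n2 = 50 in dimension p = 200
with an embedding of dimension d = 10.  Error covariances have Haar-random
eigenvectors and eigenvalues equal to an equi-spaced sequence between 0.1
and 1 raised to a decay power (20 = fast decay, approximately low-rank;
5 = slow decay), normalized so trace(Sigma) = 50.  Unit-norm mean-shift
signals are drawn near the embedding principal subspace: z ~ N_d(0, I),
v ~ N_p(U z, gamma_noise * I), delta = v / ||v||, so smaller gamma_noise
means signals better aligned with the subspace.  Power for each method is
the rejection proportion over ``n_realizations`` datasets, averaged over
``n_instances`` independent draws of (Sigma, delta).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._linalg import as_rng
from .embeddings import PrincipalSubspace, sample_haar_orthogonal, subspace_alignment
from .scalar_t import ScalarPanel
from .two_sample import TwoSampleData, afab_test, rp_test

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationScenario",
    "make_covariance",
    "make_embedding_basis",
    "make_signal",
    "simulate_two_sample",
    "power_study",
    "simulate_linear_null",
    "simulate_scalar_panel",
]


@dataclass
class SimulationScenario:
    """Configuration of the two-sample power study (defaults = study scale)."""

    p: int = 200
    d: int = 10
    n1: int = 50
    n2: int = 50
    decay_powers: tuple = (20, 5)
    total_variance: float = 50.0
    gamma_noises: tuple = (1.0, 2.0 / 3.0, 1.0 / 3.0)
    r_grid: tuple = (0.5, 0.66, 0.8)
    n_instances: int = 15
    n_realizations: int = 100
    seed: int = 0
    redraw_embedding: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.d <= self.p:
            raise ValueError("require 1 <= d <= p")
        if min(self.gamma_noises) <= 0:
            raise ValueError("gamma_noise values must be positive")

    def scaled_down(self) -> "SimulationScenario":
        """A small preset with the same structure: p=60, d=5, 5 instances of
        50 realizations each, sample sizes unchanged."""
        return replace(self, p=60, d=5, n_instances=5, n_realizations=50)


def make_covariance(
    p: int, decay_power: float, total_variance: float, seed
) -> np.ndarray:
    """SPD covariance with Haar eigenvectors and a powered equi-spaced
    spectrum: eigenvalues proportional to ``linspace(0.1, 1, p)**decay_power``
    scaled so the trace equals ``total_variance``."""
    if p < 1 or total_variance <= 0:
        raise ValueError("p must be >= 1 and total_variance > 0")
    lam = np.linspace(0.1, 1.0, p) ** decay_power
    lam *= total_variance / lam.sum()
    Q = sample_haar_orthogonal(p, seed)
    return (Q * lam) @ Q.T


def make_embedding_basis(
    p: int, d: int, seed
) -> tuple[np.ndarray, PrincipalSubspace]:
    """i.i.d. N(0,1) embedding matrix E (p x d) and its left singular
    vectors as the signal subspace."""
    if d > p:
        raise ValueError("require d <= p")
    rng = as_rng(seed)
    E = rng.standard_normal((p, d))
    U, s, _ = np.linalg.svd(E, full_matrices=False)
    return E, PrincipalSubspace(U, s)


def make_signal(
    U: PrincipalSubspace, gamma_noise: float, seed
) -> tuple[np.ndarray, float]:
    """Unit-norm mean shift concentrated near the embedding subspace.

    z ~ N_d(0, I); v ~ N_p(U z, gamma_noise I); delta = v/||v||.  Returns
    delta and its alignment ``alpha_d`` with the subspace.
    """
    if gamma_noise <= 0:
        raise ValueError("gamma_noise must be positive")
    rng = as_rng(seed)
    p, d = U.basis.shape
    z = rng.standard_normal(d)
    v = U.basis @ z + np.sqrt(gamma_noise) * rng.standard_normal(p)
    delta = v / np.linalg.norm(v)
    return delta, subspace_alignment(U, delta, d)


def simulate_two_sample(
    Sigma: np.ndarray, delta: np.ndarray, n1: int, n2: int, seed
) -> TwoSampleData:
    """Draw x1 ~ N_p(0, Sigma) and x2 ~ N_p(delta, Sigma) (signal on the
    treated sample, so E[xbar2 - xbar1] = delta)."""
    rng = as_rng(seed)
    Sigma = np.asarray(Sigma, dtype=float)
    p = Sigma.shape[0]
    # fast spectral decay makes Sigma numerically rank-deficient, so factor
    # through the (clipped) eigendecomposition rather than Cholesky
    w, V = np.linalg.eigh((Sigma + Sigma.T) / 2.0)
    L = V * np.sqrt(np.clip(w, 0.0, None))
    x1 = rng.standard_normal((n1, p)) @ L.T
    x2 = rng.standard_normal((n2, p)) @ L.T + np.asarray(delta, dtype=float)
    return TwoSampleData(x1, x2)


def _run_method(data, E, method, r, rng):
    if method == "afab_naive":
        return afab_test(data, E, "naive")
    if method == "afab_ss":
        return afab_test(data, E, "split_sample", r=r, seed=rng)
    if method == "rp":
        return rp_test(data, E.shape[1], seed=rng)
    raise ValueError(f"unknown method {method!r}")


def power_study(
    scenario: SimulationScenario,
    methods: tuple = ("afab_naive", "afab_ss", "rp"),
    alpha: float = 0.05,
    null_override: bool = False,
) -> pd.DataFrame:
    """Run the full factorial power study.

    For every (decay_power, gamma_noise, method[, r]) cell, computes
    ``n_instances`` rejection proportions, each over ``n_realizations``
    paired datasets (all methods see the same data within a realization).
    ``null_override`` forces delta = 0 so every cell estimates the type-I
    error instead of power.

    Returns a tidy DataFrame with columns decay, gamma_noise, method, r,
    instance, alignment, power.
    """
    unknown = set(methods) - {"afab_naive", "afab_ss", "rp"}
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    arms = []
    for method in methods:
        if method == "afab_ss":
            for r in scenario.r_grid:
                m1 = int(np.ceil(r * scenario.n1))
                m2 = int(np.ceil(r * scenario.n2))
                if (
                    m1 < 1 or m1 >= scenario.n1 or m2 < 1 or m2 >= scenario.n2
                ):
                    logger.warning(
                        "skipping afab_ss r=%s: empty split at n=(%d, %d)",
                        r, scenario.n1, scenario.n2,
                    )
                    continue
                arms.append((method, r))
        else:
            arms.append((method, np.nan))
    E, U = make_embedding_basis(scenario.p, scenario.d, scenario.seed)
    records = []
    for decay in scenario.decay_powers:
        for gamma_noise in scenario.gamma_noises:
            for inst in range(scenario.n_instances):
                inst_seed = scenario.seed + inst
                if scenario.redraw_embedding:
                    E, U = make_embedding_basis(
                        scenario.p, scenario.d, inst_seed + 7_000_000
                    )
                Sigma = make_covariance(
                    scenario.p, decay, scenario.total_variance,
                    inst_seed + 1_000_000 * int(decay),
                )
                delta, align = make_signal(
                    U, gamma_noise, inst_seed + int(3_000_000 * gamma_noise)
                )
                if null_override:
                    delta = np.zeros(scenario.p)
                rng = as_rng(inst_seed + 11)
                rejections = {arm: 0 for arm in arms}
                for _ in range(scenario.n_realizations):
                    data = simulate_two_sample(
                        Sigma, delta, scenario.n1, scenario.n2, rng
                    )
                    for arm in arms:
                        res = _run_method(data, E, arm[0], arm[1], rng)
                        rejections[arm] += res.p_value <= alpha
                for (method, r) in arms:
                    records.append(
                        {
                            "decay": decay,
                            "gamma_noise": gamma_noise,
                            "method": method,
                            "r": r,
                            "instance": inst,
                            "alignment": align,
                            "power": rejections[(method, r)]
                            / scenario.n_realizations,
                        }
                    )
    return pd.DataFrame(records)


def simulate_linear_null(n: int, p: int, seed) -> tuple[np.ndarray, np.ndarray]:
    """Null response ``x ~ N_n(0, I)`` and an i.i.d. Gaussian design G."""
    if n < 2 or p < 1:
        raise ValueError("require n >= 2 and p >= 1")
    rng = as_rng(seed)
    return rng.standard_normal(n), rng.standard_normal((n, p))


def simulate_scalar_panel(
    K: int,
    d: int,
    nu: float,
    gamma: float,
    eta: float,
    sigma: float,
    seed,
    n1: int = 5,
    n2: int = 5,
):
    """Scalar-panel generator matched to the FAB t model.

    Draws an i.i.d. Gaussian embedding E (K x d), a coupled effect vector
    ``theta ~ N_K(0, nu EE' + gamma I)``, and difference scores
    ``y ~ N(theta, eta sigma^2)``.  Per-gene spreads are simulated as pooled
    estimates on ``n1 + n2 - 2`` degrees of freedom so the panel behaves
    like condensed replicate data.

    Returns (panel, E, theta).
    """
    rng = as_rng(seed)
    E = rng.standard_normal((K, d))
    L = np.linalg.cholesky(
        nu * (E @ E.T) + gamma * np.eye(K) + 1e-12 * np.eye(K)
    )
    theta = L @ rng.standard_normal(K)
    y = theta + np.sqrt(eta) * sigma * rng.standard_normal(K)
    dof = n1 + n2 - 2
    sigma_hat = sigma * np.sqrt(rng.chisquare(dof, size=K) / dof)
    return ScalarPanel(y, sigma_hat, n1, n2), E, theta
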