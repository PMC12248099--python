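# Methods

This note records the statistical models the package implements, the
numerical choices behind them, what the synthetic-data generators emulate,
and the design decisions taken where more than one faithful implementation
existed. It states no empirical numbers beyond what the test suite and
`scripts/acceptance.py` compute at run time.

## The FAB principle

All three test families follow the same recipe. To test H: θ = 0 at level
α against prior information π about θ, the Neyman–Pearson lemma applied to
the *marginal* likelihood says the most powerful level-α test on average
over π rejects when `log p_π(y) − log p_0(y)` exceeds its (1−α) null
quantile. Level holds by construction regardless of whether π is right;
power concentrates where π puts mass. Here π is always a zero-mean Gaussian
with spiked covariance `Ψ = ν E Eᵀ + γ I`, so mass concentrates near the
column space of the embedding matrix E as ν/γ grows.

The alignment diagnostic motivates that choice of π: for a signal vector y
and the left singular basis U of an embedding matrix,
`α_k(U) = ‖U_{1:k}ᵀ y‖² / ‖y‖²` measures the fraction of signal energy in
the first k principal axes. Under a Haar-random basis `E[α_k] = k/p`; an
observed profile escaping the simulated Haar band at small k is evidence
the embedding axes are informative about the signal.

## Two-sample test

Model: `x_{i,j} ~ N_p(μ_j, Σ)`, j = 1 (control), 2 (treated);
`y = x̄₁ − x̄₂ ~ N_p(θ, ηΣ)`, `η = 1/n₁ + 1/n₂`.

**Oracle statistic.** Implemented as the exact log marginal-vs-null
likelihood ratio rather than a specific quadratic-form rendering, because
any increasing affine transform induces the identical test and the log-LR
form is unambiguous. The quadratic form
`yᵀΣ⁻¹(ηΨ⁻¹ + Σ⁻¹)⁻¹Σ⁻¹y` is exposed separately
(`t_fab_quadratic`); the two are related by `logLR = quad/(2η) + const`,
which the tests verify. The null of the quadratic form is
`Σ_j w_j χ²₁(j)` with `w_j = η/(η λ_j + 1)` for λ_j the eigenvalues of
`Σ^{1/2} Ψ⁻¹ Σ^{1/2}`; the Monte Carlo null is checked against this
construction distributionally. Ψ⁻¹ always goes through the Woodbury
identity so the diffuse regime (ν/γ ≈ 10¹⁶) stays numerically stable.

**Projected statistics.** `T_LFAB = yᵀA(AᵀΣA)⁻¹Aᵀy`, `A = Σ⁻¹E`, is the
ν→∞, γ→0 limit; `T_AFAB` replaces Σ by a whitening matrix Σ̃ chosen
independently of the data and ηΣ's role by the pooled S, giving the exact
scaled-F null `((n−d−1)/(d(n−2))) T ~ F_{d,n−d−1}`, n = n₁+n₂. Both
depend on E only through its column space (invariance under E ↦ EG is
tested at 1e−10 relative tolerance).

**Split-sample variant.** A seeded per-sample shuffle sends the first
⌈r·n_j⌉ rows to (y, S) and the remainder (m rows in total) to
`Σ̃ = S̃ + [p/(10 m)] I`. Ceiling rounding means r = 0.66 at n_j = 50
allocates 33/17. Whether the same subset should serve both y and S is not
uniquely determined by the study description; this implementation uses one
subset for both, which preserves the independence structure the F null
needs.

**Single-profile convention.** When one group holds a single profile (one
perturbation against a bank of controls), S comes from the replicated
sample alone with divisor n₁ − 1 and the F degrees of freedom use the
effective total n₁ + 1; this makes the scaled statistic exactly
F-distributed (one-sample Hotelling geometry) and is verified by a
calibration test.

**Baseline.** The RP test projects both samples onto an i.i.d. N(0,1)
p×d matrix and runs Hotelling's T² in the projected space with the same
exact F null.

## FAB F-test

Model: `x ~ N_n(Gθ, σ²I)`. All statistics act on `y = x/‖x‖`, uniform on
the sphere under the null, so nothing depends on σ². The finite-(ν, γ)
statistic is `−n log(yᵀ(GΨGᵀ + σ̃²I)⁻¹y)`, assembled as
`ν(GE)(GE)ᵀ + γGGᵀ + σ̃²I` so the p×p prior covariance is never formed.
Null quantiles come from normalized Gaussian draws pushed through a single
eigendecomposition of that n×n matrix (one `eigh`, then fully vectorized).
Monte Carlo p-values are reported as `(1 + #{null ≥ obs})/(1 + n_mc)` so
they are never exactly zero; the default n_mc is 10,000 and a seed is
required.

σ̃² (the point mass for the error variance) defaults to `var(x)`: the
limiting test is σ-free, and for the finite test this choice only shifts
the relative weight of the spike. The choice is logged.

The diffuse limit is exactly the classical global F-test of H: β = 0 in
`x ~ N_n(GEβ, σ²I)` with (d, n−d) degrees of freedom, implemented through
statsmodels OLS (no intercept: the model has none; a caller can center x
and G beforehand if wanted). This analytic form is the default mode. The
classical full-design F-test with (p, n−p) degrees of freedom is provided
as the baseline; it refuses n ≤ p, which is precisely the wide regime the
projected test targets.

## FAB t-tests

Model: per-gene difference scores `y ~ N_K(θ, η diag(σ̂²))` with
`σ̂_k²` the pooled per-gene variance on `dof = n₁+n₂−2` degrees of freedom
(the only df consistent with σ̂'s definition), and coupling prior
`θ ~ N_K(0, νEEᵀ + γI)`.

**Prior moments.** `(m_k, v_k)` are the Gaussian conditional mean and
variance of θ_k given `y_{−k}` whose marginal covariance is
`Ψ_{−k,−k} + ηD_{−k}`. For K ≤ 400 every gene gets its own submatrix
Cholesky solve; above that the package uses the partitioned-inverse
downdate (one inversion of `M = Ψ + ηD`, then `m_k = y_k − u_k/B_kk`,
`v_k = 1/B_kk − ησ̂_k²` with `B = M⁻¹`, `u = By`), which is algebraically
identical and O(K³) total instead of O(K⁴). The two paths are tested
against each other. The error-scale estimate σ̃ is the root mean of the
*other* genes' pooled variances, so `(m_k, v_k, σ̃_k)` are all invariant to
arbitrary changes of `(y_k, σ̂_k)` — the independence that makes the FAB
p-value exactly valid, enforced by a perturbation test over every k.

**The p-value.** The Bayes-optimal level-α test of a normal mean with a
Gaussian prior rejects outside an asymmetric pair of tails whose cut points
are mirror images about `−b/2` on the standardized scale, with prior tilt
`b = 2mσ̃√η/v`. Writing G for the t CDF with `dof` degrees of freedom and
`h(t) = G(t) + G(t + b)`, the p-value is `min(h, 2 − h)`. Two hard
contracts pin this form down: (i) it is *exactly* uniform under the null
for any fixed b, because the symmetry of the t distribution makes the two
branch cut points mirror images (`P(p ≤ α) = G(a) + G(a+b) = α`); and
(ii) b = 0 reduces it exactly to the classical two-sided p-value
`2(1 − G(|t|))`. Both contracts are asserted by tests, so the resolution is
observable rather than assumed. The √η factor in the tilt places σ̃ on the
replicate-level standard-deviation scale; validity is unaffected by this
scaling (only power is), by contract (i).

**Hyperparameters.** (ν, γ) maximize the log marginal likelihood of y
under `N_K(0, νEEᵀ + γI + ηD)` over logarithmic grids, by default
ν ∈ 10^{−2..2}, γ ∈ 10^{−3..1} (9 points each), ties broken toward the
weakest coupling. Selection uses the whole score vector; callers wanting
strict per-gene independence of the hyperparameters can pass (ν, γ)
obtained from independent data.

## Synthetic data

The generators reproduce the structure of the two-sample power study and
provide calibration fixtures for the other tests:

- **Covariances**: eigenvalues `linspace(0.1, 1, p)^q` for decay power
  q = 20 (fast, effectively low-rank) or 5 (slow), trace-normalized to 50;
  eigenvectors Haar (Gaussian QR with the positive-diagonal convention).
  Because the fast-decay Σ is numerically rank-deficient in float64,
  sampling factors through the clipped eigendecomposition, not Cholesky.
- **Embeddings**: i.i.d. N(0,1) p×d matrices; the signal subspace is their
  left singular basis U. One E is fixed per study (a flag redraws it per
  instance).
- **Signals**: `z ~ N_d(0, I)`, `v ~ N_p(Uz, γ_noise I)`, `δ = v/‖v‖`,
  added to the treated sample's mean. The generative mean is the subspace
  image Uz (the projector applied to it is a no-op). Smaller γ_noise means
  better alignment; the defaults {1, 2/3, 1/3} span roughly uniform-like
  to well-aligned signals.
- **Study scale**: n₁ = n₂ = 50, p = 200, d = 10, 15 instances × 100
  realizations per cell. The test suite and the acceptance script run a
  structurally identical scaled version (p = 60, d = 5, 5 × 50) chosen so
  the full suite completes in well under a minute; the full-scale study
  runs on one CPU via `fabgene simulate`.
- Per-instance seeds are `base_seed + instance`, so any instance is
  independently reproducible; every generator is a pure function of its
  seed.

What the generators deliberately do not emulate: non-Gaussian and
heavy-tailed expression noise, gene-gene correlation structure in the
scalar panel beyond the prior coupling, batch effects, and embeddings with
real semantic structure (they are isotropic Gaussian). Passing calibration
and power tests on these inputs therefore demonstrates correctness of the
statistics under their stated models, not robustness on real screens —
though the level guarantees of the projected tests require only Gaussianity
and independence of Σ̃, not a correct prior.

## Numerical choices

- SPD solves use Cholesky on the symmetrized matrix; failure falls back to
  an eigendecomposition with eigenvalues floored at 1e−12, logged.
- Singular-vector signs follow the largest-magnitude-entry-positive
  convention so SVD outputs are reproducible across LAPACK builds.
- The projected covariance `ÃᵀSÃ` is declared singular (insufficient
  replication) at condition number > 1e12.
- Rank checks use `numpy.linalg.matrix_rank`'s default tolerance; errors
  name the deficient rank.
- Quantile estimates from sorted Monte Carlo nulls use the default
  (linear-interpolation) empirical quantile.

## Known limitations

- The split-sample variant requires at least one held-out observation per
  group and refuses splits that round to empty parts.
- `select_hyperparameters` is a grid search; it is O(|grid| · K³) and not
  meant for K in the tens of thousands.
- The alignment null band loops over Haar draws (O(n_reps · p³)); for
  p ≫ 1000 reduce n_reps or subsample genes.
- BH is the only multiplicity adjustment offered, with missing p-values
  excluded from the test count and propagated as missing q-values.
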