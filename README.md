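# fabgene

Embedding-informed hypothesis tests for genomics screens.

High-throughput experiments pose hypothesis tests whose classical solutions
lose power as dimension grows: does a perturbation change a p-dimensional
expression profile at all? Does a drug's viability pattern across cell lines
relate to any linear combination of p gene-expression covariates? Which of K
genes respond differently between two conditions? `fabgene` implements
*frequentist-and-Bayesian* (FAB) versions of these tests. They are derived
to maximize power averaged over a Gaussian prior that concentrates near the
principal subspace of a gene-embedding matrix — the span of the top left
singular vectors of any real matrix that places genes in a coordinate space,
such as LLM-derived text embeddings — while retaining exact frequentist
type-I error control whether or not the prior is right.

## The tests

Write `E ∈ R^{p×d}` for the (rank-reduced) embedding matrix and
`Ψ = ν E Eᵀ + γ I_p` for the spiked prior covariance.

**Two-sample high-dimensional mean test.** With profiles
`x_{i,j} ~ N_p(μ_j, Σ)`, sufficient statistic `y = x̄₁ − x̄₂ ~ N_p(θ, ηΣ)`,
`η = 1/n₁ + 1/n₂`, and prior `θ ~ N_p(0, Ψ)`:

- *Oracle* (known Σ): the log likelihood ratio
  `log N(y; 0, ηΣ + Ψ) − log N(y; 0, ηΣ)`, whose null is a weighted sum of
  χ²₁ variables (Monte Carlo quantiles).
- *Diffuse limit* (ν→∞, γ→0): the projection statistic
  `T_LFAB = yᵀA(AᵀΣA)⁻¹Aᵀy`, `A = Σ⁻¹E`.
- *Practical*: the embedding-projected Hotelling statistic
  `T_AFAB = (n₁n₂/(n₁+n₂)) yᵀÃ(ÃᵀSÃ)⁻¹Ãᵀy` with `Ã = Σ̃⁻¹E`, S the pooled
  sample covariance, and any whitening matrix Σ̃ independent of the data.
  Exactly, `((n₁+n₂−d−1)/(d(n₁+n₂−2))) T_AFAB ~ F_{d, n₁+n₂−d−1}` under the
  null. Σ̃ = I gives the *naive* variant; the *split-sample* variant
  estimates a ridge-shrunk Σ̃ on held-out observations.
- *Baseline*: the random-projection (RP) Hotelling test on a Gaussian
  `p×d` projection.

**FAB F-test.** For `x ~ N_n(Gθ, σ²I)` with design G (expression values),
the self-normalized profile `y = x/‖x‖` is uniform on the sphere under
H: θ = 0, so the FAB statistic
`F_FAB(y) = −n log(yᵀ(GΨGᵀ + σ̃²I)⁻¹y)` needs no knowledge of σ². Its null
quantiles come from Monte Carlo; in the diffuse limit the test is exactly
the classical global F-test on the reduced n×d design `GE` — the default,
tuning-free mode.

**FAB t-tests.** For K per-gene difference scores
`y ~ N_K(θ, η diag(σ̂²))` with prior `θ ~ N_K(0, Ψ)`, each gene's prior
moments `(m_k, v_k)` are the Gaussian conditional mean and variance of θ_k
given the *other* genes' scores. The FAB p-value is exactly uniform under
H_k for any prior moments independent of y_k, equals the classical
two-sided t p-value when the prior tilt vanishes, and gains power for genes
whose embedding neighbors moved.

Also included: the alignment diagnostic `α_k(U) = ‖U_{1:k}ᵀy‖²/‖y‖²` with
its Haar-rotation null band (`E[α_k] = k/p` under a random basis), a
Benjamini–Hochberg step, delimited-text I/O, and a fully seeded simulation
harness reproducing the two-sample power study design.

## Worked example

```python
import numpy as np
from fabgene import afab_test, rp_test
from fabgene.simulate import (make_covariance, make_embedding_basis,
                              make_signal, simulate_two_sample)

Sigma = make_covariance(p=200, decay_power=20, total_variance=50.0, seed=1)
E, U = make_embedding_basis(200, 10, seed=2)
delta, alignment = make_signal(U, gamma_noise=1/3, seed=3)
data = simulate_two_sample(Sigma, delta, 50, 50, seed=4)

print(f"signal alignment with embedding subspace: {alignment:.3f}")
for res in (afab_test(data, E, "naive"),
            afab_test(data, E, "split_sample", r=0.66, seed=5),
            rp_test(data, 10, seed=6)):
    print(f"{res.method:>14}: T = {res.statistic:8.2f}   "
          f"F({res.df_num}, {res.df_den})   p = {res.p_value:.3g}")
```

prints

```
signal alignment with embedding subspace: 0.397
    afab_naive: T =    94.20   F(10, 89)   p = 1.24e-09
 afab_ss_r0.66: T =   126.14   F(10, 55)   p = 6.93e-10
            rp: T =     9.85   F(10, 89)   p = 0.542
```

A unit-norm mean shift carrying ~40% of its energy in the 10-dimensional
embedding subspace is decisively detected by both embedding-projected
variants (the split-sample variant pays 34 denominator degrees of freedom
for its data-driven whitening matrix but achieves a larger statistic under
this fast-decaying covariance), while a random 10-dimensional projection
misses it entirely.

The same machinery is available from the shell:

```
fabgene two-sample --x1 controls.csv --x2 treated.csv \
    --embeddings gene_embeddings.csv --d 10 --variant split --r 0.66 \
    --seed 1 --out results.tsv
fabgene align | ftest | ttest | simulate --help
```

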