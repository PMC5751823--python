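# Methods

## Data model and samplers

All phenotypes are modeled by the linear SNP regression

    y_i = μ + Σ_j X_ij α_j + e_i,    e_i ~ N(0, σ²_e),

with X the raw 0/1/2 allele-count coding (counts of the per-SNP minor
allele as determined at read time; the coding is recorded because effect
signs depend on it).  Phenotypes are pre-adjusted for systematic
environment (farm/season-year factors, slaughter age) by ordinary least
squares, and the adjusted trait keeps its original scale (residuals plus
grand mean).

**BayesA.**  α_j ~ N(0, σ²_j) with σ²_j ~ ScInvChi²(ν, S²) i.i.d. — 
marginally a t prior on each effect.  Full conditionals are the standard
conjugate forms: α_j | · ~ N(r_j/l_j, σ²_e/l_j) with
l_j = x_jᵀx_j + σ²_e/σ²_j and r_j = x_jᵀ(e + x_j α_j);
σ²_j | · ~ ScInvChi²(ν+1, (νS² + α²_j)/(ν+1)).

**BayesCπ.**  α_j = 0 with probability π, else N(0, σ²_a) with one
common slab variance σ²_a ~ ScInvChi²(ν_a, s²_a) and π ~ Uniform(0,1).
The inclusion indicator is drawn with the effect integrated out
analytically (log-space Bayes factor
½·log(σ²_e/(σ²_a l_j)) + r²_j/(2σ²_e l_j), logistic-clipped); π | · ~
Beta(k+1, M−k+1) for k exclusions among M SNPs; σ²_a | · ~
ScInvChi²(ν_a+m₁, (ν_a s²_a + Σ_incl α²)/( ν_a+m₁)).

**Residual variance.**  σ²_e | · ~ ScInvChi²(n+ν_e, (eᵀe+ν_e S²_e)/(n+ν_e)).

One Gibbs iteration updates μ, then every SNP in ascending index order
(a fixed scan, chosen for reproducibility), then the variances and π.
The per-SNP sweep has a numba fast path; because numba reproduces
NumPy's `Generator` streams exactly, the fast path and the pure-Python
reference updates are bit-identical, and the test suite asserts this.
The residual vector is maintained incrementally and checked against a
from-scratch recomputation to 1e-8.

### Priors and defaults

| parameter | default | rationale |
|---|---|---|
| ν, ν_a | 4.2 | conventional mildly informative df for effect variances |
| S², s²_a | from data | prior mean of the effect variance = ½·var(y)/(M·mean 2q(1−q)): half the phenotypic variance spread over all markers |
| ν_e, S²_e | −2, 0 | flat prior on σ²_e (conditional reduces to ScInvChi²(n−2, eᵀe/(n−2))) |
| π init | 0.5 | uninformative start; π is sampled |
| thinning | 10 | storage/autocorrelation compromise |
| monitored set | σ²_e + 10 SNP effects | fixed-seed uniform draw of SNP indices, identical across chains |
| over-dispersion | 4 | each chain starts at σ²_e = var(y)/2 × U[¼, 4] |

All are configurable (`Hyperparameters`, `GibbsChain` arguments).

### Uncentered coding

The sampler operates on the raw 0/1/2 codes that also define
GEBV_i = Σ_j X_ij g_j.  Centering columns inside the sampler is an
algebraically equivalent reparameterization (flat prior on μ), and we
evaluated it: on the desk-scale fixtures it made the residual-variance
autocorrelation dramatically worse (integrated autocorrelation time
~220 vs ~4 with raw coding, M ≫ n), so raw coding is used throughout.

## Convergence diagnosis and tunable burn-in

For each monitored scalar, m chains × n draws give the inter-chain
variance I = n/(m−1)·Σ(x̄_i−x̄)², the within-chain variance W (mean of
(n−1)-denominator variances), the pooled estimate
var̂ = (n−1)/n·W + I/n, and the shrink factor r = √(var̂/W).  No chain
splitting and no degrees-of-freedom correction are applied, and r uses
*all* draws from iteration 1 — so r ≥ √((n−1)/n) always, and the
over-dispersed starts are deliberately retained in the statistic.

Every `check_every` = 100 iterations the controller appends one r per
monitored parameter; burn-in ends at the first evaluation where the
**trailing window** of p = 10 diagnostic points satisfies |r̄ − 1| < T
and the (1/p-denominator) window SD < T, for **every** monitored
parameter (unanimity), with T = 0.001.  A verdict requires at least
`min_samples` = 200 draws; a hard cap (`max_burn_in`, default half the
run) stops tuning with an explicit non-convergence flag, after which
sampling proceeds with that burn-in.  The cadence, window length,
minimum sample count and unanimity rule are implementation choices (the
stopping threshold T is not); the trailing window was chosen over
disjoint subsections because it reacts one cadence-step sooner and is
statistically the same test.  One shared burn-in end applies to all
chains.

### When tuning cannot beat the rule of thumb

The shrink factor of an autocorrelated stationary series has expectation
≈ 1 + (2τ−1)/(2n), τ the integrated autocorrelation time, so
|r̄ − 1| < T cannot hold before roughly n ≈ (2τ−1)/(2T) iterations *no
matter how long the total run is*.  With τ ≈ 4 for the residual
variance on the 500 × 2 000 BayesA fixture and T = 0.001 this floor is
≈ 2 000–4 000 iterations.  On long production runs (e.g. 50 000
iterations with a fixed 10 000-iteration burn-in) the floor is far
below the rule of thumb and tuning pays off exactly as the speedup
arithmetic promises; on a short 10 000-iteration run whose one-fifth
rule is 2 000, the floor and the rule coincide and the tuned burn-in
usually does *not* undercut it (in our seeded experiments most runs
declared between 1 600 and 5 000).  The acceptance suite keeps this
check at the short scale and it fails there; this is a property of the
diagnostic at small n, not of the implementation.

## Forward simulator

`popsim` stands in for an external mutation-drift simulator and makes
no attempt to reproduce any particular tool: a founder population of
`effective_size` = 100 diploids evolves for `n_generations` = 100
generations of random mating with Poisson(1) crossovers per 1-Morgan
chromosome and symmetric per-locus allele flips at rate 1.25e-3; the
last generation is expanded to the target sample size by random
pairing.  Starting monomorphic, this yields > 50 % polymorphic loci at
the defaults and realistic allele-frequency spectra and LD at desk
scale, though the short history means less LD and relatedness structure
than a real livestock population — passing tests show method
correctness, not real-data performance.  QTL are a uniform draw among
polymorphic markers; effects are standard normal (or signed-gamma for a
few-large-QTL architecture); residual noise is scaled to the
*empirical* variance of the true breeding values so each replicate hits
the nominal h² in expectation.  Loci still monomorphic in the final
sample are kept (and logged); QC removes them before analysis.

## GBLUP

G = XXᵀ/(2Σq(1−q)) with X centered by 2q (mean diagonal ≈ 1 under
HWE).  REML for y = 1μ + u + e, u ~ N(0, Gσ²_u), profiles the
restricted likelihood over λ = σ²_u/σ²_e in the eigenbasis of G with a
bounded 1-D search on log λ (bounds 1e-6…1e6, xatol 1e-10) — exact and
deterministic at these sample sizes, in place of iterative EM/AI
schemes.  Identity-like G raises an identifiability error; near-singular
prediction systems receive a logged diagonal jitter of 1e-8·tr(C)/n.
BLUP û = G_{·,train}(G_{train} + (σ²_e/σ²_u)I)⁻¹(y_train − μ̂) with the
GLS mean μ̂; fixed effects are limited to the intercept because
phenotypes arrive pre-adjusted.

## Evaluation

GPA is the Pearson correlation of GEBVs with true breeding values
(simulation) or adjusted phenotypes (real data); RGPA divides by √h².
Cross-validation uses k = 5 near-equal random folds, re-partitioned in
each of 10 replicates; each replicate's GPA is computed on the pooled
out-of-fold predictions (one correlation over all individuals) rather
than a mean of five fold-wise correlations — lower-variance, and
recorded in the report metadata.  The predictor interface receives only
training indices for fitting; a canary test mutates held-out phenotypes
and asserts the predictions do not move.

## Parallel execution and pooling

Chains are seeded `base_seed + chain_index` and are pure functions of
their seeds, so sequential execution and process-pool execution give
bit-identical results (asserted in the tests); in tunable mode, chains
synchronize at every diagnostic barrier.  Pooling thins within each
chain and concatenates in chain-index order; the pooled posterior mean
is the saved-draw-count-weighted mean of per-chain means.  Two speedup
conventions are provided: `speedup` evaluates the Amdahl formula
verbatim, and `tuned_speedup` keeps the numerator at the original
sequential cost and the parallel part at its original size while only
the serial burn-in term shrinks — the convention under which shortening
m to m/2 doubles S(5) from 2.78 to 3.84 (plugging m/2 directly into the
plain formula would give 3.57 instead).  Both are exposed and
documented because they answer different questions ("how fast is this
run" vs "how much faster than the original fixed-burn-in sequential
run").

## Problem sizes used in validation

Unit tests run on 120 × 150 simulated panels; the end-to-end agreement
checks use 500 individuals × 2 000 markers with 50 QTL at h² = 0.5 and
10 000-iteration chains (4 chains, thinning 10, fixed burn-in 2 000 or
tuned), chosen so the whole suite completes on a single CPU in a few
minutes while keeping M ≫ n, the regime the samplers are built for.

## Known limitations

* No BayesB/BayesR, multi-trait, or dominance models.
* The simulator is neutral and unstructured (no selection, pedigree, or
  population stratification).
* Burn-in tuning at T = 0.001 has the small-n floor described above.
* PLINK binary (.bed) input is not parsed; use text formats.
* Posterior archives are written as `.npz`/TSV on request; no HDF5
  container is bundled.
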