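# tbmcmc — tunable burn-in multiple-chain MCMC for genomic prediction

Bayesian whole-genome regression (BayesA and BayesCπ) estimates
thousands of SNP effects jointly by Gibbs sampling, which makes it
accurate for genomic selection but expensive: the Markov chain is
inherently serial.  Running K independent chains of the same model in
parallel recovers most of the lost throughput — except for the burn-in,
which every chain must repeat.  By Amdahl's law the speedup is

    S(K) = N_T / (N_burn-in + (N_T − N_burn-in)/K),   E = S(K)/K,

so the serial burn-in is the whole bottleneck: with N_burn-in = m and
N_T = 5m, S(5) = 2.78 and S(∞) = 5 no matter how many cores you own.
`tbmcmc` implements the remedy: the burn-in is not fixed by a rule of
thumb (one-tenth, one-fifth of the run) but **ended automatically** the
moment the chains agree that they have converged, using Gelman–Rubin
shrink factors

    r = sqrt( ((n−1)/n · W + I/n) / W )

computed across chains for the residual variance and a set of monitored
SNP effects, with a windowed stopping rule: burn-in ends in the first
window of p diagnostic points where |r̄ − 1| < T and sd(r) < T (default
T = 0.001).  Shortening burn-in from m to m/2 lifts S(5) from 2.78 to
3.84 and S(20) from 4.16 to 7.14; to m/4, 4.76 and 11.11.

The package is aimed at quantitative geneticists who want parallel
Bayesian genomic prediction with a defensible burn-in, plus the
standard surrounding toolkit:

* `genotype_data` — PLINK text (`.ped`/`.map`) and TSV genotype tables,
  SNP QC (sex chromosomes, MAF < 0.05, > 5 % missing, HWE p < 1e-6),
  mean imputation, covariate adjustment of phenotypes by OLS;
* `popsim` — a forward mutation-drift simulator (three scenario
  presets: 20k–200k markers, 200 QTL, h² = 0.1/0.5/0.3) producing
  genotypes, QTL effects, true breeding values and phenotypes;
* `bayes_samplers` — single-chain Gibbs kernels for BayesA (per-SNP
  scaled-inverse-χ² variances) and BayesCπ (spike-and-slab with
  π ~ Uniform(0,1)), numba-accelerated, bit-reproducible by seed;
* `convergence` — shrink factors and the windowed burn-in controller;
* `parallel_engine` — K-chain execution (sequential or process pool,
  bit-identical either way), sample pooling, speedup/efficiency
  arithmetic;
* `gblup` — VanRaden genomic relationship matrix, eigen-profile REML,
  BLUP prediction, as the non-MCMC benchmark;
* `evaluation` — GEBV_i = Σ_j X_ij g_j, prediction accuracy
  (GPA = Pearson r against true breeding values or adjusted
  phenotypes), relative accuracy (RGPA = r/√h²), k-fold
  cross-validation with replicates.

## Worked example

Simulate a 500-individual, 2 000-marker population with 50 QTL at
h² = 0.5, then fit BayesA with four parallel chains and automatic
burn-in tuning:

```python
from tbmcmc import (SimScenario, simulate_scenario, RunPlan, MonitorConfig,
                    run_parallel, gebv, gpa, rgpa)

scn = SimScenario(n_individuals=500, n_chrom=10, markers_per_chrom=200,
                  n_qtl=50, h2=0.5, seed=1)
sim = simulate_scenario(scn)
y, G = sim.phenotypes.y_adj, sim.genotypes

plan = RunPlan(n_chains=4, n_iter=10000, burn_in_mode="tunable",
               monitor=MonitorConfig(T=0.001), thin=10, base_seed=1201)
pooled = run_parallel(y, G, "bayesA", plan=plan)

g = gebv(G, pooled.alpha_mean)
r = gpa(g, sim.tbv)
print(f"burn-in declared at iteration {pooled.burn_in_ends[0]} "
      f"(converged={pooled.converged})")
print(f"kept {pooled.total_kept} thinned draws across {plan.n_chains} chains")
print(f"GPA  (corr with true breeding values): {r:.3f}")
print(f"RGPA (GPA / sqrt(h2)):                 {rgpa(r, scn.h2):.3f}")
```

prints

```
burn-in declared at iteration 1600 (converged=True)
kept 3360 thinned draws across 4 chains
GPA  (corr with true breeding values): 0.849
RGPA (GPA / sqrt(h2)):                 1.201
```

The controller ended burn-in at iteration 1 600 — below the one-fifth
rule (2 000) — and the pooled posterior-mean effects predict true
breeding values with accuracy 0.85; the RGPA above 1 says the GEBVs
beat mass selection on the phenotype itself for this heritability.

The same workflow is available from the shell:

```bash
tbmcmc simulate --scenario scenario2 --seed 1 --out sim
tbmcmc run --geno sim.geno.tsv --pheno sim.pheno.tsv \
       --model bayesA --chains 4 --iters 10000 --burnin auto --out fit
tbmcmc predict --geno sim.geno.tsv --effects fit/effects.tsv --out gebv.tsv
tbmcmc cv --geno sim.geno.tsv --pheno sim.pheno.tsv --model gblup --out cv.tsv
tbmcmc speedup --total 50000 --burnin 10000 -k 5 -k 20
```

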