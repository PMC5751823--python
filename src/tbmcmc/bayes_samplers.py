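"""Single-chain Gibbs samplers for Bayesian whole-genome regression.

The data model is the linear SNP regression

    y_i = mu + sum_j X_ij alpha_j + e_i,   e_i ~ N(0, sigma2_e),

with X coded 0/1/2 (raw allele counts).  Two priors on the SNP effects
are implemented:

* **BayesA** — alpha_j ~ N(0, sigma2_j) with an independent scaled
  inverse chi-square prior ScInvChi2(nu, S2) on each sigma2_j
  (marginally a t prior on each effect).
* **BayesCpi** — spike-and-slab: alpha_j = 0 with probability pi, else
  N(0, sigma2_a) with a common slab variance; sigma2_a has a
  ScInvChi2(nu_a, s2_a) prior and pi ~ Uniform(0, 1).

Full conditionals follow the standard conjugate forms; every update
draws from one shared ``numpy.random.Generator`` so that a chain is a
pure function of its seed.  The per-SNP sweep has a numba fast path
(:mod:`tbmcmc._kernels`) that consumes the identical random stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels
from .genotype_data import GenotypeMatrix

SCALAR_KEYS = ("mu", "sigma2_e", "pi", "sigma2_a")


def scaled_inv_chi2(rng: np.random.Generator, df: float, scale: float,
                    size=None):
    """Draw from ScInvChi2(df, scale) = df*scale / chi2(df)."""
    if df <= 0:
        raise ValueError(f"scaled inverse chi-square needs df > 0, got {df}")
    return df * scale / rng.chisquare(df, size=size)


@dataclass
class Hyperparameters:
    """Prior settings shared by both samplers.

    ``S2``/``s2_a`` default to None and are resolved from the data so
    that the prior mean of the effect variance corresponds to half the
    phenotypic variance spread over all markers (a conventional weakly
    informative choice); ``nu_e = -2, S2_e = 0`` is the flat prior on
    the residual variance.
    """

    nu: float = 4.2
    S2: Optional[float] = None
    nu_e: float = -2.0
    S2_e: float = 0.0
    pi_init: float = 0.5
    nu_a: float = 4.2
    s2_a: Optional[float] = None
    h2_guess: float = 0.5

    def __post_init__(self) -> None:
        if self.nu <= 0 or self.nu_a <= 0:
            raise ValueError("prior degrees of freedom must be positive")
        if not 0.0 <= self.pi_init <= 1.0:
            raise ValueError("pi_init must lie in [0, 1]")
        for name in ("S2", "s2_a"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")

    def resolve(self, y: np.ndarray, X: np.ndarray) -> "Hyperparameters":
        """Fill data-dependent scale defaults, leaving set values alone."""
        if self.S2 is not None and self.s2_a is not None:
            return self
        q = X.mean(axis=0) / 2.0
        het = float(np.mean(2.0 * q * (1.0 - q)))
        M = X.shape[1]
        vary = float(np.var(y))
        base = self.h2_guess * vary / max(M * het, 1e-300)
        S2 = self.S2 if self.S2 is not None else base * (self.nu - 2.0) / self.nu
        s2_a = self.s2_a if self.s2_a is not None else \
            base * (self.nu_a - 2.0) / self.nu_a
        return Hyperparameters(nu=self.nu, S2=S2, nu_e=self.nu_e,
                               S2_e=self.S2_e, pi_init=self.pi_init,
                               nu_a=self.nu_a, s2_a=s2_a,
                               h2_guess=self.h2_guess)


@dataclass
class ChainState:
    """Current parameters of one Gibbs chain.

    ``residual`` is maintained incrementally as y - mu - X alpha; its
    consistency with a from-scratch recomputation is an invariant the
    tests enforce to 1e-8.
    """

    model: str
    y: np.ndarray
    X: np.ndarray           # Fortran-ordered float64, raw 0/1/2 codes
    xtx: np.ndarray
    hyper: Hyperparameters  # resolved scales
    mu: float
    alpha: np.ndarray
    sigma2_e: float
    residual: np.ndarray
    rng: np.random.Generator
    sigma2_j: Optional[np.ndarray] = None   # BayesA
    delta: Optional[np.ndarray] = None      # BayesCpi
    sigma2_a: Optional[float] = None        # BayesCpi
    pi: Optional[float] = None              # BayesCpi
    iteration: int = 0
    use_conditional_means: bool = False     # test hook: deterministic updates

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def n_snps(self) -> int:
        return self.X.shape[1]

    def recompute_residual(self) -> np.ndarray:
        return self.y - self.mu - self.X @ self.alpha


def _as_matrix(G) -> np.ndarray:
    calls = G.calls if isinstance(G, GenotypeMatrix) else np.asarray(G, float)
    if np.isnan(calls).any():
        raise ValueError("genotypes contain missing calls; run qc_filter first")
    return np.asfortranarray(calls, dtype=np.float64)


def init_chain(y_adj: np.ndarray, G, model: str,
               hyper: Hyperparameters | None = None,
               seed: int = 0, overdispersion: float = 4.0) -> ChainState:
    """Independent, over-dispersed chain initialization.

    The residual-variance start is var(y)/2 scaled by a chain-specific
    multiplier drawn uniformly in [1/overdispersion, overdispersion], so
    distinct seeds start from deliberately spread points; effect
    variances start from their priors; all effects start at zero.
    """
    if model not in ("bayesA", "bayesCpi"):
        raise ValueError(f"unknown model {model!r}")
    y = np.asarray(y_adj, dtype=np.float64)
    X = _as_matrix(G)
    if X.shape[0] != len(y):
        raise ValueError("genotype and phenotype dimensions disagree")
    vary = float(np.var(y))
    if vary == 0.0:
        raise ValueError("phenotype has zero variance")
    if overdispersion < 1.0:
        raise ValueError("overdispersion must be >= 1")
    hyper = (hyper or Hyperparameters()).resolve(y, X)
    rng = np.random.default_rng(seed)
    u = rng.uniform(1.0 / overdispersion, overdispersion)
    sigma2_e = vary / 2.0 * u
    mu = float(y.mean())
    M = X.shape[1]
    state = ChainState(model=model, y=y, X=X,
                       xtx=np.einsum("ij,ij->j", X, X), hyper=hyper,
                       mu=mu, alpha=np.zeros(M), sigma2_e=sigma2_e,
                       residual=y - mu, rng=rng)
    if model == "bayesA":
        state.sigma2_j = scaled_inv_chi2(rng, hyper.nu, hyper.S2, size=M)
    else:
        state.sigma2_a = float(scaled_inv_chi2(rng, hyper.nu_a, hyper.s2_a))
        state.pi = hyper.pi_init
        state.delta = np.zeros(M, dtype=np.int8)
    return state


# ---------------------------------------------------------------------------
# single-parameter updates (pure-Python reference path)


def update_mu(state: ChainState) -> ChainState:
    cond_mean = state.mu + float(state.residual.mean())
    sd = np.sqrt(state.sigma2_e / state.n)
    new = cond_mean if state.use_conditional_means else \
        float(state.rng.normal(cond_mean, sd))
    state.residual += state.mu - new
    state.mu = new
    return state


def _seq_dot(a: np.ndarray, b: np.ndarray, init: float = 0.0) -> float:
    """Left-to-right accumulation starting from ``init``, matching the
    kernels' summation order bit for bit (BLAS dot products sum in a
    different order)."""
    acc = init
    for i in range(len(a)):
        acc += a[i] * b[i]
    return float(acc)


def update_snp_bayesA(state: ChainState, j: int) -> ChainState:
    h = state.hyper
    aj = state.alpha[j]
    if state.xtx[j] > 0.0:
        xj = state.X[:, j]
        r = _seq_dot(xj, state.residual, init=state.xtx[j] * aj)
        lhs = state.xtx[j] + state.sigma2_e / state.sigma2_j[j]
        mean, sd = r / lhs, np.sqrt(state.sigma2_e / lhs)
        anew = mean if state.use_conditional_means else \
            float(state.rng.normal(mean, sd))
        state.residual += xj * (aj - anew)
        state.alpha[j] = anew
    else:
        state.alpha[j] = 0.0 if state.use_conditional_means else \
            float(state.rng.normal(0.0, np.sqrt(state.sigma2_j[j])))
    df = h.nu + 1.0
    scale = (h.nu * h.S2 + state.alpha[j] ** 2) / df
    state.sigma2_j[j] = df * scale / (df - 2.0) if state.use_conditional_means \
        else float(scaled_inv_chi2(state.rng, df, scale))
    return state


def snp_inclusion_probability(r: float, lhs: float, sigma2_e: float,
                              sigma2_a: float, pi: float) -> float:
    """Posterior probability that a SNP enters the BayesCpi model, with
    the effect integrated out analytically (computed in log space)."""
    if pi >= 1.0:
        return 0.0
    if pi <= 0.0:
        return 1.0
    logbf = 0.5 * (np.log(sigma2_e / (sigma2_a * lhs))
                   + r * r / (sigma2_e * lhs))
    logodds = logbf + np.log((1.0 - pi) / pi)
    if logodds > 35.0:
        return 1.0
    if logodds < -35.0:
        return 0.0
    return 1.0 / (1.0 + np.exp(-logodds))


def update_snp_bayesCpi(state: ChainState, j: int) -> ChainState:
    aj = state.alpha[j]
    if state.xtx[j] > 0.0:
        xj = state.X[:, j]
        r = _seq_dot(xj, state.residual, init=state.xtx[j] * aj)
        lhs = state.xtx[j] + state.sigma2_e / state.sigma2_a
        p_incl = snp_inclusion_probability(r, lhs, state.sigma2_e,
                                           state.sigma2_a, state.pi)
    else:
        r = 0.0
        lhs = state.sigma2_e / state.sigma2_a
        p_incl = 1.0 - state.pi if 0.0 < state.pi < 1.0 else \
            (0.0 if state.pi >= 1.0 else 1.0)
    include = (p_incl >= 0.5) if state.use_conditional_means else \
        (state.rng.random() < p_incl)
    if include:
        mean, sd = r / lhs, np.sqrt(state.sigma2_e / lhs)
        anew = mean if state.use_conditional_means else \
            float(state.rng.normal(mean, sd))
        state.delta[j] = 1
    else:
        anew = 0.0
        state.delta[j] = 0
    if aj != anew and state.xtx[j] > 0.0:
        state.residual += state.X[:, j] * (aj - anew)
    state.alpha[j] = anew
    return state


def update_pi(state: ChainState) -> ChainState:
    M = state.n_snps
    k = int(M - state.delta.sum())
    a, b = k + 1.0, M - k + 1.0
    state.pi = a / (a + b) if state.use_conditional_means else \
        float(state.rng.beta(a, b))
    return state


def update_common_var(state: ChainState) -> ChainState:
    h = state.hyper
    m1 = int(state.delta.sum())
    ssq = float((state.alpha[state.delta == 1] ** 2).sum())
    df = h.nu_a + m1
    scale = (h.nu_a * h.s2_a + ssq) / df
    state.sigma2_a = df * scale / (df - 2.0) if state.use_conditional_means \
        else float(scaled_inv_chi2(state.rng, df, scale))
    return state


def update_residual_var(state: ChainState) -> ChainState:
    h = state.hyper
    df = state.n + h.nu_e
    if df <= 0:
        raise ValueError("residual-variance degrees of freedom must be positive")
    sse = float(state.residual @ state.residual)
    scale = (sse + h.nu_e * h.S2_e) / df
    state.sigma2_e = df * scale / (df - 2.0) if state.use_conditional_means \
        else float(scaled_inv_chi2(state.rng, df, scale))
    return state


def gibbs_iteration(state: ChainState, use_kernel: bool = True) -> ChainState:
    """One full scan: mu, all SNPs in index order, variances, pi."""
    update_mu(state)
    h = state.hyper
    if state.model == "bayesA":
        if use_kernel and not state.use_conditional_means:
            _kernels.sweep_bayesA(state.X, state.xtx, state.residual,
                                  state.alpha, state.sigma2_j, state.sigma2_e,
                                  h.nu, h.S2, state.rng)
        else:
            for j in range(state.n_snps):
                update_snp_bayesA(state, j)
        update_residual_var(state)
    else:
        if use_kernel and not state.use_conditional_means:
            _kernels.sweep_bayesCpi(state.X, state.xtx, state.residual,
                                    state.alpha, state.delta, state.sigma2_a,
                                    state.pi, state.sigma2_e, state.rng)
        else:
            for j in range(state.n_snps):
                update_snp_bayesCpi(state, j)
        update_common_var(state)
        update_residual_var(state)
        update_pi(state)
    state.iteration += 1
    return state


# ---------------------------------------------------------------------------
# whole-chain driver


@dataclass
class PosteriorSamples:
    """Retained draws of one chain.

    Per-SNP effects are accumulated as running sums (posterior mean =
    sum / saved count) instead of a full trace; only the monitored
    parameters (residual variance plus a fixed set of SNP effects) are
    traced at every iteration, from iteration 1, for convergence
    diagnosis.
    """

    model: str
    n_saved: int
    alpha_sum: np.ndarray
    delta_sum: Optional[np.ndarray]
    draws: dict
    monitored_trace: np.ndarray
    monitored_snps: np.ndarray
    n_iter: int
    burn_in: int
    thin: int
    seed: Optional[int] = None
    meta: dict = field(default_factory=dict)

    @property
    def alpha_mean(self) -> np.ndarray:
        return self.alpha_sum / max(self.n_saved, 1)

    @property
    def delta_mean(self) -> Optional[np.ndarray]:
        if self.delta_sum is None:
            return None
        return self.delta_sum / max(self.n_saved, 1)

    def save(self, path: str) -> None:
        """Archive the retained draws and metadata as a single .npz."""
        np.savez_compressed(
            path, model=self.model, n_saved=self.n_saved,
            alpha_sum=self.alpha_sum,
            delta_sum=np.empty(0) if self.delta_sum is None else self.delta_sum,
            monitored_trace=self.monitored_trace,
            monitored_snps=self.monitored_snps,
            n_iter=self.n_iter, burn_in=self.burn_in, thin=self.thin,
            seed=-1 if self.seed is None else self.seed,
            **{f"draws_{k}": v for k, v in self.draws.items()})

    @classmethod
    def load(cls, path: str) -> "PosteriorSamples":
        z = np.load(path, allow_pickle=False)
        delta = z["delta_sum"]
        seed = int(z["seed"])
        return cls(model=str(z["model"]), n_saved=int(z["n_saved"]),
                   alpha_sum=z["alpha_sum"],
                   delta_sum=None if delta.size == 0 else delta,
                   draws={k[len("draws_"):]: z[k] for k in z.files
                          if k.startswith("draws_")},
                   monitored_trace=z["monitored_trace"],
                   monitored_snps=z["monitored_snps"],
                   n_iter=int(z["n_iter"]), burn_in=int(z["burn_in"]),
                   thin=int(z["thin"]), seed=None if seed == -1 else seed)

    def effects_table(self, snp_ids=None):
        import pandas as pd
        m = len(self.alpha_sum)
        return pd.DataFrame({
            "snp_id": snp_ids if snp_ids is not None else np.arange(m),
            "effect": self.alpha_mean,
            "inclusion_prob": self.delta_mean if self.delta_sum is not None
            else np.ones(m)})


def default_monitor(n_snps: int, n_monitored: int = 10,
                    seed: int = 20190913) -> np.ndarray:
    """Fixed-seed uniform draw of which SNP effects to monitor (the
    residual variance is always monitored in addition)."""
    k = min(n_monitored, n_snps)
    return np.sort(np.random.default_rng(seed).choice(n_snps, size=k,
                                                      replace=False))


class GibbsChain:
    """A live chain handle: advance in steps, retain post-burn-in draws.

    ``burn_in`` may be set after construction (the tunable-burn-in
    controller does exactly that once convergence is declared); samples
    are retained at iterations t with t > burn_in and
    (t - burn_in) % thin == 0.
    """

    def __init__(self, y, G, model: str, hyper: Hyperparameters | None = None,
                 seed: int = 0, overdispersion: float = 4.0,
                 thin: int = 10, monitored_snps: np.ndarray | None = None,
                 burn_in: int | None = None, use_kernel: bool = True):
        self.state = init_chain(y, G, model, hyper, seed, overdispersion)
        self.seed = seed
        self.thin = int(thin)
        self.burn_in = burn_in
        self.use_kernel = use_kernel
        M = self.state.n_snps
        self.monitored_snps = (default_monitor(M) if monitored_snps is None
                               else np.asarray(monitored_snps, dtype=np.int64))
        self._trace: list[np.ndarray] = []
        self._draws: dict[str, list[float]] = {k: [] for k in SCALAR_KEYS}
        self.alpha_sum = np.zeros(M)
        self.delta_sum = np.zeros(M) if model == "bayesCpi" else None
        self.n_saved = 0

    @property
    def iteration(self) -> int:
        return self.state.iteration

    @property
    def monitored_trace(self) -> np.ndarray:
        """(iterations, 1 + n_monitored) array: residual variance first,
        then the monitored SNP effects."""
        if not self._trace:
            return np.empty((0, 1 + len(self.monitored_snps)))
        return np.asarray(self._trace)

    def advance(self, n_steps: int) -> "GibbsChain":
        st = self.state
        for _ in range(n_steps):
            gibbs_iteration(st, use_kernel=self.use_kernel)
            self._trace.append(np.concatenate(
                ([st.sigma2_e], st.alpha[self.monitored_snps])))
            if self.burn_in is not None and st.iteration > self.burn_in and \
                    (st.iteration - self.burn_in) % self.thin == 0:
                self._retain()
        return self

    def _retain(self) -> None:
        st = self.state
        self.alpha_sum += st.alpha
        if self.delta_sum is not None:
            self.delta_sum += st.delta
        self._draws["mu"].append(st.mu)
        self._draws["sigma2_e"].append(st.sigma2_e)
        self._draws["pi"].append(st.pi if st.pi is not None else np.nan)
        self._draws["sigma2_a"].append(
            st.sigma2_a if st.sigma2_a is not None else np.nan)
        self.n_saved += 1

    def finalize(self) -> PosteriorSamples:
        return PosteriorSamples(
            model=self.state.model, n_saved=self.n_saved,
            alpha_sum=self.alpha_sum.copy(),
            delta_sum=None if self.delta_sum is None else self.delta_sum.copy(),
            draws={k: np.asarray(v) for k, v in self._draws.items()},
            monitored_trace=self.monitored_trace.copy(),
            monitored_snps=self.monitored_snps.copy(),
            n_iter=self.state.iteration,
            burn_in=self.burn_in if self.burn_in is not None else 0,
            thin=self.thin, seed=self.seed,
            meta={"hyper": self.state.hyper})


def run_chain(y, G, model: str, hyper: Hyperparameters | None = None,
              n_iter: int = 50000, burn_in: int = 5000, thin: int = 10,
              monitored: np.ndarray | None = None, seed: int = 0,
              overdispersion: float = 4.0,
              use_kernel: bool = True) -> PosteriorSamples:
    """Run one chain with a fixed burn-in and return its retained draws;
    saved count = floor((n_iter - burn_in)/thin)."""
    if burn_in >= n_iter:
        raise ValueError("burn_in must be smaller than n_iter")
    chain = GibbsChain(y, G, model, hyper, seed, overdispersion, thin,
                       monitored, burn_in=burn_in, use_kernel=use_kernel)
    chain.advance(n_iter)
    return chain.finalize()


__all__ = [
    "Hyperparameters", "ChainState", "PosteriorSamples", "GibbsChain",
    "scaled_inv_chi2", "init_chain", "update_mu", "update_snp_bayesA",
    "update_snp_bayesCpi", "snp_inclusion_probability", "update_pi",
    "update_common_var", "update_residual_var", "gibbs_iteration",
    "run_chain", "default_monitor",
]
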