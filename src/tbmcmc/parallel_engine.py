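"""Multiple-chain execution, sample pooling and Amdahl-law arithmetic.

K chains (seeds ``base_seed + chain index``) run either with a fixed
burn-in — fully independent, so whole chains can run on separate
workers — or with the tunable burn-in, where chains advance in lockstep
between diagnostic barriers and the controller in
:mod:`tbmcmc.convergence` declares the shared burn-in end.  Results are
identical whether chains run sequentially or on a process pool: a chain
is a pure function of its seed and the merge order is fixed by chain
index.
"""

from __future__ import annotations

import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .bayes_samplers import GibbsChain, Hyperparameters, PosteriorSamples
from .convergence import MonitorConfig, ShrinkSeries, burnin_controller

logger = logging.getLogger(__name__)


@dataclass
class RunPlan:
    """Execution plan for one multiple-chain run."""

    n_chains: int = 4
    n_iter: int = 50000
    burn_in_mode: str = "fixed"          # "fixed" | "tunable"
    fixed_burn_in: int = 5000
    monitor: MonitorConfig = field(default_factory=MonitorConfig)
    max_burn_in: Optional[int] = None    # tunable mode; default n_iter // 2
    thin: int = 10
    base_seed: int = 0
    overdispersion: float = 4.0

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.burn_in_mode not in ("fixed", "tunable"):
            raise ValueError(f"unknown burn_in_mode {self.burn_in_mode!r}")
        if self.burn_in_mode == "fixed" and not \
                0 <= self.fixed_burn_in < self.n_iter:
            raise ValueError("fixed_burn_in must lie in [0, n_iter)")


@dataclass
class PooledSamples:
    """Merged posterior samples across chains, chain-index order."""

    per_chain: list[PosteriorSamples]
    alpha_mean: np.ndarray
    delta_mean: Optional[np.ndarray]
    burn_in_ends: list[int]
    total_kept: int
    converged: bool
    shrink: Optional[ShrinkSeries] = None
    plan: Optional[RunPlan] = None

    @property
    def n_chains(self) -> int:
        return len(self.per_chain)


def _run_whole(chain: GibbsChain, n_steps: int) -> GibbsChain:
    return chain.advance(n_steps)


class _Pool:
    """Map chains over workers; sequential when n_workers == 1."""

    def __init__(self, n_workers: int):
        self.n_workers = max(1, int(n_workers))
        self._ex = ProcessPoolExecutor(self.n_workers) if self.n_workers > 1 \
            else None

    def advance(self, chains: list[GibbsChain], n_steps: int) -> list[GibbsChain]:
        if self._ex is None:
            for c in chains:
                c.advance(n_steps)
            return chains
        out = list(self._ex.map(_run_whole, chains, [n_steps] * len(chains)))
        chains[:] = out
        return chains

    def close(self) -> None:
        if self._ex is not None:
            self._ex.shutdown()


def pool_samples(per_chain: list[PosteriorSamples],
                 converged: bool = True,
                 shrink: ShrinkSeries | None = None,
                 plan: RunPlan | None = None) -> PooledSamples:
    """Thin-within-chain draws are already retained; merge running sums
    weighted by per-chain saved counts."""
    total = sum(s.n_saved for s in per_chain)
    alpha_sum = np.sum([s.alpha_sum for s in per_chain], axis=0)
    alpha_mean = alpha_sum / max(total, 1)
    if per_chain[0].delta_sum is not None:
        delta_mean = np.sum([s.delta_sum for s in per_chain], axis=0) / max(total, 1)
    else:
        delta_mean = None
    return PooledSamples(per_chain=per_chain, alpha_mean=alpha_mean,
                         delta_mean=delta_mean,
                         burn_in_ends=[s.burn_in for s in per_chain],
                         total_kept=total, converged=converged,
                         shrink=shrink, plan=plan)


def run_parallel(y, G, model: str, hyper: Hyperparameters | None = None,
                 plan: RunPlan | None = None,
                 n_workers: int = 1) -> PooledSamples:
    """Run the plan's K chains and pool their post-burn-in samples.

    Fixed mode discards the first ``fixed_burn_in`` draws of every
    chain; tunable mode synchronizes chains at diagnostic barriers,
    lets the burn-in controller declare one shared burn-in end, and
    retains from there.  With ``n_workers > 1`` chains (or chunks of
    them, in tunable mode) are dispatched to a process pool; output is
    bit-identical to the sequential execution.
    """
    plan = plan or RunPlan()
    workers = _Pool(n_workers)
    try:
        chains = [GibbsChain(y, G, model, hyper,
                             seed=plan.base_seed + i,
                             overdispersion=plan.overdispersion,
                             thin=plan.thin)
                  for i in range(plan.n_chains)]
        if plan.burn_in_mode == "fixed":
            for c in chains:
                c.burn_in = plan.fixed_burn_in
            chains = workers.advance(chains, plan.n_iter)
            conv, shrink = True, None
        else:
            if plan.n_chains < 2:
                raise ValueError("tunable burn-in needs at least 2 chains")
            cap = plan.max_burn_in if plan.max_burn_in is not None \
                else plan.n_iter // 2
            burn_end, shrink, conv = burnin_controller(
                chains, plan.monitor, max_burn_in=cap,
                advance=lambda cs, n: workers.advance(cs, n))
            for c in chains:
                c.burn_in = burn_end
            remaining = plan.n_iter - chains[0].iteration
            if remaining > 0:
                chains = workers.advance(chains, remaining)
    finally:
        workers.close()
    return pool_samples([c.finalize() for c in chains], converged=conv,
                        shrink=shrink, plan=plan)


# ---------------------------------------------------------------------------
# Amdahl-law arithmetic


def speedup(N_T: float, N_burn: float, K: int) -> float:
    """Speedup of K parallel chains over one sequential chain when the
    burn-in cannot be parallelized: S(K) = N_T / (N_burn + (N_T - N_burn)/K).
    """
    if not 0 <= N_burn < N_T:
        raise ValueError("need 0 <= N_burn < N_T")
    if K < 1:
        raise ValueError("K must be >= 1")
    return N_T / (N_burn + (N_T - N_burn) / K)


def tuned_speedup(N_T_orig: float, N_burn_orig: float, N_burn_new: float,
                  K: int) -> float:
    """Speedup when burn-in tuning shortens the burn-in.

    The sequential baseline keeps its original cost ``N_T_orig`` and the
    parallelizable portion its original size ``N_T_orig - N_burn_orig``;
    only the serial burn-in term shrinks to ``N_burn_new``:

        S = N_T_orig / (N_burn_new + (N_T_orig - N_burn_orig)/K).

    With ``N_burn_new == N_burn_orig`` this reduces to :func:`speedup`.
    """
    if not N_burn_new <= N_burn_orig < N_T_orig:
        raise ValueError("need N_burn_new <= N_burn_orig < N_T_orig")
    if N_burn_new < 0 or K < 1:
        raise ValueError("invalid burn-in or core count")
    return N_T_orig / (N_burn_new + (N_T_orig - N_burn_orig) / K)


def efficiency(S: float, K: int) -> float:
    """Parallel efficiency E = S(K)/K."""
    if K < 1:
        raise ValueError("K must be >= 1")
    return S / K


__all__ = ["RunPlan", "PooledSamples", "run_parallel", "pool_samples",
           "speedup", "tuned_speedup", "efficiency"]
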