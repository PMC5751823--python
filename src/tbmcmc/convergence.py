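"""Gelman-Rubin shrink factors and the windowed burn-in stopping rule.

For each monitored scalar parameter, m chains of n draws give

    I      = n/(m-1) * sum_i (xbar_i - xbar)^2          (inter-chain)
    W      = mean_i s_i^2                               (within-chain)
    varhat = (n-1)/n * W + I/n
    r      = sqrt(varhat / W)                           (shrink factor)

with s_i^2 the usual (n-1)-denominator variance.  No chain splitting
and no degrees-of-freedom correction are applied.  Shrink factors are
evaluated on all draws from iteration 1 at a fixed cadence; burn-in
ends at the first evaluation where, for every monitored parameter, the
trailing window of p shrink factors satisfies |mean(r) - 1| < T and
popsd(r) < T.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class MonitorConfig:
    """Settings of the convergence monitor.

    ``T`` is the unitless convergence threshold applied to both the
    window mean's distance from 1 and the window SD; ``p`` the window
    length in diagnostic points; ``check_every`` the iteration gap
    between diagnostic evaluations; ``min_samples`` the minimum
    per-chain draw count before any verdict.
    """

    T: float = 0.001
    p: int = 10
    check_every: int = 100
    min_samples: int = 200
    monitored_params: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("threshold T must be positive")
        if self.p < 2:
            raise ValueError("window length p must be >= 2")
        if self.check_every < 1:
            raise ValueError("check_every must be >= 1")


@dataclass
class ShrinkSeries:
    """Shrink-factor history of one monitored run."""

    param_names: list[str]
    iterations: list[int] = field(default_factory=list)
    r_values: list[np.ndarray] = field(default_factory=list)  # per eval, per param
    window_stats: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    verdict_iteration: Optional[int] = None

    def append(self, iteration: int, r: np.ndarray) -> None:
        self.iterations.append(int(iteration))
        self.r_values.append(np.asarray(r, dtype=np.float64))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.r_values) if self.r_values else \
            np.empty((0, len(self.param_names)))

    def to_frame(self):
        import pandas as pd
        arr = self.as_array()
        rows = []
        for i, it in enumerate(self.iterations):
            for k, name in enumerate(self.param_names):
                rows.append((it, name, arr[i, k]))
        return pd.DataFrame(rows, columns=["iteration", "parameter", "r"])


def shrink_factor(samples: np.ndarray) -> float:
    """Potential scale reduction of one scalar parameter.

    ``samples`` is an (m chains, n draws) array, m >= 2, n >= 2.  When
    every chain is internally constant (W = 0) the statistic is
    undefined; identical chains return 1.0, differing chains +inf with
    a warning.
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("shrink_factor needs an (m>=2, n>=2) array")
    m, n = x.shape
    chain_means = x.mean(axis=1)
    grand = chain_means.mean()
    I = n / (m - 1.0) * float(((chain_means - grand) ** 2).sum())
    W = float(x.var(axis=1, ddof=1).mean())
    if W == 0.0:
        if I == 0.0:
            return 1.0
        warnings.warn("all chains internally constant but differ between "
                      "chains; shrink factor is infinite", RuntimeWarning)
        return np.inf
    varhat = (n - 1.0) / n * W + I / n
    return float(np.sqrt(varhat / W))


def window_stats(R_window: Sequence[float]) -> tuple[float, float]:
    """Mean and population (1/p-denominator) SD of one shrink-factor window."""
    w = np.asarray(R_window, dtype=np.float64)
    return float(w.mean()), float(w.std(ddof=0))


def converged(r_bar: float, S: float, T: float) -> bool:
    """True iff |r_bar - 1| < T and S < T (both strict)."""
    return abs(r_bar - 1.0) < T and S < T


def burnin_controller(chains, cfg: MonitorConfig,
                      max_burn_in: int,
                      advance=None) -> tuple[int, ShrinkSeries, bool]:
    """Drive live chains to the end of burn-in.

    Every ``cfg.check_every`` iterations all chains advance in lockstep
    (through ``advance(chains, n_steps)`` if given, else sequentially),
    shrink factors are computed per monitored parameter from all draws
    so far, and the trailing window of ``cfg.p`` diagnostic points is
    tested.  Returns (burn_in_end, series, converged_flag); on reaching
    ``max_burn_in`` without a verdict the flag is False.
    """
    if len(chains) < 2:
        raise ValueError("burn-in diagnosis needs at least 2 chains")
    iters = {c.iteration for c in chains}
    if len(iters) != 1:
        raise RuntimeError(f"chains desynchronized at iterations {sorted(iters)}")
    t = iters.pop()

    n_mon = 1 + len(chains[0].monitored_snps)
    names = cfg.monitored_params
    if names is None:
        names = ["sigma2_e"] + [f"alpha[{j}]" for j in chains[0].monitored_snps]
    series = ShrinkSeries(param_names=list(names))

    while t < max_burn_in:
        step = min(cfg.check_every, max_burn_in - t)
        if advance is not None:
            advance(chains, step)
        else:
            for c in chains:
                c.advance(step)
        t += step
        iters = {c.iteration for c in chains}
        if iters != {t}:
            raise RuntimeError(f"chains desynchronized at iterations {sorted(iters)}")
        if t < max(cfg.min_samples, 2):
            continue
        traces = np.stack([c.monitored_trace for c in chains])  # (m, t, P)
        r = np.array([shrink_factor(traces[:, :, k]) for k in range(n_mon)])
        series.append(t, r)
        if len(series.r_values) >= cfg.p:
            win = np.asarray(series.r_values[-cfg.p:])
            means = win.mean(axis=0)
            sds = win.std(axis=0, ddof=0)
            series.window_stats.append((means, sds))
            if all(converged(means[k], sds[k], cfg.T) for k in range(n_mon)):
                series.verdict_iteration = t
                logger.info("burn-in converged at iteration %d "
                            "(max |r_bar-1| = %.2e, max S = %.2e)",
                            t, float(np.abs(means - 1).max()), float(sds.max()))
                return t, series, True
    logger.warning("burn-in did not converge within %d iterations", max_burn_in)
    return max_burn_in, series, False


__all__ = ["MonitorConfig", "ShrinkSeries", "shrink_factor", "window_stats",
           "converged", "burnin_controller"]
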