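"""Numba kernels for the per-SNP Gibbs sweeps.

These consume the same ``numpy.random.Generator`` stream, in the same
call order, as the pure-Python reference updates in
:mod:`tbmcmc.bayes_samplers`; the two paths are bit-identical and the
test suite asserts it.  Genotype matrices are passed Fortran-ordered so
column access is contiguous.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def sweep_bayesA(X, xtx, resid, alpha, sigma2_j, sigma2_e, nu, S2, rng):
    n, M = X.shape
    for j in range(M):
        aj = alpha[j]
        if xtx[j] > 0.0:
            r = xtx[j] * aj
            for i in range(n):
                r += X[i, j] * resid[i]
            lhs = xtx[j] + sigma2_e / sigma2_j[j]
            anew = rng.normal(r / lhs, np.sqrt(sigma2_e / lhs))
            diff = aj - anew
            for i in range(n):
                resid[i] += X[i, j] * diff
            alpha[j] = anew
        else:
            # constant column: no likelihood information, prior draw
            alpha[j] = rng.normal(0.0, np.sqrt(sigma2_j[j]))
        df = nu + 1.0
        scale = (nu * S2 + alpha[j] * alpha[j]) / df
        sigma2_j[j] = df * scale / rng.chisquare(df)


@njit(cache=True)
def sweep_bayesCpi(X, xtx, resid, alpha, delta, sigma2_a, pi, sigma2_e, rng):
    n, M = X.shape
    for j in range(M):
        aj = alpha[j]
        if xtx[j] > 0.0:
            r = xtx[j] * aj
            for i in range(n):
                r += X[i, j] * resid[i]
            lhs = xtx[j] + sigma2_e / sigma2_a
            # log Bayes factor of inclusion vs exclusion, alpha integrated out
            logbf = 0.5 * (np.log(sigma2_e / (sigma2_a * lhs))
                           + r * r / (sigma2_e * lhs))
        else:
            r = 0.0
            lhs = sigma2_e / sigma2_a
            logbf = 0.0
        if pi >= 1.0:
            p_incl = 0.0
        elif pi <= 0.0:
            p_incl = 1.0
        else:
            logodds = logbf + np.log((1.0 - pi) / pi)
            if logodds > 35.0:
                p_incl = 1.0
            elif logodds < -35.0:
                p_incl = 0.0
            else:
                p_incl = 1.0 / (1.0 + np.exp(-logodds))
        if rng.random() < p_incl:
            anew = rng.normal(r / lhs, np.sqrt(sigma2_e / lhs))
            delta[j] = 1
        else:
            anew = 0.0
            delta[j] = 0
        diff = aj - anew
        if diff != 0.0 and xtx[j] > 0.0:
            for i in range(n):
                resid[i] += X[i, j] * diff
        alpha[j] = anew


__all__ = ["sweep_bayesA", "sweep_bayesCpi"]
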