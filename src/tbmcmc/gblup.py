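"""GBLUP benchmark: genomic relationship matrix, REML, BLUP.

The animal model is y = 1 mu + u + e with u ~ N(0, G sigma2_u) and the
VanRaden genomic relationship matrix G = X X' / (2 sum q(1-q)), X the
allele-frequency-centered genotype matrix.  Variance components come
from a restricted likelihood profiled over the ratio
lambda = sigma2_u / sigma2_e via one eigendecomposition of G and a
bounded one-dimensional search — exact and deterministic at the sample
sizes this package targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .genotype_data import GenotypeMatrix, center_genotypes

logger = logging.getLogger(__name__)


@dataclass
class GRM:
    G: np.ndarray
    denom: float
    individual_ids: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.G.shape[0]


@dataclass
class VarianceComponents:
    sigma2_u: float
    sigma2_e: float
    loglik: float

    @property
    def h2(self) -> float:
        tot = self.sigma2_u + self.sigma2_e
        return self.sigma2_u / tot if tot > 0 else 0.0

    @property
    def lam(self) -> float:
        """Variance ratio sigma2_u / sigma2_e."""
        return self.sigma2_u / self.sigma2_e


def compute_grm(G: GenotypeMatrix) -> GRM:
    """VanRaden genomic relationship matrix from a QC'd panel."""
    q = G.compute_allele_freq()
    if np.any((q <= 0.0) | (q >= 1.0)):
        raise ValueError("monomorphic SNPs present; apply qc_filter before "
                         "building the relationship matrix")
    X = center_genotypes(G)
    denom = float(2.0 * np.sum(q * (1.0 - q)))
    mat = (X @ X.T) / denom
    mat = (mat + mat.T) / 2.0  # enforce exact symmetry
    return GRM(G=mat, denom=denom, individual_ids=G.individual_ids)


def _neg2_restricted_loglik(log_lam: float, d: np.ndarray, yt: np.ndarray,
                            xt: np.ndarray) -> float:
    lam = np.exp(log_lam)
    w = 1.0 / (lam * d + 1.0)
    sxx = float(np.sum(w * xt * xt))
    mu = float(np.sum(w * xt * yt)) / sxx
    rss = float(np.sum(w * (yt - xt * mu) ** 2))
    n = len(yt)
    return ((n - 1) * np.log(rss / (n - 1)) - np.sum(np.log(w))
            + np.log(sxx))


def reml_fit(y_adj: np.ndarray, grm: GRM,
              lam_bounds: tuple[float, float] = (1e-6, 1e6)) -> VarianceComponents:
    """REML variance components of y = 1 mu + u + e, u ~ N(0, G sigma2_u).

    The restricted likelihood is profiled over lambda = sigma2_u/sigma2_e
    after rotating into the eigenbasis of G; sigma2_e is then the usual
    REML residual estimate at the optimum.
    """
    y = np.asarray(y_adj, dtype=np.float64)
    if grm.n != len(y):
        raise ValueError("relationship matrix does not match phenotype length")
    if np.var(y) == 0.0:
        raise ValueError("phenotype has zero variance")
    n = len(y)
    off = grm.G - np.diag(np.diag(grm.G))
    if np.abs(off).max() < 1e-12 and np.ptp(np.diag(grm.G)) < 1e-12:
        raise ValueError("relationship matrix is proportional to the "
                         "identity; genetic and residual variances are "
                         "not separable")
    d, U = np.linalg.eigh(grm.G)
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    xt = U.T @ np.ones(n)
    res = minimize_scalar(_neg2_restricted_loglik,
                          bounds=(np.log(lam_bounds[0]), np.log(lam_bounds[1])),
                          args=(d, yt, xt), method="bounded",
                          options={"xatol": 1e-10})
    lam = float(np.exp(res.x))
    w = 1.0 / (lam * d + 1.0)
    sxx = float(np.sum(w * xt * xt))
    mu = float(np.sum(w * xt * yt)) / sxx
    sigma2_e = float(np.sum(w * (yt - xt * mu) ** 2)) / (n - 1)
    return VarianceComponents(sigma2_u=lam * sigma2_e, sigma2_e=sigma2_e,
                              loglik=-0.5 * float(res.fun))


def restricted_loglik(y_adj: np.ndarray, grm: GRM, lam: float) -> float:
    """Profile restricted log-likelihood at a given variance ratio
    (same constant-dropping convention as :func:`reml_fit`)."""
    y = np.asarray(y_adj, dtype=np.float64)
    d, U = np.linalg.eigh(grm.G)
    d = np.clip(d, 0.0, None)
    return -0.5 * _neg2_restricted_loglik(np.log(lam), d, U.T @ y,
                                          U.T @ np.ones(len(y)))


def gblup_predict(y_train: np.ndarray, grm: GRM, train_idx: np.ndarray,
                  test_idx: np.ndarray,
                  vc: VarianceComponents) -> np.ndarray:
    """BLUP of breeding values for all individuals from training records.

    u_hat = G[:, train] (G[train, train] + (sigma2_e/sigma2_u) I)^-1
            (y_train - mu_hat), mu_hat the GLS mean on the training set.
    """
    train_idx = np.asarray(train_idx, dtype=np.int64)
    test_idx = np.asarray(test_idx, dtype=np.int64)
    if np.intersect1d(train_idx, test_idx).size:
        raise ValueError("train and test index sets must be disjoint")
    y_train = np.asarray(y_train, dtype=np.float64)
    if len(y_train) != len(train_idx):
        raise ValueError("y_train must align with train_idx")
    n = grm.n
    if vc.sigma2_u <= 0.0:
        return np.zeros(n)
    lam_inv = vc.sigma2_e / vc.sigma2_u
    Gtt = grm.G[np.ix_(train_idx, train_idx)]
    C = Gtt + lam_inv * np.eye(len(train_idx))
    try:
        Cinv_y = np.linalg.solve(C, y_train)
        Cinv_1 = np.linalg.solve(C, np.ones(len(train_idx)))
    except np.linalg.LinAlgError:
        jitter = 1e-8 * np.trace(C) / len(train_idx)
        logger.warning("singular mixed-model system; adding %g jitter", jitter)
        C = C + jitter * np.eye(len(train_idx))
        Cinv_y = np.linalg.solve(C, y_train)
        Cinv_1 = np.linalg.solve(C, np.ones(len(train_idx)))
    mu_hat = float(np.ones(len(train_idx)) @ Cinv_y) / \
        float(np.ones(len(train_idx)) @ Cinv_1)
    rhs = np.linalg.solve(C, y_train - mu_hat)
    return grm.G[:, train_idx] @ rhs


__all__ = ["GRM", "VarianceComponents", "compute_grm", "reml_fit",
           "restricted_loglik", "gblup_predict"]
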