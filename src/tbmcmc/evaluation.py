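"""Genomic prediction evaluation: GEBVs, accuracies, cross-validation.

The genomic estimated breeding value of individual i is the weighted
sum of its raw 0/1/2 genotype codes by the estimated SNP effects,
GEBV_i = sum_j X_ij g_j.  Prediction accuracy (GPA) is the Pearson
correlation between GEBVs and true breeding values (simulation) or
adjusted phenotypes (real data); relative accuracy (RGPA) divides by
sqrt(h2) so traits of different heritability are comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .bayes_samplers import Hyperparameters
from .genotype_data import GenotypeMatrix
from .gblup import compute_grm, gblup_predict, reml_fit

logger = logging.getLogger(__name__)

#: A training/prediction routine for cross-validation: receives the full
#: phenotype vector and genotypes plus the index split, must use only
#: ``y[train_idx]``, and returns predictions for ``test_idx``.
Predictor = Callable[[np.ndarray, GenotypeMatrix, np.ndarray, np.ndarray],
                     np.ndarray]


@dataclass
class PredictionResult:
    gebv: np.ndarray
    gpa: float
    rgpa: Optional[float] = None
    fold_assignments: Optional[np.ndarray] = None
    replicate_id: Optional[int] = None


def gebv(G, effects: np.ndarray) -> np.ndarray:
    """GEBV_i = sum_j X_ij g_j over raw 0/1/2 codes."""
    calls = G.calls if isinstance(G, GenotypeMatrix) else np.asarray(G, float)
    effects = np.asarray(effects, dtype=np.float64)
    if calls.shape[1] != len(effects):
        raise ValueError(f"effect vector length {len(effects)} does not match "
                         f"{calls.shape[1]} SNPs")
    return calls @ effects


def gpa(gebv_vec: np.ndarray, truth: np.ndarray) -> float:
    """Pearson correlation between predictions and truth."""
    a = np.asarray(gebv_vec, dtype=np.float64)
    b = np.asarray(truth, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        raise ValueError("correlation undefined for a zero-variance vector")
    return float(np.corrcoef(a, b)[0, 1])


def rgpa(r: float, h2: float) -> float:
    """Relative accuracy r / sqrt(h2)."""
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must lie in (0, 1]")
    return r / np.sqrt(h2)


# ---------------------------------------------------------------------------
# ready-made predictors for cross-validation


def make_gblup_predictor() -> Predictor:
    """GBLUP: GRM from all genotypes, REML and BLUP on the training set."""
    def predict(y, G, train_idx, test_idx):
        grm = compute_grm(G) if isinstance(G, GenotypeMatrix) else G
        vc = reml_fit(np.asarray(y)[train_idx],
                      _subset_grm(grm, train_idx))
        full = gblup_predict(np.asarray(y)[train_idx], grm, train_idx,
                             test_idx, vc)
        return full[test_idx]
    return predict


def _subset_grm(grm, idx):
    from .gblup import GRM
    return GRM(G=grm.G[np.ix_(idx, idx)], denom=grm.denom)


def make_bayes_predictor(model: str, hyper: Hyperparameters | None = None,
                         n_iter: int = 2000, burn_in: int = 400,
                         thin: int = 10, seed: int = 0) -> Predictor:
    """Single-chain Bayesian whole-genome regression predictor."""
    from .bayes_samplers import run_chain

    def predict(y, G, train_idx, test_idx):
        calls = G.calls if isinstance(G, GenotypeMatrix) else np.asarray(G, float)
        samples = run_chain(np.asarray(y)[train_idx], calls[train_idx],
                            model, hyper, n_iter=n_iter, burn_in=burn_in,
                            thin=thin, seed=seed)
        return gebv(calls[test_idx], samples.alpha_mean)
    return predict


# ---------------------------------------------------------------------------
# cross-validation


def kfold_cv(y: np.ndarray, G, predictor: Predictor, k: int = 5,
             replicates: int = 10, seed: int = 0,
             truth: np.ndarray | None = None,
             h2: float | None = None) -> dict:
    """k-fold cross-validation repeated over random re-partitions.

    Each replicate randomly splits individuals into k near-equal folds
    (sizes differ by at most one); each fold is predicted from a model
    trained on the remainder, and the replicate's GPA is one Pearson
    correlation over the pooled out-of-fold predictions against
    ``truth`` (true breeding values if available, else the phenotype).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    if n // k < 2:
        raise ValueError("folds would contain fewer than 2 individuals")
    target = y if truth is None else np.asarray(truth, dtype=np.float64)
    rng = np.random.default_rng(seed)
    rows, rep_gpa = [], []
    preds_by_rep = []
    for rep in range(replicates):
        perm = rng.permutation(n)
        folds = np.empty(n, dtype=np.int64)
        for f, chunk in enumerate(np.array_split(perm, k)):
            folds[chunk] = f
        preds = np.empty(n)
        for f in range(k):
            test_idx = np.where(folds == f)[0]
            train_idx = np.where(folds != f)[0]
            pred = predictor(y, G, train_idx, test_idx)
            preds[test_idx] = pred
            rows.append({"replicate": rep, "fold": f,
                         "n_test": len(test_idx),
                         "gpa": gpa(pred, target[test_idx])})
        r = gpa(preds, target)
        rep_gpa.append(r)
        preds_by_rep.append((folds, preds))
    mean_gpa = float(np.mean(rep_gpa))
    out = {
        "per_fold": pd.DataFrame(rows),
        "per_replicate": pd.DataFrame({"replicate": range(replicates),
                                       "gpa": rep_gpa}),
        "mean_gpa": mean_gpa,
        "folds": preds_by_rep[0][0],
        "gpa_definition": "pooled out-of-fold predictions per replicate",
    }
    if h2 is not None:
        out["mean_rgpa"] = rgpa(mean_gpa, h2)
    return out


__all__ = ["PredictionResult", "Predictor", "gebv", "gpa", "rgpa",
           "make_gblup_predictor", "make_bayes_predictor", "kfold_cv"]
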