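"""Genotype/phenotype ingestion, quality control and encoding.

Genotypes are held as allele counts of a designated counted allele
(0/1/2, the minor allele as determined at read time), with missing calls
stored as NaN until quality control imputes them.  Every downstream
module (samplers, GBLUP, simulator consumers) expects a clean, fully
observed matrix produced by :func:`qc_filter`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SEX_CHROM_LABELS = frozenset({"X", "Y", "XY", "CHRX", "CHRY"})


class GenotypeParseError(ValueError):
    """Malformed genotype input (carries the offending line number)."""


class EmptyPanelError(ValueError):
    """All SNPs were removed by quality control."""


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs matrix of 0/1/2 allele counts.

    ``calls`` is float64 so that missing cells can be NaN before
    imputation and fractional mean-imputed dosages can be stored after.
    Columns align 1:1 with ``snp_ids``/``chrom``/``pos``/``allele_freq``.
    """

    calls: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    individual_ids: np.ndarray
    allele_freq: np.ndarray = field(default=None)  # type: ignore[assignment]
    counted_allele: np.ndarray | None = None  # which allele 0/1/2 counts

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.float64)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("snp_ids must be unique")
        n_snp = self.calls.shape[1] if self.calls.ndim == 2 else 0
        for name, arr in (("snp_ids", self.snp_ids), ("chrom", self.chrom),
                          ("pos", self.pos)):
            if len(arr) != n_snp:
                raise ValueError(f"{name} length {len(arr)} != SNP count {n_snp}")
        if self.allele_freq is None:
            self.allele_freq = self.compute_allele_freq()
        self.allele_freq = np.asarray(self.allele_freq, dtype=np.float64)

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.calls)

    def compute_allele_freq(self) -> np.ndarray:
        """Frequency of the counted allele: sum of calls / (2 x observed)."""
        if self.calls.size == 0:
            return np.zeros(self.calls.shape[1] if self.calls.ndim == 2 else 0)
        obs = ~np.isnan(self.calls)
        n_obs = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            q = np.nansum(self.calls, axis=0) / (2.0 * np.maximum(n_obs, 1))
        q[n_obs == 0] = np.nan
        return q

    def maf(self) -> np.ndarray:
        q = self.compute_allele_freq()
        return np.minimum(q, 1.0 - q)


@dataclass
class PhenotypeTable:
    """Raw and covariate-adjusted phenotypes for one trait."""

    y_raw: np.ndarray
    y_adj: np.ndarray
    covariates: pd.DataFrame | None = None
    tbv: np.ndarray | None = None
    h2: float | None = None
    individual_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y_raw = np.asarray(self.y_raw, dtype=np.float64)
        self.y_adj = np.asarray(self.y_adj, dtype=np.float64)
        if self.y_adj.shape != self.y_raw.shape:
            raise ValueError("y_adj must align with y_raw")
        if self.tbv is not None:
            self.tbv = np.asarray(self.tbv, dtype=np.float64)


@dataclass
class QCReport:
    """Per-rule removal bookkeeping; each SNP attributed to the first
    rule (sex-chromosome -> MAF -> missingness -> HWE) that removed it."""

    n_input: int
    n_removed_by_rule: dict[str, int]
    removed_ids: dict[str, list]
    n_kept: int

    RULES = ("sex_chrom", "maf", "missing", "hwe")

    def __post_init__(self) -> None:
        total = self.n_kept + sum(self.n_removed_by_rule.values())
        if total != self.n_input:
            raise ValueError(
                f"QC conservation violated: {self.n_input} != kept {self.n_kept}"
                f" + removed {sum(self.n_removed_by_rule.values())}")


# ---------------------------------------------------------------------------
# readers


def read_genotypes(path: str, format: str = "ped_map") -> GenotypeMatrix:
    """Read a PLINK text fileset (``.ped``/``.map``) or a TSV genotype table.

    For ``ped_map``, ``path`` may be the ``.ped`` file or the common
    prefix.  Allele pairs are converted to counts of the per-SNP minor
    allele ("0" denotes a missing allele and flags the cell missing).
    """
    if format == "ped_map":
        return _read_ped_map(path)
    if format == "genotype_table":
        return _read_genotype_table(path)
    raise ValueError(f"unknown format {format!r}")


def _read_map(path: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    chroms, ids, poss = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) not in (3, 4):
                raise GenotypeParseError(
                    f"{path}: line {lineno}: expected 3 or 4 columns, got {len(parts)}")
            chroms.append(parts[0])
            ids.append(parts[1])
            try:
                poss.append(int(parts[-1]))
            except ValueError as exc:
                raise GenotypeParseError(
                    f"{path}: line {lineno}: bad base-pair position {parts[-1]!r}") from exc
    return np.array(chroms, dtype=object), np.array(ids, dtype=object), np.array(poss)


def _read_ped_map(path: str) -> GenotypeMatrix:
    if path.endswith(".ped"):
        prefix = path[: -len(".ped")]
    else:
        prefix = path
    chrom, snp_ids, pos = _read_map(prefix + ".map")
    m = len(snp_ids)
    indiv_ids, allele_rows = [], []
    with open(prefix + ".ped") as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise GenotypeParseError(
                    f"{prefix}.ped: line {lineno}: expected {6 + 2 * m} fields"
                    f" for {m} SNPs, got {len(parts)}")
            indiv_ids.append(parts[1])
            allele_rows.append(parts[6:])
    n = len(indiv_ids)
    calls = np.full((n, m), np.nan)
    counted = np.empty(m, dtype=object)
    alleles = np.array(allele_rows, dtype=object).reshape(n, m, 2) if n else \
        np.empty((0, m, 2), dtype=object)
    for j in range(m):
        a = alleles[:, j, :].ravel()
        observed = a[a != "0"]
        counts: dict[str, int] = {}
        for al in observed:
            counts[al] = counts.get(al, 0) + 1
        if len(counts) > 2:
            raise GenotypeParseError(
                f"{prefix}.ped: SNP {snp_ids[j]} has {len(counts)} alleles")
        if not counts:
            counted[j] = None
            continue
        if len(counts) == 1:
            # monomorphic: the minor allele was never observed, so every
            # observed genotype carries 0 copies of it
            counted[j] = None
            for i in range(n):
                a1, a2 = alleles[i, j]
                if a1 != "0" and a2 != "0":
                    calls[i, j] = 0.0
            continue
        # counted allele = minor; on a tie the lexicographically greater one
        a_one, a_two = sorted(counts)
        if counts[a_one] == counts[a_two]:
            minor = a_two
        else:
            minor = a_one if counts[a_one] < counts[a_two] else a_two
        counted[j] = minor
        for i in range(n):
            a1, a2 = alleles[i, j]
            if a1 == "0" or a2 == "0":
                continue
            calls[i, j] = (a1 == minor) + (a2 == minor)
    return GenotypeMatrix(calls=calls, snp_ids=snp_ids, chrom=chrom, pos=pos,
                          individual_ids=np.array(indiv_ids, dtype=object),
                          counted_allele=counted)


def _read_genotype_table(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    snp_ids = np.array(df.columns, dtype=object)
    try:
        calls = df.apply(pd.to_numeric, errors="raise").to_numpy(dtype=np.float64) \
            if len(df) else np.empty((0, len(snp_ids)))
    except ValueError as exc:
        raise GenotypeParseError(f"{path}: non-numeric genotype code: {exc}") from exc
    bad = calls[~np.isnan(calls)]
    if bad.size and not np.isin(bad, (0.0, 1.0, 2.0)).all():
        raise GenotypeParseError(f"{path}: genotype codes must be 0/1/2 or missing")
    m = len(snp_ids)
    return GenotypeMatrix(
        calls=calls, snp_ids=snp_ids,
        chrom=np.array(["0"] * m, dtype=object),
        pos=np.arange(1, m + 1),
        individual_ids=np.array(df.index, dtype=object))


def read_phenotypes(path: str, trait: str,
                    covariate_cols: list[str] | None = None) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Read a phenotype/covariate TSV keyed by an individual-id column."""
    df = pd.read_csv(path, sep="\t")
    ids = df.iloc[:, 0].to_numpy(dtype=object)
    y = df[trait].to_numpy(dtype=np.float64)
    cov = df[covariate_cols] if covariate_cols else pd.DataFrame(index=df.index)
    return y, cov, ids


# ---------------------------------------------------------------------------
# quality control


def hwe_chi2(n_AA: int, n_Aa: int, n_aa: int) -> tuple[float, float]:
    """One-degree-of-freedom chi-square goodness-of-fit test of
    Hardy-Weinberg genotype proportions.

    Monomorphic input carries no HWE information and returns (0, 1).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("total genotype count must be positive")
    p_hat = (2 * n_AA + n_Aa) / (2 * n)
    if p_hat in (0.0, 1.0):
        return 0.0, 1.0
    exp = np.array([n * p_hat ** 2, 2 * n * p_hat * (1 - p_hat),
                    n * (1 - p_hat) ** 2])
    obs = np.array([n_AA, n_Aa, n_aa], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def qc_filter(G: GenotypeMatrix, maf_min: float = 0.05,
              max_missing: float = 0.05, hwe_p_min: float = 1e-6,
              drop_sex_chroms: bool = True) -> tuple[GenotypeMatrix, QCReport]:
    """Apply SNP quality control and mean-impute surviving missing calls.

    Removal rules are applied in fixed order (sex-chromosome, MAF < maf_min,
    missing fraction > max_missing, HWE p < hwe_p_min) and each removed SNP
    is attributed to the first rule that caught it.
    """
    if G.n_snps == 0:
        raise ValueError("qc_filter requires a non-empty panel")
    removed: dict[str, list] = {r: [] for r in QCReport.RULES}
    n, m = G.calls.shape
    miss = np.isnan(G.calls)
    n_obs = (~miss).sum(axis=0)
    maf = G.maf()
    keep = np.ones(m, dtype=bool)

    chrom_upper = np.array([str(c).upper() for c in G.chrom], dtype=object)
    for j in range(m):
        if drop_sex_chroms and chrom_upper[j] in SEX_CHROM_LABELS:
            removed["sex_chrom"].append(G.snp_ids[j]); keep[j] = False
        elif not (maf[j] >= maf_min):  # NaN (all-missing) also fails
            removed["maf"].append(G.snp_ids[j]); keep[j] = False
        elif miss[:, j].mean() > max_missing:
            removed["missing"].append(G.snp_ids[j]); keep[j] = False
        else:
            col = G.calls[~miss[:, j], j]
            _, p = hwe_chi2(int((col == 2).sum()), int((col == 1).sum()),
                            int((col == 0).sum()))
            if p < hwe_p_min:
                removed["hwe"].append(G.snp_ids[j]); keep[j] = False

    if not keep.any():
        raise EmptyPanelError("quality control removed every SNP in the panel")

    calls = G.calls[:, keep].copy()
    col_mean = np.nanmean(calls, axis=0)
    idx = np.where(np.isnan(calls))
    calls[idx] = col_mean[idx[1]]
    out = GenotypeMatrix(
        calls=calls, snp_ids=G.snp_ids[keep], chrom=G.chrom[keep],
        pos=G.pos[keep], individual_ids=G.individual_ids,
        counted_allele=None if G.counted_allele is None else G.counted_allele[keep])
    report = QCReport(
        n_input=m,
        n_removed_by_rule={r: len(v) for r, v in removed.items()},
        removed_ids=removed, n_kept=int(keep.sum()))
    return out, report


def adjust_phenotypes(y_raw: np.ndarray,
                      covariates: pd.DataFrame | None) -> PhenotypeTable:
    """Pre-correct a trait for systematic environment by ordinary least
    squares on an intercept plus dummy-expanded factors and numeric
    covariates; the adjusted phenotype is the residual shifted back to
    the grand mean so the trait scale is preserved."""
    y = np.asarray(y_raw, dtype=np.float64)
    if covariates is None or covariates.shape[1] == 0:
        return PhenotypeTable(y_raw=y, y_adj=y.copy(), covariates=covariates)
    if len(covariates) != len(y):
        raise ValueError("covariate rows must align with y_raw")
    blocks = [np.ones((len(y), 1))]
    for col in covariates.columns:
        s = covariates[col]
        if s.dtype.kind in "OUSb" or isinstance(s.dtype, pd.CategoricalDtype):
            blocks.append(pd.get_dummies(s, drop_first=True).to_numpy(dtype=float))
        else:
            blocks.append(s.to_numpy(dtype=float)[:, None])
    design = np.hstack(blocks)
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        logger.warning("adjust_phenotypes: design is rank deficient "
                       "(%d < %d); aliased columns absorbed by least squares",
                       rank, design.shape[1])
    resid = y - design @ beta
    return PhenotypeTable(y_raw=y, y_adj=resid + y.mean(), covariates=covariates)


def center_genotypes(G: GenotypeMatrix) -> np.ndarray:
    """Subtract twice the allele frequency from every column (the centered
    incidence matrix X used by the genomic relationship matrix)."""
    if np.isnan(G.calls).any():
        raise ValueError("center_genotypes requires no missing calls; run qc_filter")
    q = G.compute_allele_freq()
    return G.calls - 2.0 * q


__all__ = [
    "GenotypeMatrix", "PhenotypeTable", "QCReport", "GenotypeParseError",
    "EmptyPanelError", "read_genotypes", "read_phenotypes", "hwe_chi2",
    "qc_filter", "adjust_phenotypes", "center_genotypes",
]
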