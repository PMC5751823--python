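"""Forward-in-time quantitative-trait simulator.

Generates biallelic marker panels under a neutral mutation-drift model
(symmetric per-locus mutation, Poisson recombination on a 1 Morgan map
per chromosome, random mating in a small founder population), then lays
additive QTL effects over a subset of the markers and draws phenotypes
at a nominal heritability.  Three named scenario presets mirror the
simulation designs used throughout this package's validation suite:
1000-2000 individuals, 200 QTL, heritabilities 0.1/0.5/0.3 and marker
panels from 20,000 to 200,000 SNPs at mutation rate 1.25e-3.

This is an explicit stand-in simulator: it produces mutation-drift LD
structure at desk scale, not the output of any particular external tool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genotype_data import GenotypeMatrix, PhenotypeTable

logger = logging.getLogger(__name__)


@dataclass
class SimScenario:
    """Parameters of one simulated population/trait.

    ``mut_rate`` is the per-locus, per-generation probability that an
    allele flips; ``effective_size`` is the number of diploid founders
    carried through ``n_generations`` of random mating before the final
    expansion to ``n_individuals``.
    """

    n_individuals: int = 1000
    n_chrom: int = 5
    markers_per_chrom: int = 4000
    n_qtl: int = 200
    h2: float = 0.1
    mut_rate: float = 1.25e-3
    n_generations: int = 100
    effective_size: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must lie in (0, 1)")
        if self.n_qtl > self.n_chrom * self.markers_per_chrom:
            raise ValueError("n_qtl exceeds total marker count")
        for name in ("n_individuals", "n_chrom", "markers_per_chrom"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_qtl < 0:
            raise ValueError("n_qtl must be non-negative")

    @property
    def n_markers(self) -> int:
        return self.n_chrom * self.markers_per_chrom


#: Scenario presets: three population/trait designs spanning marker
#: densities of 20k, 50k and 200k SNPs.
SCENARIOS: dict[str, SimScenario] = {
    "scenario1": SimScenario(n_individuals=1000, n_chrom=5,
                             markers_per_chrom=4000, n_qtl=200, h2=0.1),
    "scenario2": SimScenario(n_individuals=1000, n_chrom=10,
                             markers_per_chrom=5000, n_qtl=200, h2=0.5),
    "scenario3": SimScenario(n_individuals=2000, n_chrom=5,
                             markers_per_chrom=40000, n_qtl=200, h2=0.3),
}


@dataclass
class SimOutput:
    genotypes: GenotypeMatrix
    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    tbv: np.ndarray
    phenotypes: PhenotypeTable
    scenario: SimScenario | None = None


def _gametes(rng: np.random.Generator, haps: np.ndarray,
             parents: np.ndarray, chrom_slices: list[slice]) -> np.ndarray:
    """One recombined gamete per parent.

    ``haps`` has shape (n_parents, 2, L); crossover counts per chromosome
    are Poisson(1) (a 1 Morgan map) with uniform breakpoints.
    """
    n_out = len(parents)
    L = haps.shape[2]
    out = np.empty((n_out, L), dtype=np.int8)
    for k, par in enumerate(parents):
        for sl in chrom_slices:
            ln = sl.stop - sl.start
            n_x = rng.poisson(1.0)
            cur = rng.integers(2)
            if n_x == 0 or ln < 2:
                out[k, sl] = haps[par, cur, sl]
                continue
            breaks = np.sort(rng.integers(1, ln, size=n_x))
            seg = np.empty(ln, dtype=np.int8)
            start = 0
            for b in list(breaks) + [ln]:
                seg[start:b] = haps[par, cur, sl][start:b]
                cur ^= 1
                start = b
            out[k, sl] = seg
    return out


def simulate_population(scn: SimScenario,
                        rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Neutral forward simulation of the marker panel.

    Founder haplotypes start monomorphic (all zero); polymorphism arises
    from mutation and is shaped by drift and recombination over
    ``n_generations`` of random mating, after which the final generation
    is expanded to ``n_individuals`` by random pairing of parents.
    """
    if scn.effective_size < 2:
        raise ValueError("effective_size must be at least 2")
    rng = np.random.default_rng(scn.seed) if rng is None else rng
    ne, L = scn.effective_size, scn.n_markers
    chrom_slices = [slice(c * scn.markers_per_chrom, (c + 1) * scn.markers_per_chrom)
                    for c in range(scn.n_chrom)]
    haps = np.zeros((ne, 2, L), dtype=np.int8)
    for _ in range(scn.n_generations):
        dams = rng.integers(ne, size=ne)
        sires = rng.integers(ne, size=ne)
        g1 = _gametes(rng, haps, dams, chrom_slices)
        g2 = _gametes(rng, haps, sires, chrom_slices)
        child = np.stack([g1, g2], axis=1)
        if scn.mut_rate > 0:
            flips = rng.random(child.shape) < scn.mut_rate
            child ^= flips
        haps = child
    # expansion: each individual from two random parents of the last generation
    dams = rng.integers(ne, size=scn.n_individuals)
    sires = rng.integers(ne, size=scn.n_individuals)
    g1 = _gametes(rng, haps, dams, chrom_slices)
    g2 = _gametes(rng, haps, sires, chrom_slices)
    calls = (g1 + g2).astype(np.float64)

    q = calls.sum(axis=0) / (2.0 * scn.n_individuals)
    n_mono = int(((q == 0) | (q == 1)).sum())
    if n_mono:
        logger.info("simulate_population: %d of %d loci monomorphic in the "
                    "final sample", n_mono, L)
    chrom = np.concatenate([
        np.full(scn.markers_per_chrom, str(c + 1), dtype=object)
        for c in range(scn.n_chrom)])
    pos = np.concatenate([np.arange(1, scn.markers_per_chrom + 1)
                          for _ in range(scn.n_chrom)])
    snp_ids = np.array([f"snp{c + 1}_{p}" for c, p in
                        zip(np.repeat(np.arange(scn.n_chrom), scn.markers_per_chrom),
                            pos)], dtype=object)
    return GenotypeMatrix(calls=calls, snp_ids=snp_ids, chrom=chrom, pos=pos,
                          individual_ids=np.array(
                              [f"ind{i}" for i in range(scn.n_individuals)],
                              dtype=object))


def sample_qtl(G: GenotypeMatrix, n_qtl: int,
               effect_dist: str = "gaussian",
               seed: int | np.random.Generator = 0) -> tuple[np.ndarray, np.ndarray]:
    """Pick causal loci uniformly among polymorphic markers and draw
    their additive effects.

    ``gamma_signed`` draws effect magnitudes from Gamma(shape=0.4,
    scale=1.66) with a random sign, giving a few large QTL; the default
    is standard normal.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q = G.compute_allele_freq()
    poly = np.where((q > 0) & (q < 1))[0]
    if n_qtl > len(poly):
        raise ValueError(f"n_qtl={n_qtl} exceeds {len(poly)} polymorphic loci")
    if n_qtl == 0:
        return np.array([], dtype=np.int64), np.array([])
    idx = np.sort(rng.choice(poly, size=n_qtl, replace=False))
    if effect_dist == "gaussian":
        eff = rng.standard_normal(n_qtl)
    elif effect_dist == "gamma_signed":
        eff = rng.gamma(0.4, 1.66, size=n_qtl) * rng.choice([-1.0, 1.0], size=n_qtl)
    else:
        raise ValueError(f"unknown effect_dist {effect_dist!r}")
    return idx, eff


def simulate_phenotypes(G: GenotypeMatrix, qtl_indices: np.ndarray,
                        qtl_effects: np.ndarray, h2: float,
                        seed: int | np.random.Generator = 0,
                        scenario: SimScenario | None = None) -> SimOutput:
    """True breeding values plus normal noise scaled to hit ``h2``.

    The residual variance is matched to the *empirical* variance of the
    true breeding values in this sample, so every replicate has the
    nominal heritability in expectation.
    """
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must lie in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    qtl_indices = np.asarray(qtl_indices, dtype=np.int64)
    qtl_effects = np.asarray(qtl_effects, dtype=np.float64)
    tbv = G.calls[:, qtl_indices] @ qtl_effects if len(qtl_indices) else \
        np.zeros(G.n_individuals)
    var_tbv = float(np.var(tbv))
    if var_tbv == 0.0:
        raise ValueError("true breeding values have zero variance; "
                         "cannot scale residual noise to the requested h2")
    sigma_e = np.sqrt(var_tbv * (1.0 - h2) / h2)
    phen = tbv + rng.normal(0.0, sigma_e, size=len(tbv))
    pt = PhenotypeTable(y_raw=phen, y_adj=phen.copy(), tbv=tbv, h2=h2,
                        individual_ids=G.individual_ids)
    return SimOutput(genotypes=G, qtl_indices=qtl_indices,
                     qtl_effects=qtl_effects, tbv=tbv, phenotypes=pt,
                     scenario=scenario)


def simulate_scenario(scn: SimScenario,
                      effect_dist: str = "gaussian") -> SimOutput:
    """Full pipeline: population, QTL and phenotypes from one seed."""
    rng = np.random.default_rng(scn.seed)
    G = simulate_population(scn, rng)
    idx, eff = sample_qtl(G, scn.n_qtl, effect_dist=effect_dist, seed=rng)
    return simulate_phenotypes(G, idx, eff, scn.h2, seed=rng, scenario=scn)


def write_sim_output(out: SimOutput, prefix: str) -> None:
    """Dump a simulation as the package's text dialects: a genotype
    table, a phenotype TSV and a truth TSV (qtl index, effect, tbv)."""
    import pandas as pd

    G = out.genotypes
    pd.DataFrame(G.calls.astype(np.int64), index=G.individual_ids,
                 columns=G.snp_ids).to_csv(f"{prefix}.geno.tsv", sep="\t")
    pd.DataFrame({"individual_id": G.individual_ids,
                  "phenotype": out.phenotypes.y_raw,
                  "tbv": out.tbv}).to_csv(f"{prefix}.pheno.tsv", sep="\t",
                                          index=False)
    pd.DataFrame({"qtl_index": out.qtl_indices,
                  "snp_id": G.snp_ids[out.qtl_indices],
                  "effect": out.qtl_effects}).to_csv(
        f"{prefix}.truth.tsv", sep="\t", index=False)


__all__ = ["SimScenario", "SimOutput", "SCENARIOS", "simulate_population",
           "sample_qtl", "simulate_phenotypes", "simulate_scenario",
           "write_sim_output"]
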