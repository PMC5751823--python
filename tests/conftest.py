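import numpy as np
import pytest

from tbmcmc.popsim import SimScenario, simulate_scenario


@pytest.fixture(scope="session")
def small_sim():
    """A small but realistic simulated population shared across tests:
    120 individuals x 150 markers, 15 QTL, h2 = 0.5."""
    scn = SimScenario(n_individuals=120, n_chrom=3, markers_per_chrom=50,
                      n_qtl=15, h2=0.5, seed=1234)
    return simulate_scenario(scn)


@pytest.fixture()
def ped_fixture(tmp_path):
    """Hand-constructed 2-individual, 2-SNP PLINK text fileset.

    SNP1 alleles (A A / G G), SNP2 (A G / A G): counting G (minor by the
    tie rule) gives calls [[0, 1], [2, 1]].
    """
    (tmp_path / "toy.map").write_text(
        "1 snp1 0 100\n1 snp2 0 200\n")
    (tmp_path / "toy.ped").write_text(
        "f1 ind1 0 0 1 -9 A A A G\n"
        "f1 ind2 0 0 2 -9 G G A G\n")
    return str(tmp_path / "toy")
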