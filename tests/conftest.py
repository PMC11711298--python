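"""Shared simulated fixtures (session-scoped; all data generated in-process)."""

import numpy as np
import pandas as pd
import pytest

import gwgp
from gwgp import simulate as sim


@pytest.fixture(scope="session")
def structured_panel():
    """200 accessions x 5000 SNPs, two subpopulations at F = 0.24."""
    cfg = gwgp.SimGenotypeConfig(
        n_accessions=200, n_snps=5000, n_chromosomes=5, fst_target=0.24, seed=1
    )
    geno, labels = sim.simulate_genotypes(cfg)
    return geno, labels, cfg


@pytest.fixture(scope="session")
def small_panel():
    """200 x 1000 panmictic panel for cheap model/GWAS tests."""
    cfg = gwgp.SimGenotypeConfig(
        n_accessions=200, n_snps=1000, n_chromosomes=4, fst_target=0.0, seed=2
    )
    geno, labels = sim.simulate_genotypes(cfg)
    return geno, labels


@pytest.fixture()
def toy_geno():
    """3 accessions x 2 SNPs with dosages ((0,2),(1,1),(2,0))."""
    return gwgp.GenotypeMatrix(
        dosages=np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]]),
        accession_ids=["a", "b", "c"],
        markers=pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "pos": [100, 200],
                "ref": ["A", "G"],
                "alt": ["C", "T"],
            }
        ),
    )


def make_trait(geno, labels, h2, n_qtl=50, n_env=4, gxe=0.15, seed=0, traits=("t",)):
    cfg = gwgp.SimPhenotypeConfig(
        traits=traits,
        n_qtl_per_trait=n_qtl,
        h2_target=h2,
        n_environments=n_env,
        gxe_var_fraction=gxe,
        seed=seed,
    )
    return sim.simulate_phenotypes(geno, labels, cfg)
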