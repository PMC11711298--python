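"""Multi-environment BLUP, descriptive statistics and SNP heritability."""

import numpy as np
import pandas as pd
import pytest

import gwgp
from gwgp import pheno_blup, simulate as sim

from conftest import make_trait


def test_noise_free_blups_recover_genetic_values(small_panel):
    # single group: with two groups the fixed group effect would absorb the
    # between-group share of g and cap the correlation just below 1
    geno, _ = small_panel
    labels = np.zeros(geno.n_accessions, dtype=int)
    trials, truth = make_trait(geno, labels, h2=1.0, gxe=0.0, seed=11)
    res = pheno_blup.fit_multienv_blup(trials)
    tb = res.per_trait["t"]
    g = truth.genetic_values["t"].loc[tb.genotype_blups.index]
    r = np.corrcoef(tb.genotype_blups.to_numpy(), g.to_numpy())[0, 1]
    assert r > 0.9999


def test_blup_permutation_equivariance(small_panel):
    geno, labels = small_panel
    trials, _ = make_trait(geno, labels, h2=0.5, seed=12)
    res1 = pheno_blup.fit_multienv_blup(trials)
    # random-effect BLUPs sum to ~0 at the scale of the effects
    b = res1.per_trait["t"].genotype_blups
    assert abs(b.sum()) < 1e-6 * max(1.0, np.abs(b).sum())
    # permute accession labels consistently
    ids = sorted(trials["accession"].unique())
    perm = {a: b for a, b in zip(ids, np.random.default_rng(0).permutation(ids))}
    trials2 = trials.assign(accession=trials["accession"].map(perm))
    res2 = pheno_blup.fit_multienv_blup(trials2)
    b1 = res1.per_trait["t"].genotype_blups
    b2 = res2.per_trait["t"].genotype_blups
    for a in ids:
        assert b2.loc[perm[a]] == pytest.approx(b1.loc[a], abs=1e-8)


def test_blup_beats_single_environment(small_panel):
    geno, labels = small_panel
    wins = 0
    for seed in range(10):
        trials, truth = make_trait(geno, labels, h2=0.6, seed=100 + seed)
        res = pheno_blup.fit_multienv_blup(trials)
        g = truth.genetic_values["t"]
        yc = res.per_trait["t"].y_c.loc[g.index].to_numpy()
        env1 = (
            trials[trials["environment"] == "env1"]
            .set_index("accession")["value"]
            .loc[g.index]
            .to_numpy()
        )
        wins += np.corrcoef(yc, g)[0, 1] > np.corrcoef(env1, g)[0, 1]
    assert wins >= 8  # shrinkage/averaging benefit on average


def test_blup_requires_two_environments(small_panel):
    geno, labels = small_panel
    trials, _ = make_trait(geno, labels, h2=0.5, n_env=1, seed=1)
    with pytest.raises(ValueError, match="environments"):
        pheno_blup.fit_multienv_blup(trials)


def test_gxe_variance_estimable_with_replicates():
    # small balanced replicated design with known components
    rng = np.random.default_rng(3)
    n_acc, n_env, n_rep = 40, 3, 3
    g = rng.normal(0, 1.0, n_acc)
    gxe = rng.normal(0, 0.7, (n_acc, n_env))
    rows = []
    for i in range(n_acc):
        for j in range(n_env):
            for r in range(n_rep):
                rows.append(
                    {
                        "accession": f"a{i}",
                        "environment": f"e{j}",
                        "group": "g1",
                        "trait": "t",
                        "value": 5.0 + g[i] + 0.3 * j + gxe[i, j]
                        + rng.normal(0, 0.5),
                    }
                )
    res = pheno_blup.fit_multienv_blup(pd.DataFrame(rows))
    tb = res.per_trait["t"]
    assert tb.gxe_estimable
    assert tb.sigma2_g == pytest.approx(1.0, abs=0.5)
    assert tb.sigma2_gxe == pytest.approx(0.49, abs=0.3)
    assert tb.sigma2_e == pytest.approx(0.25, abs=0.15)


def test_descriptive_stats_hand_values():
    trials = pd.DataFrame(
        {
            "accession": ["a", "b", "c", "d"],
            "environment": ["e1"] * 4,
            "group": ["g"] * 4,
            "trait": ["x", "x", "y", "y"],
            "value": [2.0, 4.0, 7.0, 7.0],
        }
    )
    st = pheno_blup.descriptive_stats(trials)
    assert st.loc["x", "mean"] == 3.0
    assert st.loc["x", "variance"] == pytest.approx(2.0)  # sample variance
    assert st.loc["x", "cv"] == pytest.approx(np.sqrt(2.0) / 3.0)
    assert st.loc["y", "cv"] == 0.0  # constant trait


def test_descriptive_cv_envelope_on_preset():
    geno, labels = sim.simulate_genotypes(sim.oat195_genotype_config(n_snps=2000, seed=5))
    trials, _ = sim.simulate_phenotypes(
        geno, labels, sim.oat195_phenotype_config(seed=5)
    )
    st = pheno_blup.descriptive_stats(trials)
    assert ((st["cv"] > 0.05) & (st["cv"] < 0.60)).all()


def _single_env_y(geno, labels, h2, seed, n_qtl=50):
    cfg = gwgp.SimPhenotypeConfig(
        traits=("t",), n_qtl_per_trait=n_qtl, h2_target=h2,
        n_environments=1, gxe_var_fraction=0.0, seed=seed,
    )
    trials, truth = sim.simulate_phenotypes(geno, labels, cfg)
    y = trials.set_index("accession")["value"].loc[geno.accession_ids].to_numpy()
    return y, truth


@pytest.fixture(scope="module")
def h2_panel():
    # local LD (as in real reduced-representation panels) concentrates the
    # kernel spectrum, which the REML likelihood needs to pin h2 down
    cfg = gwgp.SimGenotypeConfig(n_accessions=400, n_snps=5000, n_chromosomes=5,
                                 fst_target=0.0, ld_rho=0.5, seed=19)
    geno, labels = sim.simulate_genotypes(cfg)
    return geno, labels


def test_h2_noise_free_and_null_limits(h2_panel):
    geno, labels = h2_panel
    # dense polygenic architecture so the genome-wide kernel can represent
    # the genetic covariance in the noise-free limit
    y, truth = _single_env_y(geno, labels, h2=1.0, seed=21, n_qtl=500)
    est = pheno_blup.estimate_h2(y, geno)
    assert est.h2 > 0.9
    rng = np.random.default_rng(2)
    nulls = [
        pheno_blup.estimate_h2(rng.normal(size=geno.n_accessions), geno).h2
        for _ in range(20)
    ]
    assert np.mean(nulls) < 0.1


def test_h2_affine_invariance(small_panel):
    geno, labels = small_panel
    y, _ = _single_env_y(geno, labels, h2=0.5, seed=22)
    a = pheno_blup.estimate_h2(y, geno).h2
    b = pheno_blup.estimate_h2(3.7 * y - 11.0, geno).h2
    assert a == pytest.approx(b, abs=1e-6)


def test_h2_decreases_with_noise(small_panel):
    geno, labels = small_panel
    means = []
    for h2 in (0.8, 0.5, 0.2):  # increasing residual noise
        ests = []
        for s in range(6):
            y, _ = _single_env_y(geno, labels, h2=h2, seed=300 + s)
            ests.append(pheno_blup.estimate_h2(y, geno).h2)
        means.append(np.mean(ests))
    assert means[0] > means[1] > means[2]


def test_h2_weights_mark_thinned_snps():
    cfg = gwgp.SimGenotypeConfig(n_accessions=100, n_snps=500, n_chromosomes=2,
                                 chrom_length_bp=500_000, ld_rho=0.8, seed=6)
    geno, labels = sim.simulate_genotypes(cfg)
    y, _ = _single_env_y(geno, labels, h2=0.5, seed=7, n_qtl=20)
    est = pheno_blup.estimate_h2(y, geno, prune=(0.5, 50.0))
    assert est.n_snps_used < geno.n_snps  # high LD panel gets thinned
    assert set(np.unique(est.weights)) <= {0.0, 1.0}
    assert est.weights.sum() == est.n_snps_used
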