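"""Mixed-model association scan, thresholds, ranking and TAS counting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import gwgp
from gwgp import gwas as gw, popgen, simulate as sim


def test_bonferroni_threshold_values():
    assert gw.bonferroni_threshold(77_835, 0.05) == pytest.approx(6.4238e-7, rel=1e-4)
    assert gw.bonferroni_threshold(100, 0.01) == pytest.approx(1e-4)
    assert gw.bonferroni_threshold(1, 0.05) == 0.05
    with pytest.raises(ValueError):
        gw.bonferroni_threshold(0, 0.05)
    with pytest.raises(ValueError):
        gw.bonferroni_threshold(10, 1.5)


@pytest.fixture(scope="module")
def scan_panel():
    cfg = gwgp.SimGenotypeConfig(n_accessions=250, n_snps=2000, n_chromosomes=4,
                                 fst_target=0.1, seed=31)
    geno, labels = sim.simulate_genotypes(cfg)
    return geno, labels, popgen.compute_grm(geno)


def test_duplicate_snp_identical_rows(scan_panel):
    geno, labels, kin = scan_panel
    d = geno.dosages.copy()
    d[:, 1] = d[:, 0]
    dup = gwgp.GenotypeMatrix(d, list(geno.accession_ids), geno.markers.copy())
    rng = np.random.default_rng(0)
    y = d[:, 0] * 0.3 + rng.normal(size=geno.n_accessions)
    res = gw.mlm_scan(y, dup, kin)
    r0, r1 = res.table.iloc[0], res.table.iloc[1]
    for col in ("beta", "se", "wald", "p"):
        assert r0[col] == pytest.approx(r1[col], abs=1e-12)


def test_affine_invariance_of_pvalues(scan_panel):
    geno, labels, kin = scan_panel
    rng = np.random.default_rng(1)
    y = geno.dosages[:, 5] * 0.4 + rng.normal(size=geno.n_accessions)
    p1 = gw.mlm_scan(y, geno, kin).table["p"]
    p2 = gw.mlm_scan(2.5 * y + 7.0, geno, kin).table["p"]
    assert np.abs(p1 - p2).max() < 1e-8


def test_forced_large_delta_matches_ols(scan_panel):
    geno, labels, kin = scan_panel
    sub = geno.take_accessions(np.arange(200))
    poly = np.flatnonzero(sub.dosages.std(axis=0) > 0)[:200]
    sub = sub.take_snps(poly)
    kin_sub = popgen.compute_grm(sub)
    rng = np.random.default_rng(2)
    y = rng.normal(size=200)
    res = gw.mlm_scan(y, sub, kin_sub, n_pcs=2, delta_override=1e10)
    # direct OLS oracle with the same covariates
    scores, _ = popgen.pca(sub, n_components=2)
    X = np.column_stack([np.ones(200), scores])
    Q, _ = np.linalg.qr(X)
    y_r = y - Q @ (Q.T @ y)
    for j in (0, 17, 111):
        g = sub.dosages[:, j]
        g_r = g - Q @ (Q.T @ g)
        beta = g_r @ y_r / (g_r @ g_r)
        rss = y_r @ y_r - beta**2 * (g_r @ g_r)
        se = np.sqrt(rss / (200 - 4) / (g_r @ g_r))
        p = 2 * stats.norm.sf(abs(beta / se))
        assert res.table["p"].iloc[j] == pytest.approx(p, abs=1e-6)


def test_constant_snp_flagged(scan_panel):
    geno, labels, kin = scan_panel
    d = geno.dosages.copy()
    d[:, 3] = 1.0
    g2 = gwgp.GenotypeMatrix(d, list(geno.accession_ids), geno.markers.copy())
    y = np.random.default_rng(3).normal(size=geno.n_accessions)
    res = gw.mlm_scan(y, g2, kin)
    assert res.table["flag_constant"].iloc[3]
    assert res.table["p"].iloc[3] == 1.0


def _fake_result(pvals, markers, name):
    tab = pd.DataFrame(
        {
            "chrom": markers["chrom"],
            "pos": markers["pos"],
            "beta": 0.0,
            "se": 1.0,
            "wald": 0.0,
            "p": pvals,
            "flag_constant": False,
        }
    )
    return gw.GwasResult(
        table=tab, trait="t", phenotype_set=name, n_pcs=0, delta=1.0,
        threshold_5=gw.bonferroni_threshold(len(pvals), 0.05),
        threshold_1=gw.bonferroni_threshold(len(pvals), 0.01),
    )


def test_rank_markers_min_p_semantics():
    mk = pd.DataFrame({"chrom": ["chr1"] * 4, "pos": [10, 20, 30, 40]})
    rA = _fake_result([1e-9, 0.5, 0.9, 0.2], mk, "A")
    rB = _fake_result([0.8, 0.7, 1e-7, 0.3], mk, "B")
    order = gw.rank_markers([rA, rB], top_n=4)
    assert list(order[:2]) == [0, 2]  # the two set-specific best SNPs first
    assert sorted(order) == [0, 1, 2, 3]  # top_n = n is a permutation
    with pytest.raises(ValueError):
        gw.rank_markers([rA], top_n=5)


def test_count_tas_deduplication():
    mk = pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [10, 20, 30]})
    thr = gw.bonferroni_threshold(3, 0.05)
    rA = _fake_result([thr / 10, 0.5, 0.9], mk, "env1")
    rB = _fake_result([thr / 5, 0.5, thr / 2], mk, "env2")
    tas = gw.count_tas([rA, rB], alpha=0.05)
    assert len(tas) == 2
    first = tas[tas["pos"] == 10].iloc[0]
    assert first["multi_set"] and first["n_sets"] == 2
    assert not tas[tas["pos"] == 30].iloc[0]["multi_set"]
    # nothing significant -> empty
    rC = _fake_result([0.5, 0.6, 0.7], mk, "x")
    assert len(gw.count_tas([rC])) == 0


def test_null_tas_count_respects_bonferroni(scan_panel):
    geno, labels, kin = scan_panel
    rng = np.random.default_rng(4)
    total = 0
    for s in range(10):
        results = [
            gw.mlm_scan(rng.normal(size=geno.n_accessions), geno, kin,
                        phenotype_set=f"set{k}")
            for k in range(2)
        ]
        total += len(gw.count_tas(results))
    assert total <= 3  # expected ~= 10 * 2 * 0.05 = 1


def test_qtl_enrichment_in_top_ranked():
    # ranking operates on multi-environment BLUP phenotypes, as in the
    # pipeline's intended use
    from gwgp import pheno_blup

    enrich = []
    for s in range(5):
        cfg = gwgp.SimGenotypeConfig(n_accessions=400, n_snps=5000,
                                     n_chromosomes=5, fst_target=0.1,
                                     seed=600 + s)
        geno, labels = sim.simulate_genotypes(cfg)
        pcfg = gwgp.SimPhenotypeConfig(traits=("t",), n_qtl_per_trait=50,
                                       h2_target=0.6, seed=700 + s)
        trials, truth = sim.simulate_phenotypes(geno, labels, pcfg)
        blup = pheno_blup.fit_multienv_blup(trials)
        y = blup.per_trait["t"].y_c.loc[geno.accession_ids].to_numpy()
        kin = popgen.compute_grm(geno)
        res = gw.mlm_scan(y, geno, kin)
        top = gw.rank_markers([res], top_n=100)

        pos = geno.markers["pos"].to_numpy()
        chrom = geno.markers["chrom"].to_numpy()
        near = np.zeros(geno.n_snps, dtype=bool)
        for q in truth.qtl_indices["t"]:
            near |= (chrom == chrom[q]) & (np.abs(pos - pos[q]) <= 50_000)
        enrich.append(near[top].mean() / near.mean())
    assert np.mean(enrich) >= 5.0


def test_kinship_mismatch_rejected(scan_panel):
    geno, labels, kin = scan_panel
    y = np.zeros(geno.n_accessions)
    sub = geno.take_accessions(np.arange(100))
    with pytest.raises(ValueError):
        gw.mlm_scan(y[:100], sub, kin)
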