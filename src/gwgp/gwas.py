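"""Mixed-linear-model association scan and GWAS-based marker ranking.

The scan follows the P3D/EMMAX scheme: the variance ratio
delta = sigma2_e / sigma2_g of the null polygenic model
y ~ N(X beta, sigma2_g G + sigma2_e I) — X an intercept plus leading
principal components — is estimated once by spectral REML, the data are
whitened by (D + delta I)^(-1/2) U' with G = U D U', and each marker is
tested by generalized least squares with a two-sided Wald test.

Per-marker rankings across phenotype sets (environments and the BLUP set)
aggregate by minimum p-value; genome-wide significance uses the Bonferroni
threshold alpha / n_snps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._reml import reml_single_kernel
from .popgen import KinshipMatrix
from .variants_io import GenotypeMatrix

__all__ = [
    "GwasResult",
    "mlm_scan",
    "bonferroni_threshold",
    "rank_markers",
    "count_tas",
]


@dataclass
class GwasResult:
    """Per-SNP association results for one trait / phenotype set."""

    table: pd.DataFrame  # chrom, pos, beta, se, wald, p, flag_constant
    trait: str
    phenotype_set: str
    n_pcs: int
    delta: float
    threshold_5: float
    threshold_1: float

    @property
    def n_snps(self) -> int:
        return len(self.table)


def bonferroni_threshold(n_snps: int, alpha: float = 0.05) -> float:
    """Family-wise threshold alpha / n_snps."""
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / n_snps


def mlm_scan(
    y_c: np.ndarray | pd.Series,
    geno: GenotypeMatrix,
    kinship: KinshipMatrix,
    n_pcs: int = 3,
    trait: str = "trait",
    phenotype_set: str = "BLUP",
    delta_override: float | None = None,
) -> GwasResult:
    """P3D mixed-model scan of every SNP against a corrected phenotype.

    Constant dosage columns are reported with p = 1 and flagged rather than
    dropped, so row indices align with the marker table. ``delta_override``
    fixes the variance ratio instead of estimating it (a very large value
    collapses the scan to ordinary least squares with PC covariates).
    """
    y = np.asarray(y_c, dtype=float).ravel()
    n = geno.n_accessions
    if len(y) != n:
        raise ValueError("y_c must hold one value per accession")
    if kinship.values.shape != (n, n):
        raise ValueError("kinship dimension does not match the panel")
    if list(kinship.accession_ids) != list(geno.accession_ids):
        raise ValueError("kinship accession ids do not match the genotypes")
    d = geno.dosages
    if np.isnan(d).any():
        raise ValueError("genotypes must be imputed before mlm_scan")

    evals, evecs = np.linalg.eigh((kinship.values + kinship.values.T) / 2.0)

    X = np.ones((n, 1))
    if n_pcs > 0:
        # PC scores are the kinship eigenvectors scaled by sqrt(eigenvalue),
        # identical to popgen.pca on the same panel
        order = np.argsort(evals)[::-1][:n_pcs]
        scores = evecs[:, order] * np.sqrt(np.clip(evals[order], 0.0, None))
        X = np.hstack([X, scores])
    q = X.shape[1]

    if delta_override is None:
        null = reml_single_kernel(y, X, kinship.values)
        delta = null.delta
    else:
        delta = float(delta_override)
    w = 1.0 / np.sqrt(np.clip(evals, 0.0, None) + delta)
    # whitening: Var(T y) = sigma2_g I with T = diag(w) U'
    Ty = (evecs.T @ y) * w
    TX = (evecs.T @ X) * w[:, None]
    TG = (evecs.T @ d) * w[:, None]

    # residualize markers and phenotype against whitened covariates
    Q, _ = np.linalg.qr(TX)
    y_r = Ty - Q @ (Q.T @ Ty)
    G_r = TG - Q @ (Q.T @ TG)

    gtg = np.einsum("ij,ij->j", G_r, G_r)
    constant = gtg <= 1e-12 * n
    gtg_safe = np.where(constant, 1.0, gtg)
    beta = (G_r.T @ y_r) / gtg_safe
    rss = float(y_r @ y_r) - beta**2 * gtg_safe
    dof = n - q - 1
    sigma2 = np.clip(rss, 0.0, None) / dof
    se = np.sqrt(sigma2 / gtg_safe)
    with np.errstate(invalid="ignore", divide="ignore"):
        wald = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(wald))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    beta = np.where(constant, 0.0, beta)
    se = np.where(constant, np.nan, se)
    wald = np.where(constant, 0.0, wald)
    p = np.where(constant, 1.0, p)

    table = pd.DataFrame(
        {
            "chrom": geno.markers["chrom"].to_numpy(),
            "pos": geno.markers["pos"].to_numpy(),
            "beta": beta,
            "se": se,
            "wald": wald,
            "p": p,
            "flag_constant": constant,
        }
    )
    return GwasResult(
        table=table,
        trait=trait,
        phenotype_set=phenotype_set,
        n_pcs=n_pcs,
        delta=float(delta),
        threshold_5=bonferroni_threshold(geno.n_snps, 0.05),
        threshold_1=bonferroni_threshold(geno.n_snps, 0.01),
    )


def _check_same_panel(results: list[GwasResult]) -> pd.DataFrame:
    if not results:
        raise ValueError("no GWAS results supplied")
    ref = results[0].table[["chrom", "pos"]]
    for r in results[1:]:
        if not ref.equals(r.table[["chrom", "pos"]]):
            raise ValueError("GWAS results do not share the same marker panel")
    return ref


def rank_markers(results: list[GwasResult], top_n: int) -> np.ndarray:
    """Top markers by minimum p-value across phenotype sets.

    Ties break by (chrom, pos); the returned indices are positions in the
    shared marker table, best first.
    """
    ref = _check_same_panel(results)
    m = len(ref)
    if top_n > m:
        raise ValueError(f"top_n={top_n} exceeds marker count {m}")
    min_p = np.min(np.column_stack([r.table["p"].to_numpy() for r in results]), axis=1)
    order = pd.DataFrame(
        {"p": min_p, "chrom": ref["chrom"], "pos": ref["pos"]}
    ).sort_values(["p", "chrom", "pos"], kind="stable")
    return order.index.to_numpy()[:top_n]


def count_tas(results: list[GwasResult], alpha: float = 0.05) -> pd.DataFrame:
    """Trait-associated SNPs at the per-set Bonferroni threshold.

    One row per unique significant (chrom, pos), with the sets it was
    significant in and a multi-set flag (supports 'significant in at least
    two environments' style reporting).
    """
    ref = _check_same_panel(results)
    hits: dict[tuple, list[str]] = {}
    for r in results:
        thr = bonferroni_threshold(r.n_snps, alpha)
        sig = r.table["p"].to_numpy() < thr
        for i in np.flatnonzero(sig):
            key = (ref["chrom"].iloc[i], int(ref["pos"].iloc[i]))
            hits.setdefault(key, []).append(r.phenotype_set)
    rows = [
        {
            "chrom": c,
            "pos": p,
            "sets": sorted(set(sets)),
            "n_sets": len(set(sets)),
            "multi_set": len(set(sets)) > 1,
        }
        for (c, p), sets in sorted(hits.items())
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "sets", "n_sets", "multi_set"]
    )
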