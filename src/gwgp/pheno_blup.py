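"""Multi-environment phenotype BLUP and SNP heritability.

The trial model is

    y_ijk = mu + G_i + beta_j + alpha_k + (G x beta)_ij + e_ijk

with genotype effects G_i (and, when replicated data allow it, the G×E
deviations) random, and environment and group effects fixed. Variance
components come from REML; corrected phenotypes y_c = mu + G_i feed the
association scan and the prediction benchmark.

SNP heritability follows an LD-thinned, frequency-weighted GRM: markers are
thinned at r^2 <= 0.98 within 100 kb, each retained SNP's centered dosage is
weighted so its variance contribution scales as [2 p (1-p)]^alpha with
alpha = 0.75 (down-weighting common variants relative to the unweighted
GRM), leading principal components are regressed out as ancestry
covariates, and a single-component spectral REML gives
h2 = sigma2_g / (sigma2_g + sigma2_e).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._reml import em_reml_mme, reml_single_kernel
from .popgen import ld_prune, pca
from .variants_io import GenotypeMatrix

__all__ = [
    "TraitBlup",
    "BlupResult",
    "H2Estimate",
    "fit_multienv_blup",
    "descriptive_stats",
    "estimate_h2",
]


@dataclass
class TraitBlup:
    trait: str
    grand_mean: float
    env_effects: dict[str, float]
    group_effects: dict[str, float]
    genotype_blups: pd.Series  # indexed by accession
    accession_groups: pd.Series  # group label per accession
    sigma2_g: float
    sigma2_gxe: float
    sigma2_e: float
    gxe_estimable: bool
    n_iter: int

    @property
    def y_c(self) -> pd.Series:
        """Corrected phenotype mu + alpha_k + G_i.

        The fixed group estimate alpha_k absorbs the between-group share of
        the genetic signal (the model cannot split it from G_i), so it is
        added back: dropping it would strip marker-predictable variance
        from the prediction target. Use :attr:`y_c_within_group` for the
        group-centered variant.
        """
        if not self.group_effects:
            return self.grand_mean + self.genotype_blups
        alpha = self.accession_groups.map(self.group_effects).astype(float)
        return self.grand_mean + self.genotype_blups + alpha

    @property
    def y_c_within_group(self) -> pd.Series:
        """Group-centered corrected phenotype mu + G_i."""
        return self.grand_mean + self.genotype_blups


@dataclass
class BlupResult:
    per_trait: dict[str, TraitBlup] = field(default_factory=dict)

    @property
    def yc(self) -> pd.DataFrame:
        """Accession x trait table of corrected phenotypes."""
        return pd.DataFrame({t: b.y_c for t, b in self.per_trait.items()})

    def varcomp(self) -> pd.DataFrame:
        rows = [
            {
                "trait": t,
                "sigma2_g": b.sigma2_g,
                "sigma2_gxe": b.sigma2_gxe,
                "sigma2_e": b.sigma2_e,
                "gxe_estimable": b.gxe_estimable,
            }
            for t, b in self.per_trait.items()
        ]
        return pd.DataFrame(rows)


REQUIRED_COLS = {"accession", "environment", "trait", "value"}


def _design(sub: pd.DataFrame):
    accs = sorted(sub["accession"].unique())
    envs = sorted(sub["environment"].unique())
    groups = sorted(sub["group"].unique()) if "group" in sub else []
    acc_ix = {a: i for i, a in enumerate(accs)}
    env_ix = {e: i for i, e in enumerate(envs)}
    n = len(sub)

    X_cols = [np.ones(n)]
    names = ["intercept"]
    for e in envs[1:]:
        X_cols.append((sub["environment"] == e).to_numpy(float))
        names.append(f"env:{e}")
    if len(groups) > 1:
        for g in groups[1:]:
            X_cols.append((sub["group"] == g).to_numpy(float))
            names.append(f"group:{g}")
    X = np.column_stack(X_cols)

    Zg = np.zeros((n, len(accs)))
    Zg[np.arange(n), sub["accession"].map(acc_ix).to_numpy()] = 1.0
    cell = sub["accession"].map(acc_ix).to_numpy() * len(envs) + sub[
        "environment"
    ].map(env_ix).to_numpy()
    return accs, envs, groups, X, names, Zg, cell


def fit_multienv_blup(trials: pd.DataFrame, max_iter: int = 500) -> BlupResult:
    """REML fit of the multi-environment model, one trait at a time.

    Genotype effects (and G×E deviations when the data carry within-cell
    replicates) are random; environment and group are fixed. With a single
    record per accession x environment the G×E variance is confounded with
    the residual and is absorbed into it (``gxe_estimable=False``).
    """
    missing = REQUIRED_COLS - set(trials.columns)
    if missing:
        raise ValueError(f"trial table lacks columns: {sorted(missing)}")
    result = BlupResult()
    for trait, sub in trials.groupby("trait", sort=False):
        sub = sub.reset_index(drop=True)
        if sub["environment"].nunique() < 2:
            raise ValueError(
                f"trait {trait}: >=2 environments required for the "
                "multi-environment model"
            )
        accs, envs, groups, X, names, Zg, cell = _design(sub)
        replicated = (
            sub.groupby(["accession", "environment"]).size().max() > 1
        )
        Z_list = [Zg]
        if replicated:
            Zge = np.zeros((len(sub), len(accs) * len(envs)))
            Zge[np.arange(len(sub)), cell] = 1.0
            Z_list.append(Zge)

        fit = em_reml_mme(
            sub["value"].to_numpy(float), X, Z_list, max_iter=max_iter
        )
        if not fit["converged"] and fit["n_iter"] >= max_iter:
            raise RuntimeError(
                f"trait {trait}: REML did not converge in {max_iter} EM "
                f"iterations (last loglik {fit['loglik']:.6g})"
            )
        beta = dict(zip(names, fit["beta"]))
        env_eff = {envs[0]: 0.0}
        env_eff.update({e: float(beta[f"env:{e}"]) for e in envs[1:]})
        grp_eff = {}
        if len(groups) > 1:
            grp_eff = {groups[0]: 0.0}
            grp_eff.update({g: float(beta[f"group:{g}"]) for g in groups[1:]})
        elif groups:
            grp_eff = {groups[0]: 0.0}
        # grand mean: intercept plus the average environment effect
        grand_mean = float(beta["intercept"] + np.mean(list(env_eff.values())))

        acc_groups = (
            sub.drop_duplicates("accession")
            .set_index("accession")["group"]
            .reindex(accs)
            if "group" in sub
            else pd.Series(groups[0] if groups else "all", index=accs)
        )
        result.per_trait[trait] = TraitBlup(
            trait=trait,
            grand_mean=grand_mean,
            env_effects=env_eff,
            group_effects=grp_eff,
            accession_groups=acc_groups,
            genotype_blups=pd.Series(fit["u"][0], index=accs, name=trait),
            sigma2_g=float(fit["sigma2"][0]),
            sigma2_gxe=float(fit["sigma2"][1]) if replicated else 0.0,
            sigma2_e=float(fit["sigma2_e"]),
            gxe_estimable=bool(replicated),
            n_iter=fit["n_iter"],
        )
    return result


def descriptive_stats(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-trait mean, max, min, sample variance and coefficient of
    variation (cv = sd/mean as a fraction; NaN when the mean is 0)."""
    rows = []
    for trait, sub in trials.groupby("trait", sort=False):
        v = sub["value"].to_numpy(float)
        if len(v) < 2:
            raise ValueError(f"trait {trait}: need >=2 observations")
        mean = v.mean()
        var = v.var(ddof=1)
        cv = np.sqrt(var) / mean if mean != 0 else np.nan
        rows.append(
            {
                "trait": trait,
                "mean": mean,
                "max": v.max(),
                "min": v.min(),
                "variance": var,
                "cv": cv,
            }
        )
    return pd.DataFrame(rows).set_index("trait")


@dataclass
class H2Estimate:
    h2: float
    sigma2_g: float
    sigma2_e: float
    n_snps_used: int
    weights: np.ndarray  # per-SNP 0/1 thinning indicator
    alpha_power: float
    at_boundary: bool


def _weighted_grm(
    d: np.ndarray, alpha_power: float
) -> np.ndarray:
    """GRM whose SNP-j contribution scales as [2 p_j (1-p_j)]^alpha."""
    p = d.mean(axis=0) / 2.0
    het = 2.0 * p * (1.0 - p)
    if (het <= 0).any():
        raise ValueError("monomorphic SNPs in the thinned set; filter first")
    W = (d - 2.0 * p[None, :]) * het[None, :] ** ((alpha_power - 1.0) / 2.0)
    return (W @ W.T) / float(np.sum(het**alpha_power))


def estimate_h2(
    y_c: np.ndarray | pd.Series,
    geno: GenotypeMatrix,
    alpha_power: float = 0.75,
    prune: tuple[float, float] = (0.98, 100.0),
    n_pcs: int = 4,
) -> H2Estimate:
    """SNP heritability on a thinned, frequency-weighted GRM.

    Thins markers (r2 <= prune[0] within prune[1] kb), builds the weighted
    GRM, regresses out an intercept plus the first ``n_pcs`` principal
    components, and maximizes the single-component restricted likelihood
    over delta = sigma2_e/sigma2_g on log delta in [-10, 10].
    """
    y = np.asarray(y_c, dtype=float).ravel()
    if len(y) != geno.n_accessions:
        raise ValueError("y_c must hold one value per accession")
    if np.isnan(geno.dosages).any():
        raise ValueError("genotypes must be imputed before estimate_h2")

    keep = ld_prune(geno, r2_max=prune[0], window_kb=prune[1])
    weights = np.zeros(geno.n_snps)
    weights[keep] = 1.0
    thinned = geno.take_snps(keep, note=f"estimate_h2 thinning ({len(keep)} kept)")

    K = _weighted_grm(thinned.dosages, alpha_power)
    eigtol = -1e-8 * max(1.0, np.trace(K))
    if np.linalg.eigvalsh(K).min() < eigtol:
        raise ValueError("weighted GRM is not PSD within tolerance")

    X = np.ones((len(y), 1))
    if n_pcs > 0:
        scores, _ = pca(thinned, n_components=n_pcs)
        X = np.hstack([X, scores])

    fit = reml_single_kernel(y, X, K)
    return H2Estimate(
        h2=float(fit.h2),
        sigma2_g=float(fit.sigma2_g),
        sigma2_e=float(fit.sigma2_e),
        n_snps_used=len(keep),
        weights=weights,
        alpha_power=alpha_power,
        at_boundary=fit.at_boundary,
    )
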