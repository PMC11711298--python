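"""Synthetic structured panels with known ground truth.

Genotypes follow the Balding–Nichols model: each SNP has an ancestral
frequency p drawn uniformly on [maf_floor, 1 - maf_floor], each subpopulation
draws its own frequency from Beta(p(1-F)/F, (1-p)(1-F)/F) — whose expected
Weir–Cockerham differentiation is exactly F — and diploid dosages are
binomial draws within subpopulation. Local linkage disequilibrium is induced
by previous-marker copying: with probability ld_rho an accession's dosage at
SNP j is copied from its dosage at SNP j-1 on the same chromosome.

Phenotypes follow an additive multi-environment model: a small set of QTL
SNPs receives normal effects; the genetic value is rescaled so that, per
observation, Var(g) / (Var(g) + sigma2_gxe + sigma2_e) equals the target
narrow-sense heritability; environment and subpopulation-group main effects
plus per-accession-per-environment G×E deviations and residuals complete the
record. One record is emitted per accession x environment x trait.

The simulators are the test bed for every downstream stage: recovery of the
divergence parameter by the Fst estimator, of heritability by REML, of QTL
positions by the association scan, and of prediction accuracy orderings by
the cross-validation engine.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variants_io import GenotypeMatrix, read_vcf

__all__ = [
    "SimGenotypeConfig",
    "SimPhenotypeConfig",
    "TruthRecord",
    "simulate_genotypes",
    "simulate_phenotypes",
    "write_fixture",
    "oat195_genotype_config",
    "oat195_phenotype_config",
]

TRAITS_OAT = ["PH", "CL", "FLL", "FLW", "SPP", "SD", "TN"]


@dataclass(frozen=True)
class SimGenotypeConfig:
    """Parameters of the structured-panel genotype simulator."""

    n_accessions: int = 200
    n_snps: int = 5000
    n_chromosomes: int = 5
    chrom_length_bp: int = 30_000_000
    n_subpops: int = 2
    subpop_proportions: tuple[float, ...] | None = None
    fst_target: float = 0.0
    maf_floor: float = 0.05
    ld_rho: float = 0.0
    inbreeding: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def proportions(self) -> np.ndarray:
        if self.subpop_proportions is None:
            return np.full(self.n_subpops, 1.0 / self.n_subpops)
        p = np.asarray(self.subpop_proportions, dtype=float)
        if len(p) != self.n_subpops:
            raise ValueError("subpop_proportions length must equal n_subpops")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("subpop_proportions must sum to 1 within 1e-12")
        return p

    def __post_init__(self) -> None:
        if not 0.0 <= self.fst_target < 1.0:
            raise ValueError("fst_target must lie in [0, 1)")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must lie in [0, 1)")
        if not 0.0 < self.maf_floor < 0.5:
            raise ValueError("maf_floor must lie in (0, 0.5)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.inbreeding <= 1.0:
            raise ValueError("inbreeding must lie in [0, 1]")
        if self.n_snps < self.n_chromosomes:
            raise ValueError("n_snps must be >= n_chromosomes")
        self.proportions()


@dataclass(frozen=True)
class SimPhenotypeConfig:
    """Parameters of the multi-environment phenotype simulator."""

    traits: tuple[str, ...] = ("trait1",)
    n_qtl_per_trait: int = 50
    h2_target: float | tuple[float, ...] = 0.6
    n_environments: int = 4
    env_effect_sd: float = 0.5
    gxe_var_fraction: float = 0.15
    group_effect_sd: float = 0.3
    seed: int = 0

    def h2_for(self, t: int) -> float:
        if isinstance(self.h2_target, (tuple, list)):
            return float(self.h2_target[t])
        return float(self.h2_target)

    def __post_init__(self) -> None:
        h2s = (
            list(self.h2_target)
            if isinstance(self.h2_target, (tuple, list))
            else [self.h2_target]
        )
        for h2 in h2s:
            if not 0.0 < h2 <= 1.0:
                raise ValueError("h2_target must lie in (0, 1]")
            if h2 == 1.0 and self.gxe_var_fraction > 0:
                raise ValueError(
                    "h2_target=1 with gxe_var_fraction>0 is inconsistent"
                )
            if 1.0 - h2 * (1.0 + self.gxe_var_fraction) < -1e-12:
                raise ValueError(
                    "h2_target*(1+gxe_var_fraction) exceeds 1: residual "
                    "variance would be negative"
                )
        if not 0.0 <= self.gxe_var_fraction < 1.0:
            raise ValueError("gxe_var_fraction must lie in [0, 1)")
        if self.n_environments < 1:
            raise ValueError("n_environments must be >= 1")


@dataclass
class TruthRecord:
    """Ground truth of one simulated phenotype set."""

    qtl_indices: dict[str, np.ndarray]
    qtl_effects: dict[str, np.ndarray]
    genetic_values: pd.DataFrame  # accessions x traits
    realized_h2: dict[str, float]
    subpop_labels: np.ndarray
    variance_components: dict[str, dict[str, float]] = field(default_factory=dict)


def _positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """n strictly increasing 1-based positions on a chromosome."""
    if n > length:
        raise ValueError("more SNPs than base pairs on a chromosome")
    pos = rng.choice(length, size=n, replace=False) + 1
    pos.sort()
    return pos


def simulate_genotypes(
    config: SimGenotypeConfig,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Draw a Balding–Nichols panel; returns (genotypes, subpop labels).

    Deterministic given ``config.seed``. With ``fst_target == 0`` the Beta
    draw is bypassed and every subpopulation shares the ancestral frequency.
    """
    rng = np.random.default_rng(config.seed)
    props = config.proportions()
    n = config.n_accessions
    m = config.n_snps

    counts = np.floor(props * n).astype(int)
    counts[-1] = n - counts[:-1].sum()
    if (counts < 1).any():
        raise ValueError("every subpopulation needs at least one accession")
    labels = np.repeat(np.arange(config.n_subpops), counts)

    # marker map: SNPs split as evenly as possible across chromosomes
    per_chrom = np.full(config.n_chromosomes, m // config.n_chromosomes)
    per_chrom[: m % config.n_chromosomes] += 1
    chroms: list[str] = []
    positions: list[int] = []
    chrom_of = np.empty(m, dtype=int)
    j0 = 0
    for c, mc in enumerate(per_chrom):
        pos = _positions(rng, int(mc), config.chrom_length_bp)
        chroms.extend([f"chr{c + 1}"] * int(mc))
        positions.extend(pos.tolist())
        chrom_of[j0 : j0 + int(mc)] = c
        j0 += int(mc)

    p_anc = rng.uniform(config.maf_floor, 1.0 - config.maf_floor, size=m)
    F = config.fst_target
    if F == 0.0:
        subpop_freqs = np.tile(p_anc, (config.n_subpops, 1))
    else:
        a = p_anc * (1.0 - F) / F
        b = (1.0 - p_anc) * (1.0 - F) / F
        subpop_freqs = rng.beta(a[None, :], b[None, :], size=(config.n_subpops, m))

    freq_per_acc = subpop_freqs[labels, :]  # n x m
    # diploid dosages via two latent uniforms per call; local LD is induced
    # by an accession re-using its previous SNP's uniforms with probability
    # ld_rho (rank-preserving copying: the per-SNP marginal stays exactly
    # Binomial(2, p_subpop), so realized Fst is not distorted by LD)
    U = rng.random((2, n, m))
    if config.ld_rho > 0.0:
        copy = rng.random((n, m)) < config.ld_rho
        new_chrom = np.empty(m, dtype=bool)
        new_chrom[0] = True
        new_chrom[1:] = chrom_of[1:] != chrom_of[:-1]
        copy[:, new_chrom] = False
        for j in range(1, m):
            cj = copy[:, j]
            if cj.any():
                U[0, cj, j] = U[0, cj, j - 1]
                U[1, cj, j] = U[1, cj, j - 1]
    dosages = (
        (U[0] < freq_per_acc).astype(float) + (U[1] < freq_per_acc)
    )
    if config.inbreeding > 0.0:
        # selfing crops: with probability `inbreeding` a call is
        # autozygous (both alleles determined by one uniform), which
        # reduces heterozygosity by the factor (1 - F_IS) while leaving
        # allele frequencies untouched
        autozygous = rng.random((n, m)) < config.inbreeding
        dosages = np.where(
            autozygous, 2.0 * (U[0] < freq_per_acc), dosages
        )

    # resample monomorphic columns (possible when the Beta draw pushes a
    # frequency to an extreme); a handful of redraw rounds almost always
    # suffices at maf_floor >= 0.05 and n >= 100
    for _ in range(20):
        mono = np.flatnonzero(np.all(dosages == dosages[0, :], axis=0))
        if mono.size == 0:
            break
        p_re = rng.uniform(config.maf_floor, 1.0 - config.maf_floor, size=mono.size)
        if F == 0.0:
            freqs_re = np.tile(p_re, (config.n_subpops, 1))
        else:
            freqs_re = rng.beta(
                p_re[None, :] * (1.0 - F) / F,
                (1.0 - p_re[None, :]) * (1.0 - F) / F,
                size=(config.n_subpops, mono.size),
            )
        U_re = rng.random((2, n, mono.size))
        f_re = freqs_re[labels, :]
        d_re = (U_re[0] < f_re).astype(float) + (U_re[1] < f_re)
        if config.inbreeding > 0.0:
            az = rng.random((n, mono.size)) < config.inbreeding
            d_re = np.where(az, 2.0 * (U_re[0] < f_re), d_re)
        dosages[:, mono] = d_re

    if config.missing_rate > 0.0:
        miss = rng.random((n, m)) < config.missing_rate
        dosages[miss] = np.nan

    ref = rng.choice(list("ACGT"), size=m)
    alt = np.array(
        [rng.choice([b for b in "ACGT" if b != r]) for r in ref]
    )
    markers = pd.DataFrame(
        {"chrom": chroms, "pos": positions, "ref": ref, "alt": alt}
    )
    geno = GenotypeMatrix(
        dosages=dosages,
        accession_ids=[f"acc{i:04d}" for i in range(n)],
        markers=markers,
        provenance=[
            "simulate_genotypes: Balding-Nichols "
            f"F={F} n={n} m={m} subpops={counts.tolist()} "
            f"ld_rho={config.ld_rho} seed={config.seed}"
        ],
    )
    return geno, labels


def _mean_filled(d: np.ndarray) -> np.ndarray:
    if not np.isnan(d).any():
        return d
    col = np.nanmean(d, axis=0)
    return np.where(np.isnan(d), col[None, :], d)


def simulate_phenotypes(
    geno: GenotypeMatrix,
    labels: np.ndarray,
    config: SimPhenotypeConfig,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Additive QTL phenotypes in a multi-environment trial layout.

    Returns a long-format trial table (accession, environment, group, trait,
    value) with one record per accession x environment per trait, and the
    ground-truth record (QTL sets, effects, genetic values, realized h2).
    """
    if config.n_qtl_per_trait > geno.n_snps:
        raise ValueError("n_qtl_per_trait exceeds the number of SNPs")
    rng = np.random.default_rng(config.seed)
    d = _mean_filled(geno.dosages)
    centered = d - d.mean(axis=0, keepdims=True)
    n, m = d.shape
    J = config.n_environments
    envs = [f"env{j + 1}" for j in range(J)]
    groups = np.asarray([f"group{int(k) + 1}" for k in labels])

    qtl_idx: dict[str, np.ndarray] = {}
    qtl_eff: dict[str, np.ndarray] = {}
    gvals = np.zeros((n, len(config.traits)))
    realized: dict[str, float] = {}
    varcomp: dict[str, dict[str, float]] = {}
    records: list[pd.DataFrame] = []

    for t, trait in enumerate(config.traits):
        h2 = config.h2_for(t)
        idx = rng.choice(m, size=config.n_qtl_per_trait, replace=False)
        idx.sort()
        eff = rng.normal(0.0, 1.0, size=config.n_qtl_per_trait)
        g_raw = centered[:, idx] @ eff
        vg = g_raw.var()
        if vg <= 0:
            raise ValueError("degenerate genetic values (all-monomorphic QTL set)")
        # scale so per-observation h2 = Var(g)/(Var(g)+s2_gxe+s2_e) = target
        g = g_raw * np.sqrt(h2 / vg)
        s2_g = h2
        s2_gxe = config.gxe_var_fraction * h2
        s2_e = max(1.0 - s2_g - s2_gxe, 0.0)

        mu = rng.uniform(3.0, 10.0)
        beta_env = rng.normal(0.0, config.env_effect_sd, size=J)
        n_groups = int(np.max(labels)) + 1
        alpha_grp = rng.normal(0.0, config.group_effect_sd, size=n_groups)
        gxe = (
            rng.normal(0.0, np.sqrt(s2_gxe), size=(n, J)) if s2_gxe > 0 else np.zeros((n, J))
        )
        e = rng.normal(0.0, np.sqrt(s2_e), size=(n, J)) if s2_e > 0 else np.zeros((n, J))

        y = (
            mu
            + g[:, None]
            + beta_env[None, :]
            + alpha_grp[labels][:, None]
            + gxe
            + e
        )
        noise_var = gxe.var() + e.var()
        realized[trait] = float(g.var() / (g.var() + noise_var)) if (
            g.var() + noise_var
        ) > 0 else 1.0
        qtl_idx[trait] = idx
        qtl_eff[trait] = eff * np.sqrt(h2 / vg)
        gvals[:, t] = g
        varcomp[trait] = {
            "mu": float(mu),
            "sigma2_g": float(s2_g),
            "sigma2_gxe": float(s2_gxe),
            "sigma2_e": float(s2_e),
        }
        records.append(
            pd.DataFrame(
                {
                    "accession": np.repeat(geno.accession_ids, J),
                    "environment": np.tile(envs, n),
                    "group": np.repeat(groups, J),
                    "trait": trait,
                    "value": y.ravel(),
                }
            )
        )

    trials = pd.concat(records, ignore_index=True)
    truth = TruthRecord(
        qtl_indices=qtl_idx,
        qtl_effects=qtl_eff,
        genetic_values=pd.DataFrame(
            gvals, index=geno.accession_ids, columns=list(config.traits)
        ),
        realized_h2=realized,
        subpop_labels=np.asarray(labels),
        variance_components=varcomp,
    )
    return trials, truth


_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_fixture(
    geno: GenotypeMatrix,
    trials: pd.DataFrame | None,
    out_dir: str,
    overwrite: bool = False,
) -> dict[str, str]:
    """Write a minimal VCF 4.2 (+ phenotype CSV) fixture to ``out_dir``.

    Heterozygous dosage 1 is written as 0/1, missing as ./.. The VCF
    round-trips losslessly through :func:`gwgp.variants_io.read_vcf`.
    """
    os.makedirs(out_dir, exist_ok=True)
    vcf_path = os.path.join(out_dir, "genotypes.vcf")
    csv_path = os.path.join(out_dir, "phenotypes.csv")
    for p in (vcf_path, csv_path if trials is not None else vcf_path):
        if os.path.exists(p) and not overwrite:
            raise FileExistsError(f"{p} exists; pass overwrite=True to replace")

    mk = geno.markers
    contigs = list(dict.fromkeys(mk["chrom"]))
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in contigs:
            length = int(mk.loc[mk["chrom"] == c, "pos"].max())
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.accession_ids)
            + "\n"
        )
        for j in range(geno.n_snps):
            row = mk.iloc[j]
            calls = [
                "./." if np.isnan(v) else _GT[float(v)]
                for v in geno.dosages[:, j]
            ]
            fh.write(
                f"{row.chrom}\t{int(row.pos)}\t.\t{row.ref}\t{row.alt}"
                "\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )

    out = {"vcf": vcf_path}
    if trials is not None:
        trials.to_csv(csv_path, index=False)
        out["phenotypes"] = csv_path
    return out


def read_fixture(dir_or_vcf: str) -> GenotypeMatrix:
    """Convenience loader for fixtures written by :func:`write_fixture`."""
    path = dir_or_vcf
    if os.path.isdir(path):
        path = os.path.join(path, "genotypes.vcf")
    return read_vcf(path)


def oat195_genotype_config(
    n_snps: int = 20_000, missing_rate: float = 0.02, seed: int = 0
) -> SimGenotypeConfig:
    """Default emulation preset: 195 accessions in two groups of 75/120 on
    21 chromosomes at divergence F = 0.24, moderate local LD, and the high
    homozygosity of a selfing cereal (so panels pass a <20% per-SNP
    heterozygosity QC filter)."""
    return SimGenotypeConfig(
        n_accessions=195,
        n_snps=n_snps,
        n_chromosomes=21,
        chrom_length_bp=30_000_000,
        n_subpops=2,
        subpop_proportions=(75 / 195, 120 / 195),
        fst_target=0.24,
        maf_floor=0.05,
        ld_rho=0.3,
        inbreeding=0.9,
        missing_rate=missing_rate,
        seed=seed,
    )


def oat195_phenotype_config(
    seed: int = 0,
    traits: tuple[str, ...] = tuple(TRAITS_OAT),
    h2_range: tuple[float, float] = (0.55, 0.76),
    n_qtl_per_trait: int = 300,
) -> SimPhenotypeConfig:
    """Seven quantitative traits in four environments with moderate-to-high
    heritability drawn once from ``h2_range`` (deterministic in seed).

    Traits are polygenic (300 QTL) — agronomic traits are governed by many
    small-effect loci, and on a structured panel a sparse architecture
    would make the between-group share of genetic variance vary wildly
    from trait to trait."""
    rng = np.random.default_rng(seed + 104729)
    h2s = tuple(float(h) for h in rng.uniform(*h2_range, size=len(traits)))
    return SimPhenotypeConfig(
        traits=tuple(traits),
        n_qtl_per_trait=n_qtl_per_trait,
        h2_target=h2s,
        n_environments=4,
        env_effect_sd=0.5,
        gxe_var_fraction=0.15,
        group_effect_sd=0.3,
        seed=seed,
    )
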