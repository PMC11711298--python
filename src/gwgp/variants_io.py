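"""Genotype input/output and marker quality control.

The pipeline operates on biallelic SNP dosages (count of ALT alleles, 0/1/2,
with missing calls carried as NaN). Genotypes enter from a VCF with GT fields;
marker QC applies the standard panel filters — minor allele frequency,
per-SNP heterozygote fraction and per-SNP missingness — and missing calls are
completed by per-SNP mean imputation so downstream matrix algebra sees a
dense matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "FilterSpec",
    "read_vcf",
    "filter_snps",
    "impute_missing",
    "write_dosage_tsv",
]

MARKER_COLUMNS = ("chrom", "pos", "ref", "alt")


@dataclass
class GenotypeMatrix:
    """Accessions x SNPs alt-allele dosage matrix with marker metadata.

    Attributes
    ----------
    dosages
        Float array of shape (n_accessions, n_snps); entries in {0, 1, 2}
        or NaN for missing calls (imputed matrices hold real values in
        [0, 2]).
    accession_ids
        Unique sample identifiers, one per row.
    markers
        DataFrame with columns chrom, pos (1-based), ref, alt; one row per
        SNP, unique on (chrom, pos).
    provenance
        Log of the I/O and filtering steps applied, human readable.
    """

    dosages: np.ndarray
    accession_ids: list[str]
    markers: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D accessions x SNPs array")
        if self.dosages.shape[0] != len(self.accession_ids):
            raise ValueError("row count does not match accession_ids")
        if self.dosages.shape[1] != len(self.markers):
            raise ValueError("column count does not match markers table")
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise ValueError("accession ids must be unique")
        key = self.markers[["chrom", "pos"]].apply(tuple, axis=1)
        if key.duplicated().any():
            raise ValueError("duplicate (chrom, pos) in marker table")
        if len(self.markers) and (self.markers["pos"] < 1).any():
            raise ValueError("positions must be >= 1 (1-based)")

    @property
    def n_accessions(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def allele_freqs(self) -> np.ndarray:
        """Per-SNP ALT allele frequency over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def take_snps(self, idx: np.ndarray, note: str | None = None) -> "GenotypeMatrix":
        """Column subset preserving order; appends a provenance note."""
        idx = np.asarray(idx)
        prov = list(self.provenance)
        if note:
            prov.append(note)
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            accession_ids=list(self.accession_ids),
            markers=self.markers.iloc[idx].reset_index(drop=True),
            provenance=prov,
        )

    def take_accessions(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            dosages=self.dosages[idx, :],
            accession_ids=[self.accession_ids[i] for i in idx],
            markers=self.markers.copy(),
            provenance=list(self.provenance),
        )


@dataclass(frozen=True)
class FilterSpec:
    """Marker QC thresholds.

    Comparisons are strict: a SNP is kept iff MAF > maf_min, heterozygote
    fraction < het_max and missing fraction < missing_max. MAF and
    heterozygosity are computed over non-missing calls; the missing fraction
    over all calls.
    """

    maf_min: float = 0.01
    het_max: float = 0.20
    missing_max: float = 0.70
    biallelic_only: bool = True

    def __post_init__(self) -> None:
        for name in ("maf_min", "het_max", "missing_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def read_vcf(path: str, biallelic_only: bool = True) -> GenotypeMatrix:
    """Read a VCF with GT fields into a dosage matrix.

    ``./.`` and ``.|.`` genotypes map to NaN. Multiallelic records are
    dropped (and counted in provenance) when ``biallelic_only``.
    """
    import os

    from cyvcf2 import VCF

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if os.path.getsize(path) == 0:
        raise ValueError(f"empty VCF file: {path}")

    try:
        vcf = VCF(path)
    except Exception as exc:  # htslib raises opaque errors on bad headers
        raise ValueError(f"failed to parse VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    meta: list[tuple] = []
    n_multi = 0
    for i, variant in enumerate(vcf):
        if len(variant.ALT) != 1:
            if biallelic_only:
                n_multi += 1
                continue
            raise ValueError(
                f"multiallelic record at {variant.CHROM}:{variant.POS} "
                "(record {i + 1}); pass biallelic_only=True to drop"
            )
        gts = variant.genotypes  # [[a1, a2, phased], ...]
        dose = np.empty(len(samples))
        for s, g in enumerate(gts):
            a = g[:-1]
            dose[s] = np.nan if min(a) < 0 else float(sum(a))
        rows.append(dose)
        meta.append((variant.CHROM, variant.POS, variant.REF, variant.ALT[0]))
    if not rows:
        raise ValueError(f"no biallelic SNP records found in {path}")

    markers = pd.DataFrame(meta, columns=list(MARKER_COLUMNS))
    prov = [f"read_vcf: {path} ({len(rows)} SNPs x {len(samples)} accessions)"]
    if n_multi:
        prov.append(f"read_vcf: dropped {n_multi} multiallelic records")
    return GenotypeMatrix(
        dosages=np.vstack(rows).T,
        accession_ids=samples,
        markers=markers,
        provenance=prov,
    )


def _snp_stats(geno: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(maf, het_fraction, missing_fraction) per SNP."""
    d = geno.dosages
    miss = np.isnan(d)
    n_obs = (~miss).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_obs > 0, np.nansum(d, axis=0) / (2.0 * n_obs), np.nan)
        het = np.where(n_obs > 0, np.nansum(d == 1, axis=0) / n_obs, np.nan)
    maf = np.minimum(p, 1.0 - p)
    miss_frac = miss.mean(axis=0)
    return maf, het, miss_frac


def filter_snps(geno: GenotypeMatrix, spec: FilterSpec | None = None) -> GenotypeMatrix:
    """Apply MAF / heterozygosity / missingness filters (strict thresholds)."""
    spec = spec or FilterSpec()
    maf, het, miss = _snp_stats(geno)
    # SNPs with zero observed calls fail the MAF rule (maf is NaN -> not > min)
    pass_maf = maf > spec.maf_min
    pass_het = het < spec.het_max
    pass_miss = miss < spec.missing_max
    keep = pass_maf & pass_het & pass_miss
    if not keep.any():
        raise ValueError(
            "all SNPs removed by filtering "
            f"(maf>{spec.maf_min}, het<{spec.het_max}, miss<{spec.missing_max})"
        )
    note = (
        "filter_snps: removed "
        f"{int((~pass_maf).sum())} by MAF<= {spec.maf_min}, "
        f"{int((~pass_het).sum())} by het>= {spec.het_max}, "
        f"{int((~pass_miss).sum())} by missing>= {spec.missing_max}; "
        f"kept {int(keep.sum())}/{geno.n_snps}"
    )
    return geno.take_snps(np.flatnonzero(keep), note=note)


def impute_missing(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing call by its SNP's mean non-missing dosage."""
    d = geno.dosages
    miss = np.isnan(d)
    if not miss.any():
        return replace(geno, provenance=geno.provenance + ["impute_missing: no-op"])
    n_obs = (~miss).sum(axis=0)
    if (n_obs == 0).any():
        bad = np.flatnonzero(n_obs == 0)
        raise ValueError(
            f"SNPs with zero non-missing calls cannot be imputed: columns {bad[:5]}"
        )
    col_mean = np.nansum(d, axis=0) / n_obs
    filled = np.where(miss, col_mean[None, :], d)
    return GenotypeMatrix(
        dosages=filled,
        accession_ids=list(geno.accession_ids),
        markers=geno.markers.copy(),
        provenance=geno.provenance
        + [f"impute_missing: filled {int(miss.sum())} calls with SNP means"],
    )


def write_dosage_tsv(geno: GenotypeMatrix, path: str) -> None:
    """Plain TSV export: one row per accession, one column per chrom:pos."""
    cols = [f"{c}:{p}" for c, p in zip(geno.markers["chrom"], geno.markers["pos"])]
    pd.DataFrame(geno.dosages, index=geno.accession_ids, columns=cols).to_csv(
        path, sep="\t", index_label="accession"
    )
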