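"""Population-genetic summaries of a dosage panel.

Covers the genomic relationship matrix (VanRaden method 1), principal
component analysis via the GRM eigendecomposition, the Weir & Cockerham
(1984) Fst variance-components estimator (per SNP, in non-overlapping
physical windows, and genome-wide as a ratio of sums), and greedy LD-based
marker thinning within a physical window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants_io import GenotypeMatrix

__all__ = ["KinshipMatrix", "FstResult", "compute_grm", "pca", "fst", "ld_prune"]


@dataclass
class KinshipMatrix:
    """VanRaden genomic relationship matrix G = WW' / 2*sum p(1-p)."""

    values: np.ndarray
    scaling_constant: float
    allele_freqs: np.ndarray
    accession_ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric within 1e-10")


def _require_dense(geno: GenotypeMatrix, who: str) -> np.ndarray:
    if np.isnan(geno.dosages).any():
        raise ValueError(f"{who} requires a missing-free matrix; impute first")
    return geno.dosages


def compute_grm(geno: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden method-1 GRM from the panel's own allele frequencies.

    W holds dosages centered by 2p per column; the scaling constant is
    2 * sum_j p_j (1 - p_j). Monomorphic columns are rejected: they carry no
    relationship information and should have been removed by QC.
    """
    d = _require_dense(geno, "compute_grm")
    if geno.n_accessions < 2:
        raise ValueError("need at least two accessions")
    p = d.mean(axis=0) / 2.0
    mono = (p <= 0.0) | (p >= 1.0)
    if mono.any():
        raise ValueError(
            f"{int(mono.sum())} monomorphic SNPs present; filter them "
            "(filter_snps) before computing the GRM"
        )
    W = d - 2.0 * p[None, :]
    c = float(2.0 * np.sum(p * (1.0 - p)))
    return KinshipMatrix(
        values=(W @ W.T) / c,
        scaling_constant=c,
        allele_freqs=p,
        accession_ids=list(geno.accession_ids),
    )


def pca(
    geno: GenotypeMatrix, n_components: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """PC scores and explained-variance fractions from the GRM spectrum.

    Scores are eigenvectors scaled by sqrt(eigenvalue) (PLINK convention);
    fractions are eigenvalues over the GRM trace, non-increasing.
    """
    if n_components <= 0:
        raise ValueError("n_components must be positive")
    if n_components >= min(geno.n_accessions, geno.n_snps):
        raise ValueError("n_components must be < min(n_accessions, n_snps)")
    G = compute_grm(geno).values
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    lam = np.clip(evals[:n_components], 0.0, None)
    scores = evecs[:, :n_components] * np.sqrt(lam)[None, :]
    fractions = evals[:n_components] / evals.sum()
    return scores, fractions


@dataclass
class FstResult:
    """Weir–Cockerham variance components and theta estimates."""

    per_snp: pd.DataFrame  # chrom, pos, a, b, c, fst
    windowed: pd.DataFrame  # chrom, window_start, window_end, n_snps, fst
    overall: float

    @property
    def n_snps(self) -> int:
        return len(self.per_snp)


def _wc_components(
    d: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP Weir & Cockerham (1984) a, b, c for diploid data.

    Two-level estimator (populations, individuals) with the observed
    heterozygote correction; vectorized over SNPs. Missing calls are
    excluded per subpopulation per SNP.
    """
    pops = np.unique(labels)
    r = len(pops)
    m = d.shape[1]
    n_i = np.zeros((r, m))  # individuals observed per pop per SNP
    p_i = np.zeros((r, m))  # ALT frequency per pop
    h_i = np.zeros((r, m))  # observed het fraction per pop
    for k, pop in enumerate(pops):
        sub = d[labels == pop]
        obs = ~np.isnan(sub)
        cnt = obs.sum(axis=0)
        if (cnt < 2).any():
            # sub-2 sample sizes make the variance components undefined
            raise ValueError(
                "each subpopulation needs >=2 non-missing calls per SNP; "
                "filter or impute first"
            )
        n_i[k] = cnt
        p_i[k] = np.nansum(sub, axis=0) / (2.0 * cnt)
        h_i[k] = np.nansum(sub == 1, axis=0) / cnt

    n_bar = n_i.mean(axis=0)
    n_tot = n_i.sum(axis=0)
    n_c = (n_tot - (n_i**2).sum(axis=0) / n_tot) / (r - 1)
    p_bar = (n_i * p_i).sum(axis=0) / n_tot
    s2 = (n_i * (p_i - p_bar[None, :]) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (n_i * h_i).sum(axis=0) / n_tot

    pq = p_bar * (1.0 - p_bar)
    a = (n_bar / n_c) * (
        s2 - (pq - s2 * (r - 1) / r - h_bar / 4.0) / (n_bar - 1.0)
    )
    b = (n_bar / (n_bar - 1.0)) * (
        pq - s2 * (r - 1) / r - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar)
    )
    c = h_bar / 2.0
    return a, b, c


def fst(
    geno: GenotypeMatrix,
    subpop_labels: np.ndarray,
    window_bp: int = 30_000,
) -> FstResult:
    """Weir–Cockerham Fst per SNP, per non-overlapping window, and overall.

    Window and overall estimates aggregate variance components as a ratio
    of sums (sum a / sum(a+b+c)), the standard multi-locus combination;
    per-SNP theta may be negative. Windows tile each chromosome from
    position 1 in steps of ``window_bp``.
    """
    labels = np.asarray(subpop_labels)
    if len(labels) != geno.n_accessions:
        raise ValueError("labels length must match accession count")
    pops, counts = np.unique(labels, return_counts=True)
    if len(pops) < 2:
        raise ValueError("need at least two subpopulations")
    if (counts < 2).any():
        raise ValueError("every subpopulation needs at least two accessions")

    a, b, c = _wc_components(geno.dosages, labels)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(denom != 0, a / denom, np.nan)
    per_snp = pd.DataFrame(
        {
            "chrom": geno.markers["chrom"].to_numpy(),
            "pos": geno.markers["pos"].to_numpy(),
            "a": a,
            "b": b,
            "c": c,
            "fst": theta,
        }
    )

    win_rows = []
    for chrom, grp in per_snp.groupby("chrom", sort=False):
        win_idx = (grp["pos"].to_numpy() - 1) // window_bp
        for w in np.unique(win_idx):
            sel = grp[win_idx == w]
            num, den = sel["a"].sum(), (sel["a"] + sel["b"] + sel["c"]).sum()
            win_rows.append(
                {
                    "chrom": chrom,
                    "window_start": int(w) * window_bp + 1,
                    "window_end": (int(w) + 1) * window_bp,
                    "n_snps": len(sel),
                    "fst": num / den if den != 0 else np.nan,
                }
            )
    windowed = pd.DataFrame(win_rows)
    overall = float(a.sum() / denom.sum())
    return FstResult(per_snp=per_snp, windowed=windowed, overall=overall)


def ld_prune(
    geno: GenotypeMatrix, r2_max: float = 0.98, window_kb: float = 100.0
) -> np.ndarray:
    """Greedy left-to-right LD thinning within a physical window.

    Scanning each chromosome in position order, a SNP is dropped when its
    squared Pearson dosage correlation with any already-retained SNP within
    ``window_kb`` upstream exceeds ``r2_max``. Returns retained column
    indices in original order. Ties (equal position) keep the earlier column.
    """
    d = _require_dense(geno, "ld_prune")
    n = d.shape[0]
    sd = d.std(axis=0)
    z = np.zeros_like(d)
    ok = sd > 0
    z[:, ok] = (d[:, ok] - d[:, ok].mean(axis=0)) / sd[ok]
    window_bp = window_kb * 1000.0

    retained: list[int] = []
    chrom_arr = geno.markers["chrom"].to_numpy()
    pos_arr = geno.markers["pos"].to_numpy()
    for chrom in dict.fromkeys(chrom_arr):
        idx = np.flatnonzero(chrom_arr == chrom)
        idx = idx[np.argsort(pos_arr[idx], kind="stable")]
        kept: list[int] = []
        kept_pos: list[float] = []
        start = 0  # left edge of the in-window retained set
        for j in idx:
            pj = pos_arr[j]
            while start < len(kept) and kept_pos[start] < pj - window_bp:
                start += 1
            inwin = kept[start:]
            if inwin and sd[j] > 0:
                r = z[:, inwin].T @ z[:, j] / n
                if np.any(r**2 > r2_max):
                    continue
            kept.append(int(j))
            kept_pos.append(float(pj))
        retained.extend(kept)
    return np.array(sorted(retained), dtype=int)
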