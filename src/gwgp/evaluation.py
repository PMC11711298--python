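"""Cross-validated benchmarking of prediction models and the GWAS-derived
marker-subset sweep.

The engine runs repeated k-fold cross-validation (default fivefold, i.e.
80/20 train/test) with nested hyperparameter tuning: within each training
fold every candidate from the model's grid is scored by internal k-fold
accuracy, the winner is refit on the whole training fold and evaluated on
the held-out fold by four metrics — Pearson accuracy, unbiasedness slope
(observed regressed on predicted), MSE and MAE.

The marker-subset sweep compares top-N GWAS-ranked marker panels against
the all-marker baseline under identical fold splits. Two ranking modes:
``within_fold`` re-runs the association scan on each training fold only
(leakage-safe); ``whole_data`` ranks once from a scan of all accessions,
which reuses the test accessions for ranking and is therefore optimistically
biased — it is provided for comparability with published pipelines and
flagged as such in the report.

Randomness is hierarchical: the top-level seed spawns one stream per
repeat, so fold splits are invariant to the model list.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
import pandas as pd

from . import gp_models
from .gp_models import ModelSpec, default_grid
from .gwas import GwasResult, mlm_scan, rank_markers
from .popgen import KinshipMatrix
from .variants_io import GenotypeMatrix

__all__ = [
    "CVConfig",
    "CVReport",
    "SweepReport",
    "make_folds",
    "metrics",
    "run_cv",
    "marker_subset_sweep",
    "report",
]

UsageRecorder = Callable[[str, int, int, np.ndarray], None]


@dataclass(frozen=True)
class CVConfig:
    """Repeated cross-validation settings."""

    n_folds: int = 5
    n_repeats: int = 500
    tuning_folds: int = 5
    seed: int = 0
    models: tuple[ModelSpec, ...] = tuple(
        ModelSpec(f) for f in gp_models.FAMILIES
    )
    grid_size: str = "full"

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not self.models:
            raise ValueError("model list must not be empty")


@dataclass
class CVReport:
    cells: pd.DataFrame  # trait, model, repeat, fold, accuracy, slope, mse, mae
    config: CVConfig
    failures: list[str] = field(default_factory=list)

    def aggregate(self) -> pd.DataFrame:
        g = self.cells.groupby(["trait", "model"])
        out = g.agg(
            mean_accuracy=("accuracy", "mean"),
            sd_accuracy=("accuracy", "std"),
            mean_slope=("slope", "mean"),
            mean_mse=("mse", "mean"),
            mean_mae=("mae", "mean"),
            n_cells=("accuracy", "size"),
        ).reset_index()
        return out


@dataclass
class SweepReport:
    cells: pd.DataFrame  # trait, model, top_n, repeat, fold, metrics...
    mode: str
    top_grid: tuple[int, ...]
    config: CVConfig
    biased_ranking: bool  # True for whole_data mode

    def aggregate(self) -> pd.DataFrame:
        g = self.cells.groupby(["trait", "model", "top_n"])
        return g.agg(
            mean_accuracy=("accuracy", "mean"),
            sd_accuracy=("accuracy", "std"),
            mean_slope=("slope", "mean"),
            mean_mse=("mse", "mean"),
            mean_mae=("mae", "mean"),
            n_cells=("accuracy", "size"),
        ).reset_index()


def make_folds(
    accession_ids: list[str] | int, n_folds: int, seed: int
) -> np.ndarray:
    """Random fold assignment: near-equal parts (sizes differ by <= 1)."""
    n = accession_ids if isinstance(accession_ids, int) else len(accession_ids)
    if n_folds > n:
        raise ValueError("n_folds exceeds the number of accessions")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    for k, part in enumerate(np.array_split(perm, n_folds)):
        assignment[part] = k
    return assignment


def metrics(
    y_c: np.ndarray, y_p: np.ndarray
) -> tuple[float, float, float, float]:
    """(accuracy, unbiasedness slope, MSE, MAE) on a test fold.

    Accuracy is the Pearson correlation of observed and predicted; the slope
    is from regressing observed on predicted (1 = unbiased scaling). Both
    are NaN when predictions are constant.
    """
    y_c = np.asarray(y_c, dtype=float).ravel()
    y_p = np.asarray(y_p, dtype=float).ravel()
    if len(y_c) != len(y_p):
        raise ValueError("length mismatch between observed and predicted")
    if len(y_c) < 3:
        raise ValueError("need at least 3 test observations")
    diff = y_p - y_c
    mse = float(np.mean(diff**2))
    mae = float(np.mean(np.abs(diff)))
    var_p = y_p.var(ddof=1)
    if var_p <= 0 or y_c.var(ddof=1) <= 0:
        return np.nan, np.nan, mse, mae
    cov = float(np.cov(y_c, y_p, ddof=1)[0, 1])
    acc = cov / np.sqrt(y_c.var(ddof=1) * var_p)
    slope = cov / var_p
    return float(acc), float(slope), mse, mae


def _repeat_seed(seed: int, repeat: int, salt: int = 0) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(repeat, salt))
    return int(ss.generate_state(1)[0] % (2**31))


def _tune(
    spec: ModelSpec,
    grid: list[dict[str, Any]],
    W: np.ndarray,
    y: np.ndarray,
    tuning_folds: int,
    seed: int,
) -> ModelSpec:
    """Grid search by internal k-fold mean accuracy; first-best wins ties."""
    if len(grid) <= 1:
        return spec.with_params(**grid[0]) if grid else spec
    k = min(tuning_folds, len(y))
    folds = make_folds(len(y), k, seed)
    best_spec, best_score = None, -np.inf
    for params in grid:
        cand = spec.with_params(**params)
        scores = []
        for f in range(k):
            tr, te = folds != f, folds == f
            if te.sum() < 3:
                continue
            try:
                model = gp_models.fit(cand, W[tr], y[tr])
                acc = metrics(y[te], gp_models.predict(model, W[te]))[0]
            except Exception:
                acc = np.nan
            scores.append(acc)
        score = np.nanmean(scores) if scores and not np.all(np.isnan(scores)) else -np.inf
        if score > best_score:
            best_score, best_spec = score, cand
    return best_spec if best_spec is not None else spec


def _as_trait_dict(y_c) -> dict[str, np.ndarray]:
    if isinstance(y_c, pd.DataFrame):
        return {str(t): y_c[t].to_numpy(float) for t in y_c.columns}
    if isinstance(y_c, pd.Series):
        return {str(y_c.name or "trait"): y_c.to_numpy(float)}
    if isinstance(y_c, dict):
        return {str(k): np.asarray(v, dtype=float) for k, v in y_c.items()}
    return {"trait": np.asarray(y_c, dtype=float)}


def run_cv(
    geno: GenotypeMatrix,
    y_c,
    config: CVConfig,
    usage_recorder: UsageRecorder | None = None,
) -> CVReport:
    """Repeated k-fold CV of every configured model on every trait."""
    traits = _as_trait_dict(y_c)
    W_all = geno.dosages
    if np.isnan(W_all).any():
        raise ValueError("genotypes must be imputed before run_cv")
    for t, v in traits.items():
        if len(v) != geno.n_accessions:
            raise ValueError(f"trait {t}: phenotype length mismatch")

    rows, failures = [], []
    for rep in range(config.n_repeats):
        folds = make_folds(
            geno.n_accessions, config.n_folds, _repeat_seed(config.seed, rep)
        )
        for f in range(config.n_folds):
            tr = np.flatnonzero(folds != f)
            te = np.flatnonzero(folds == f)
            if usage_recorder:
                usage_recorder("train", rep, f, tr)
                usage_recorder("test", rep, f, te)
            for trait, y in traits.items():
                for spec in config.models:
                    cell = _fit_eval_cell(
                        spec, W_all, y, tr, te, config,
                        _repeat_seed(config.seed, rep, salt=1 + f),
                    )
                    if cell is None:
                        failures.append(
                            f"{trait}/{spec.family} failed on repeat {rep} fold {f}"
                        )
                        cell = dict.fromkeys(
                            ("accuracy", "slope", "mse", "mae"), np.nan
                        ) | {"params": None}
                    rows.append(
                        {
                            "trait": trait,
                            "model": spec.family,
                            "repeat": rep,
                            "fold": f,
                            **cell,
                        }
                    )
    return CVReport(cells=pd.DataFrame(rows), config=config, failures=failures)


def _fit_eval_cell(
    spec: ModelSpec,
    W: np.ndarray,
    y: np.ndarray,
    tr: np.ndarray,
    te: np.ndarray,
    config: CVConfig,
    tune_seed: int,
) -> dict | None:
    grid = default_grid(spec.family, size=config.grid_size)
    try:
        tuned = _tune(spec, grid, W[tr], y[tr], config.tuning_folds, tune_seed)
        model = gp_models.fit(tuned, W[tr], y[tr])
        acc, slope, mse, mae = metrics(y[te], gp_models.predict(model, W[te]))
    except Exception:
        return None
    return {
        "accuracy": acc,
        "slope": slope,
        "mse": mse,
        "mae": mae,
        "params": json.dumps(tuned.hyperparams, default=str),
    }


def _grm_of(geno: GenotypeMatrix) -> KinshipMatrix:
    # tolerant GRM (monomorphic columns contribute nothing); used on fold
    # subsets where strict QC guarantees no longer hold
    d = geno.dosages
    p = d.mean(axis=0) / 2.0
    c = float(2.0 * np.sum(p * (1.0 - p)))
    Wc = d - 2.0 * p[None, :]
    return KinshipMatrix(
        values=Wc @ Wc.T / c,
        scaling_constant=c,
        allele_freqs=p,
        accession_ids=list(geno.accession_ids),
    )


def _rank_on(
    geno_sub: GenotypeMatrix,
    ranking_sets: dict[str, np.ndarray],
    rows: np.ndarray,
    n_pcs: int,
) -> np.ndarray:
    """Full marker ordering from scans restricted to ``rows`` accessions.

    Columns monomorphic within the subset rank last (their tests are flagged
    p=1). Returns indices into the full marker panel, best first.
    """
    sub = geno_sub.take_accessions(rows)
    kin = _grm_of(sub)
    scans: list[GwasResult] = []
    for name, vec in ranking_sets.items():
        scans.append(
            mlm_scan(
                np.asarray(vec, dtype=float)[rows],
                sub,
                kin,
                n_pcs=n_pcs,
                phenotype_set=name,
            )
        )
    return rank_markers(scans, top_n=sub.n_snps)


def marker_subset_sweep(
    geno: GenotypeMatrix,
    y_c,
    gwas_inputs: dict[str, np.ndarray] | None,
    top_grid: tuple[int, ...] = (100, 500, 1000, 3000, 5000),
    mode: str = "within_fold",
    config: CVConfig | None = None,
    model: ModelSpec | None = None,
    n_pcs: int = 3,
    usage_recorder: UsageRecorder | None = None,
) -> SweepReport:
    """Top-N GWAS-derived marker panels versus the all-marker baseline.

    ``gwas_inputs`` maps phenotype-set names (environment means, "BLUP") to
    per-accession vectors used for ranking; defaults to the trait itself.
    ``model`` is the single family carried across the sweep (the benchmark's
    best all-marker model); defaults to ridge. ``top_n`` values beyond the
    marker count are skipped with a note.
    """
    if mode not in ("within_fold", "whole_data"):
        raise ValueError("mode must be 'within_fold' or 'whole_data'")
    config = config or CVConfig(n_repeats=10, grid_size="fast")
    model = model or ModelSpec("ridge")
    traits = _as_trait_dict(y_c)
    if len(traits) != 1:
        raise ValueError("sweep runs one trait at a time")
    (trait, y), = traits.items()
    W_all = geno.dosages
    if np.isnan(W_all).any():
        raise ValueError("genotypes must be imputed before the sweep")
    ranking_sets = gwas_inputs or {"trait": y}
    top_grid = tuple(sorted(set(int(t) for t in top_grid)))
    usable = [t for t in top_grid if t <= geno.n_snps]

    whole_rank = None
    if mode == "whole_data":
        whole_rank = _rank_on(
            geno, ranking_sets, np.arange(geno.n_accessions), n_pcs
        )

    rows = []
    for rep in range(config.n_repeats):
        folds = make_folds(
            geno.n_accessions, config.n_folds, _repeat_seed(config.seed, rep)
        )
        for f in range(config.n_folds):
            tr = np.flatnonzero(folds != f)
            te = np.flatnonzero(folds == f)
            if mode == "within_fold":
                rank = _rank_on(geno, ranking_sets, tr, n_pcs)
                if usage_recorder:
                    usage_recorder("ranking", rep, f, tr)
            else:
                rank = whole_rank
            tune_seed = _repeat_seed(config.seed, rep, salt=1 + f)
            for top_n in list(usable) + ["all"]:
                cols = (
                    np.arange(geno.n_snps)
                    if top_n == "all"
                    else np.sort(rank[: int(top_n)])
                )
                cell = _fit_eval_cell(
                    model, W_all[:, cols], y, tr, te, config, tune_seed
                )
                if cell is None:
                    cell = dict.fromkeys(
                        ("accuracy", "slope", "mse", "mae"), np.nan
                    ) | {"params": None}
                rows.append(
                    {
                        "trait": trait,
                        "model": model.family,
                        "top_n": top_n,
                        "repeat": rep,
                        "fold": f,
                        **cell,
                    }
                )
    return SweepReport(
        cells=pd.DataFrame(rows),
        mode=mode,
        top_grid=tuple(usable),
        config=config,
        biased_ranking=(mode == "whole_data"),
    )


def report(
    rep: CVReport | SweepReport,
    out_dir: str,
    inputs_hash: str | None = None,
) -> dict[str, str]:
    """Write tidy aggregate + per-cell TSVs and a JSON run manifest."""
    os.makedirs(out_dir, exist_ok=True)
    agg = rep.aggregate()
    agg_path = os.path.join(out_dir, "aggregate.tsv")
    cells_path = os.path.join(out_dir, "cells.tsv")
    agg.to_csv(agg_path, sep="\t", index=False, float_format="%.6g")
    rep.cells.to_csv(cells_path, sep="\t", index=False, float_format="%.6g")
    manifest = {
        "kind": type(rep).__name__,
        "config": {
            "n_folds": rep.config.n_folds,
            "n_repeats": rep.config.n_repeats,
            "tuning_folds": rep.config.tuning_folds,
            "seed": rep.config.seed,
            "grid_size": rep.config.grid_size,
            "models": [m.family for m in rep.config.models],
        },
        "inputs_hash": inputs_hash,
    }
    if isinstance(rep, SweepReport):
        manifest["mode"] = rep.mode
        manifest["top_grid"] = list(rep.top_grid)
        manifest["biased_ranking"] = rep.biased_ranking
    if isinstance(rep, CVReport):
        manifest["failures"] = rep.failures
    man_path = os.path.join(out_dir, "manifest.json")
    with open(man_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {"aggregate": agg_path, "cells": cells_path, "manifest": man_path}


def hash_inputs(geno: GenotypeMatrix, y_c) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(np.nan_to_num(geno.dosages)).tobytes())
    for t, v in sorted(_as_trait_dict(y_c).items()):
        h.update(t.encode())
        h.update(np.ascontiguousarray(v).tobytes())
    return h.hexdigest()[:16]
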