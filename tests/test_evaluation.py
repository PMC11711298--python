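"""Cross-validation engine: folds, metrics, reporting, leakage safety."""

import json

import numpy as np
import pytest

import gwgp
from gwgp import evaluation as ev, gp_models as gp, simulate as sim


def test_fold_sizes_and_determinism():
    folds = ev.make_folds(195, 5, seed=3)
    sizes = sorted(np.bincount(folds))
    assert sizes == [39] * 5
    assert (folds == ev.make_folds(195, 5, seed=3)).all()
    assert not (folds == ev.make_folds(195, 5, seed=4)).all()
    small = np.bincount(ev.make_folds(7, 5, seed=0))
    assert sorted(small, reverse=True) == [2, 2, 1, 1, 1]
    with pytest.raises(ValueError):
        ev.make_folds(3, 5, seed=0)


def test_metrics_identities_and_hand_values():
    y = np.array([1.0, 2.0, 3.0, 4.0])
    assert ev.metrics(y, y) == pytest.approx((1.0, 1.0, 0.0, 0.0))
    acc, slope, mse, mae = ev.metrics(y, 2 * y)
    assert acc == pytest.approx(1.0)
    assert slope == pytest.approx(0.5)
    yp = np.array([1.0, 2.0, 3.0, 5.0])
    acc, slope, mse, mae = ev.metrics(y, yp)
    assert mse == pytest.approx(0.25)
    assert mae == pytest.approx(0.25)
    assert acc == pytest.approx(np.corrcoef(y, yp)[0, 1])
    assert acc == pytest.approx(0.9827, abs=5e-4)


def test_metrics_errors_and_degenerate():
    with pytest.raises(ValueError):
        ev.metrics([1, 2], [1, 2])
    with pytest.raises(ValueError):
        ev.metrics([1, 2, 3], [1, 2])
    acc, slope, mse, mae = ev.metrics([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
    assert np.isnan(acc) and np.isnan(slope)
    assert mse > 0


def test_mae_squared_bounded_by_mse():
    rng = np.random.default_rng(0)
    for _ in range(50):
        a, b = rng.normal(size=(2, 20))
        _, _, mse, mae = ev.metrics(a, b)
        assert mae**2 <= mse + 1e-12


@pytest.fixture(scope="module")
def cv_setup():
    cfg = gwgp.SimGenotypeConfig(n_accessions=120, n_snps=400, n_chromosomes=2,
                                 fst_target=0.1, seed=41)
    geno, labels = sim.simulate_genotypes(cfg)
    pcfg = gwgp.SimPhenotypeConfig(traits=("t",), n_qtl_per_trait=30,
                                   h2_target=0.7, n_environments=1,
                                   gxe_var_fraction=0.0, seed=42)
    trials, _ = sim.simulate_phenotypes(geno, labels, pcfg)
    y = trials.set_index("accession")["value"].loc[geno.accession_ids].to_numpy()
    return geno, y


def test_run_cv_report_shape_and_bounds(cv_setup):
    geno, y = cv_setup
    cfg = ev.CVConfig(
        n_repeats=2, seed=7, grid_size="fast",
        models=(gp.ModelSpec("ridge"), gp.ModelSpec("gblup")),
    )
    rep = ev.run_cv(geno, {"t": y}, cfg)
    assert len(rep.cells) == 2 * 5 * 2  # repeats x folds x models
    ok = rep.cells["accuracy"].dropna()
    assert ((ok >= -1) & (ok <= 1)).all()
    assert (rep.cells["mae"] ** 2 <= rep.cells["mse"] + 1e-12).all()
    # adding a model must not perturb fold splits: ridge cells identical
    cfg2 = ev.CVConfig(
        n_repeats=2, seed=7, grid_size="fast",
        models=(gp.ModelSpec("ridge"),),
    )
    rep2 = ev.run_cv(geno, {"t": y}, cfg2)
    a = rep.cells.query("model=='ridge'")["accuracy"].to_numpy()
    b = rep2.cells["accuracy"].to_numpy()
    assert np.allclose(a, b, equal_nan=True)


def test_no_test_accession_in_training(cv_setup):
    geno, y = cv_setup
    usage = []
    cfg = ev.CVConfig(n_repeats=1, seed=1, grid_size="fast",
                      models=(gp.ModelSpec("ridge"),))
    ev.run_cv(geno, {"t": y}, cfg, usage_recorder=lambda *a: usage.append(a))
    by_fold = {}
    for stage, rep, fold, idx in usage:
        by_fold.setdefault((rep, fold), {})[stage] = set(idx.tolist())
    for (r, f), d in by_fold.items():
        assert not d["train"] & d["test"]
    # each accession in exactly one test fold
    all_test = sum((sorted(d["test"]) for d in by_fold.values()), [])
    assert sorted(all_test) == list(range(geno.n_accessions))


def test_sweep_ranking_excludes_test_fold(cv_setup):
    geno, y = cv_setup
    usage = []
    cfg = ev.CVConfig(n_repeats=1, seed=2, grid_size="fast",
                      models=(gp.ModelSpec("ridge"),))
    rep = ev.marker_subset_sweep(
        geno, {"t": y}, None, top_grid=(50,), mode="within_fold",
        config=cfg, usage_recorder=lambda *a: usage.append(a),
    )
    folds = ev.make_folds(geno.n_accessions, 5, ev._repeat_seed(2, 0))
    for stage, r, f, idx in usage:
        if stage == "ranking":
            test_idx = set(np.flatnonzero(folds == f).tolist())
            assert not test_idx & set(idx.tolist())


def test_sweep_all_cell_matches_run_cv(cv_setup):
    geno, y = cv_setup
    cfg = ev.CVConfig(n_repeats=2, seed=9, grid_size="fast",
                      models=(gp.ModelSpec("ridge"),))
    sweep = ev.marker_subset_sweep(
        geno, {"t": y}, None, top_grid=(50,), mode="whole_data",
        config=cfg, model=gp.ModelSpec("ridge"),
    )
    cv = ev.run_cv(geno, {"t": y}, cfg)
    a = sweep.cells.query("top_n=='all'")["accuracy"].to_numpy(float)
    b = cv.cells["accuracy"].to_numpy(float)
    assert np.allclose(np.sort(a), np.sort(b))
    # oversized top_n values are skipped
    assert sweep.top_grid == (50,)
    big = ev.marker_subset_sweep(
        geno, {"t": y}, None, top_grid=(50, 10_000), mode="whole_data",
        config=ev.CVConfig(n_repeats=1, seed=9, grid_size="fast",
                           models=(gp.ModelSpec("ridge"),)),
    )
    assert big.top_grid == (50,)


def test_report_files_and_reproducibility(tmp_path, cv_setup):
    geno, y = cv_setup
    cfg = ev.CVConfig(n_repeats=1, seed=5, grid_size="fast",
                      models=(gp.ModelSpec("ridge"),))
    rep = ev.run_cv(geno, {"t": y}, cfg)
    out1 = tmp_path / "r1"
    out2 = tmp_path / "r2"
    ev.report(rep, str(out1), inputs_hash=ev.hash_inputs(geno, {"t": y}))
    rep2 = ev.run_cv(geno, {"t": y}, cfg)
    ev.report(rep2, str(out2), inputs_hash=ev.hash_inputs(geno, {"t": y}))
    assert (out1 / "aggregate.tsv").read_bytes() == (out2 / "aggregate.tsv").read_bytes()
    man = json.loads((out1 / "manifest.json").read_text())
    assert man["config"]["seed"] == 5 and man["config"]["models"] == ["ridge"]


def test_empty_model_list_rejected():
    with pytest.raises(ValueError):
        ev.CVConfig(models=())


def test_repeat_mean_stabilizes(cv_setup):
    geno, y = cv_setup
    cfg = ev.CVConfig(n_repeats=20, seed=11, grid_size="fast",
                      models=(gp.ModelSpec("ridge"),))
    rep = ev.run_cv(geno, {"t": y}, cfg)
    per_rep = rep.cells.groupby("repeat")["accuracy"].mean()
    m1, m2 = per_rep.iloc[:10].mean(), per_rep.iloc[10:].mean()
    assert abs(m1 - m2) < 0.05
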