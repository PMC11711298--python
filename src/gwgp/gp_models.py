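"""Genomic prediction models behind one fit/predict contract.

Seven families: GBLUP (mixed model on the genomic relationship matrix),
ridge, lasso, elastic net (penalized marker regressions of the bridge
family), kernel ridge regression, and support vector regression with linear
or polynomial kernel.

Conventions
-----------
Penalized objectives are parameterized as

    (1/2) ||y - W b||^2 + lam * P(b),   P_ridge = ||b||^2 / 2,
    P_lasso = ||b||_1,  P_enet = l1 ||b||_1 + (1 - l1) ||b||^2 / 2,

so elastic net at l1_fraction 0/1 is exactly ridge/lasso at the same lam,
and ridge at lam = lambda_G * 2*sum p(1-p) reproduces GBLUP predictions on
centered dosages (RR-BLUP equivalence). Phenotypes are centered and, by
default, features standardized inside fit; the intercept is never
penalized. Ridge, KRR and GBLUP are solved in closed form; lasso / elastic
net use coordinate descent and the SVR families the libsvm dual
(scikit-learn backends).
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Any

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, Lasso
from sklearn.svm import SVR

from ._reml import reml_single_kernel

__all__ = ["ModelSpec", "FittedModel", "fit", "predict", "default_grid", "FAMILIES"]

FAMILIES = (
    "gblup",
    "ridge",
    "lasso",
    "elasticnet",
    "krr",
    "svr_linear",
    "svr_poly",
)

ARCHIVE_VERSION = "gwgp-model-1"


@dataclass(frozen=True)
class ModelSpec:
    family: str
    hyperparams: dict[str, Any] = field(default_factory=dict)
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family: {self.family!r}")
        hp = self.hyperparams
        if "lam" in hp and not hp["lam"] > 0:
            raise ValueError("lam must be > 0")
        if "C" in hp and not hp["C"] > 0:
            raise ValueError("C must be > 0")
        if "epsilon" in hp and hp["epsilon"] < 0:
            raise ValueError("epsilon must be >= 0")
        if "degree" in hp and (int(hp["degree"]) != hp["degree"] or hp["degree"] < 1):
            raise ValueError("degree must be an integer >= 1")
        if "l1_fraction" in hp and not 0.0 <= hp["l1_fraction"] <= 1.0:
            raise ValueError("l1_fraction must lie in [0, 1]")

    def with_params(self, **kw: Any) -> "ModelSpec":
        return ModelSpec(self.family, {**self.hyperparams, **kw}, self.standardize)


@dataclass
class FittedModel:
    """Learned state sufficient for prediction on new genotypes."""

    family: str
    spec: ModelSpec
    center: np.ndarray  # per-feature centering constants
    scale: np.ndarray  # per-feature scaling divisors (1 when unscaled)
    intercept: float
    state: dict[str, Any] = field(default_factory=dict)
    version: str = ARCHIVE_VERSION

    def save(self, path: str) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str) -> "FittedModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if model.version != ARCHIVE_VERSION:
            raise ValueError(f"unsupported model archive version {model.version}")
        return model


def _resolve_gamma(gamma: Any, n_features: int) -> float:
    if gamma == "1/p":
        return 1.0 / n_features
    return float(gamma)


def _prep(
    W: np.ndarray, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    center = W.mean(axis=0)
    if spec.standardize and spec.family != "gblup":
        sd = W.std(axis=0)
        scale = np.where(sd > 0, sd, 1.0)
    else:
        scale = np.ones(W.shape[1])
    return (W - center[None, :]) / scale[None, :], center, scale


def _poly_kernel(A: np.ndarray, B: np.ndarray, gamma: float, r: float, d: int):
    return (gamma * (A @ B.T) + r) ** d


def _rbf_kernel(A: np.ndarray, B: np.ndarray, gamma: float):
    aa = np.sum(A**2, axis=1)[:, None]
    bb = np.sum(B**2, axis=1)[None, :]
    return np.exp(-gamma * (aa + bb - 2.0 * A @ B.T))


def _ridge_beta(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    n, p = X.shape
    if p <= n:
        return np.linalg.solve(X.T @ X + lam * np.eye(p), X.T @ y)
    dual = np.linalg.solve(X @ X.T + lam * np.eye(n), y)
    return X.T @ dual


def fit(spec: ModelSpec, W: np.ndarray, y: np.ndarray) -> FittedModel:
    """Fit one model family on training dosages W and phenotypes y."""
    W = np.asarray(W, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if np.isnan(W).any():
        raise ValueError("training dosages contain missing values; impute first")
    if W.shape[0] != len(y):
        raise ValueError("rows of W must match length of y")
    hp = dict(spec.hyperparams)
    n, p = W.shape
    y_mean = float(y.mean())
    yc = y - y_mean

    if spec.family == "gblup":
        # VanRaden GRM on the training rows; monomorphic columns contribute 0
        freqs = W.mean(axis=0) / 2.0
        c = float(2.0 * np.sum(freqs * (1.0 - freqs)))
        if c <= 0:
            raise ValueError("all training SNPs monomorphic; cannot build GRM")
        Wc = W - 2.0 * freqs[None, :]
        G = Wc @ Wc.T / c
        if "lambda_g" in hp:
            lam_g = float(hp["lambda_g"])
        else:
            reml = reml_single_kernel(yc, np.ones((n, 1)), G)
            lam_g = reml.delta
        mu = _gls_intercept(y, G, lam_g)
        alpha = np.linalg.solve(G + lam_g * np.eye(n), y - mu)
        return FittedModel(
            family="gblup",
            spec=spec,
            center=2.0 * freqs,
            scale=np.ones(p),
            intercept=mu,
            state={
                "alpha": alpha,
                "grm_scaling": c,
                "lambda_g": lam_g,
                "W_train_c": Wc,
            },
        )

    X, center, scale = _prep(W, spec)

    if spec.family == "ridge" or (
        spec.family == "elasticnet" and hp.get("l1_fraction", 0.5) == 0.0
    ):
        lam = float(hp.get("lam", 1.0))
        beta = _ridge_beta(X, yc, lam)
        return FittedModel(spec.family, spec, center, scale, y_mean, {"beta": beta})

    if spec.family == "lasso" or (
        spec.family == "elasticnet" and hp.get("l1_fraction", 0.5) == 1.0
    ):
        lam = _resolve_lam(hp, X, yc, l1=1.0)
        beta = _cd_fit(Lasso(alpha=lam / n, fit_intercept=False), X, yc)
        return FittedModel(spec.family, spec, center, scale, y_mean, {"beta": beta})

    if spec.family == "elasticnet":
        l1 = float(hp.get("l1_fraction", 0.5))
        lam = _resolve_lam(hp, X, yc, l1=l1)
        est = ElasticNet(alpha=lam / n, l1_ratio=l1, fit_intercept=False)
        beta = _cd_fit(est, X, yc)
        return FittedModel(spec.family, spec, center, scale, y_mean, {"beta": beta})

    if spec.family == "krr":
        lam = float(hp.get("lam", 1.0))
        kernel = hp.get("kernel", "poly")
        K = _train_kernel(X, X, kernel, hp, p)
        try:
            dual = np.linalg.solve(K + lam * np.eye(n), yc)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"K + lam*I numerically singular at lam={lam}; increase lam"
            ) from exc
        return FittedModel(
            "krr",
            spec,
            center,
            scale,
            y_mean,
            {"dual": dual, "X_train": X, "kernel": kernel},
        )

    if spec.family in ("svr_linear", "svr_poly"):
        C = float(hp.get("C", 1.0))
        eps = float(hp.get("epsilon", 0.1))
        if spec.family == "svr_linear":
            est = SVR(kernel="linear", C=C, epsilon=eps)
        else:
            est = SVR(
                kernel="poly",
                C=C,
                epsilon=eps,
                gamma=_resolve_gamma(hp.get("gamma", "1/p"), p),
                coef0=float(hp.get("r", 1.0)),
                degree=int(hp.get("degree", 2)),
            )
        est.fit(X, yc)
        return FittedModel(
            spec.family, spec, center, scale, y_mean, {"svr": est}
        )

    raise ValueError(f"unknown model family: {spec.family!r}")


def _resolve_lam(hp: dict, X: np.ndarray, yc: np.ndarray, l1: float) -> float:
    """Absolute lam, or lam_frac as a fraction of the coefficient-killing
    lam_max = max_j |X_j' y| (scaled by 1/l1 for elastic net), the usual
    regularization-path parameterization."""
    if "lam" in hp:
        return float(hp["lam"])
    if "lam_frac" in hp:
        lam_max = float(np.abs(X.T @ yc).max())
        return float(hp["lam_frac"]) * lam_max / max(l1, 1e-3)
    return 1.0


def _cd_fit(est, X: np.ndarray, yc: np.ndarray, tol: float = 1e-4) -> np.ndarray:
    # tol is scikit-learn's dual-gap criterion (scaled by ||y||^2), the
    # library's convergence contract for coordinate descent
    est.set_params(max_iter=10_000, tol=tol)
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            est.fit(X, yc)
        except ConvergenceWarning as exc:
            raise RuntimeError(
                f"coordinate descent did not converge within "
                f"{est.max_iter} sweeps: {exc}"
            ) from exc
    return est.coef_.copy()


def _train_kernel(A, B, kernel: str, hp: dict, p: int) -> np.ndarray:
    if kernel == "linear":
        return A @ B.T
    if kernel == "poly":
        return _poly_kernel(
            A,
            B,
            _resolve_gamma(hp.get("gamma", "1/p"), p),
            float(hp.get("r", 1.0)),
            int(hp.get("degree", 2)),
        )
    if kernel == "rbf":
        return _rbf_kernel(A, B, _resolve_gamma(hp.get("gamma", "1/p"), p))
    raise ValueError(f"unknown kernel {kernel!r}")


def _gls_intercept(y: np.ndarray, G: np.ndarray, lam_g: float) -> float:
    n = len(y)
    Vinv_1 = np.linalg.solve(G + lam_g * np.eye(n), np.ones(n))
    return float(Vinv_1 @ y / Vinv_1.sum())


def predict(model: FittedModel, W_new: np.ndarray) -> np.ndarray:
    """Predict corrected phenotypes for new genotype rows."""
    W_new = np.asarray(W_new, dtype=float)
    if W_new.shape[1] != len(model.center):
        raise ValueError(
            f"feature mismatch: model trained on {len(model.center)} markers, "
            f"got {W_new.shape[1]}"
        )
    X = (W_new - model.center[None, :]) / model.scale[None, :]

    if model.family == "gblup":
        # u_new = G_{new,train} (G + lam_G I)^-1 (y - mu); X is already
        # centered by the training 2p (scale is all-ones for gblup)
        G_nt = X @ model.state["W_train_c"].T / model.state["grm_scaling"]
        return model.intercept + G_nt @ model.state["alpha"]
    if model.family in ("ridge", "lasso", "elasticnet"):
        return model.intercept + X @ model.state["beta"]
    if model.family == "krr":
        hp = dict(model.spec.hyperparams)
        K = _train_kernel(
            X, model.state["X_train"], model.state["kernel"], hp, X.shape[1]
        )
        return model.intercept + K @ model.state["dual"]
    if model.family in ("svr_linear", "svr_poly"):
        return model.intercept + model.state["svr"].predict(X)
    raise ValueError(f"unknown model family: {model.family!r}")


def default_grid(
    family: str, size: str = "full"
) -> list[dict[str, Any]]:
    """Hyperparameter grids for internal-CV tuning.

    ``size='full'`` are the documented defaults (13 log-spaced lam values,
    Cartesian SVR grids); ``size='fast'`` are the reduced desk-scale grids
    used by the bundled benchmarks. Grids are ordered so that the
    tie-breaking rule "first wins" prefers smaller lam / simpler kernels.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown model family: {family!r}")
    if size not in ("full", "fast"):
        raise ValueError("size must be 'full' or 'fast'")

    if family == "gblup":
        return [{}]  # lambda_G is REML-estimated, no grid

    if size == "full":
        lams = list(np.logspace(-4, 4, 13))
        l1s = [0.1, 0.3, 0.5, 0.7, 0.9]
        Cs = [0.1, 1.0, 10.0, 100.0]
        epss = [0.01, 0.1, 0.5]
        gammas = ["1/p", 1e-3, 1e-2]
        rs = [0.0, 1.0]
        ds = [2, 3]
    else:
        lams = list(np.logspace(-1, 4, 5))
        l1s = [0.1, 0.5, 0.9]
        Cs = [1.0, 10.0]
        epss = [0.1]
        gammas = ["1/p"]
        rs = [1.0]
        ds = [2]

    if family == "ridge":
        return [{"lam": l} for l in lams]
    if family == "lasso":
        if size == "fast":
            return [{"lam_frac": f} for f in (0.02, 0.1, 0.3)]
        return [{"lam": l} for l in lams]
    if family == "elasticnet":
        if size == "fast":
            return [
                {"lam_frac": lf, "l1_fraction": f}
                for lf, f in product((0.02, 0.1, 0.3), l1s)
            ]
        return [{"lam": l, "l1_fraction": f} for l, f in product(lams, l1s)]
    if family == "krr":
        if size == "fast":
            lams = [1e-2, 1.0, 100.0]
            return [{"lam": l, "kernel": "poly", "gamma": "1/p", "r": 1.0, "degree": 2}
                    for l in lams]
        return [
            {"lam": l, "kernel": "poly", "gamma": g, "r": r, "degree": d}
            for l, g, r, d in product(lams, gammas, rs, ds)
        ]
    if family == "svr_linear":
        return [{"C": C, "epsilon": e} for C, e in product(Cs, epss)]
    if family == "svr_poly":
        return [
            {"C": C, "epsilon": e, "gamma": g, "r": r, "degree": d}
            for C, e, g, r, d in product(Cs, epss, gammas, rs, ds)
        ]
    raise AssertionError("unreachable")
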