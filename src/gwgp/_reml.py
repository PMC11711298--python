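"""Restricted-maximum-likelihood machinery shared across modules.

Two engines:

* :func:`reml_single_kernel` — profile REML for the one-random-component
  model y ~ N(Xb, sigma2_g K + sigma2_e I), via the spectral decomposition
  of the projected kernel and a 1-D search over delta = sigma2_e/sigma2_g
  (coarse grid then golden-section on log delta). Used by SNP-heritability
  estimation, the P3D association scan's null model, and GBLUP.

* :func:`em_reml_mme` — EM-REML on the mixed-model equations for one or two
  i.i.d. random effects (genotype, optionally G×E), used by the
  multi-environment phenotype BLUP where the design is an incidence
  structure rather than a dense kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["SingleKernelREML", "reml_single_kernel", "em_reml_mme"]

LOG_DELTA_RANGE = (-10.0, 10.0)


@dataclass
class SingleKernelREML:
    sigma2_g: float
    sigma2_e: float
    delta: float
    loglik: float
    beta: np.ndarray  # GLS fixed-effect estimates at the optimum
    at_boundary: bool

    @property
    def h2(self) -> float:
        return self.sigma2_g / (self.sigma2_g + self.sigma2_e)


def _project_out(X: np.ndarray) -> np.ndarray:
    """Residual-maker matrix I - X (X'X)^-1 X' (X assumed full rank)."""
    Q, _ = np.linalg.qr(X)
    return np.eye(X.shape[0]) - Q @ Q.T


def reml_single_kernel(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray,
    log_delta_range: tuple[float, float] = LOG_DELTA_RANGE,
    tol: float = 1e-6,
    n_grid: int = 64,
) -> SingleKernelREML:
    """Profile REML for Var(y) = sigma2_g K + sigma2_e I with fixed effects X.

    The restricted likelihood is profiled on delta = sigma2_e / sigma2_g
    using the nonzero spectrum of S K S (S the projection orthogonal to X):
    a coarse grid over log10 delta localizes the optimum, then bounded
    scalar minimization polishes it to ``tol``.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = len(y)
    q = np.linalg.matrix_rank(X)
    if n - q < 2:
        raise ValueError("too few residual degrees of freedom for REML")

    S = _project_out(X)
    SKS = S @ K @ S
    SKS = (SKS + SKS.T) / 2.0
    evals, evecs = np.linalg.eigh(SKS)
    # keep the n - q structural eigenpairs (largest); clip tiny negatives
    order = np.argsort(evals)[::-1][: n - q]
    xi = np.clip(evals[order], 0.0, None)
    eta = evecs[:, order].T @ y

    df = n - q
    eta2 = eta**2

    def neg_restricted_ll(log10_delta: float) -> float:
        delta = 10.0**log10_delta
        denom = xi + delta
        ss = float(np.sum(eta2 / denom))
        ll = 0.5 * (
            df * (np.log(df / (2.0 * np.pi)) - 1.0 - np.log(ss))
            - float(np.sum(np.log(denom)))
        )
        return -ll

    lo, hi = log_delta_range
    grid = np.linspace(lo, hi, n_grid)
    vals = np.array([neg_restricted_ll(g) for g in grid])
    i = int(np.argmin(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, n_grid - 1)]
    res = minimize_scalar(
        neg_restricted_ll, bounds=(a, b), method="bounded",
        options={"xatol": tol},
    )
    log10_delta = float(res.x)
    at_boundary = i in (0, n_grid - 1) and abs(log10_delta - grid[i]) < 2 * tol
    delta = 10.0**log10_delta
    sigma2_g = float(np.sum(eta2 / (xi + delta)) / df)
    sigma2_e = delta * sigma2_g

    # GLS fixed effects at the optimum (full-spectrum whitening)
    evals_K, evecs_K = np.linalg.eigh((K + K.T) / 2.0)
    d = np.clip(evals_K, 0.0, None) + delta
    Ut_y = evecs_K.T @ y
    Ut_X = evecs_K.T @ X
    w = 1.0 / d
    XtVX = Ut_X.T @ (Ut_X * w[:, None])
    XtVy = Ut_X.T @ (Ut_y * w)
    beta = np.linalg.solve(XtVX, XtVy)

    return SingleKernelREML(
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_e,
        delta=float(delta),
        loglik=-float(res.fun),
        beta=beta,
        at_boundary=bool(at_boundary),
    )


def em_reml_mme(
    y: np.ndarray,
    X: np.ndarray,
    Z_list: list[np.ndarray],
    max_iter: int = 500,
    tol: float = 1e-8,
) -> dict:
    """EM-REML for y = Xb + sum_i Z_i u_i + e with u_i ~ N(0, sigma2_i I).

    Iterates the classical EM updates on the mixed-model equations and
    monitors the restricted log-likelihood (computed from the MME Cholesky
    factors); convergence when successive change < ``tol``.

    Returns dict with 'beta', 'u' (list), 'sigma2' (list), 'sigma2_e',
    'loglik', 'n_iter', 'converged'.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError(
            "singular fixed-effect design: a fixed term is confounded "
            "(drop redundant environment/group columns)"
        )
    Z = [np.asarray(Zi, dtype=float) for Zi in Z_list]
    q = [Zi.shape[1] for Zi in Z]
    T = np.hstack([X] + Z)
    TtT = T.T @ T
    Tty = T.T @ y
    yty = float(y @ y)

    sigma2 = [max(np.var(y) / (2 * len(Z)), 1e-6) for _ in Z]
    sigma2_e = max(np.var(y) / 2, 1e-6)
    ll_old = -np.inf
    n_iter = 0
    converged = False

    blocks = []
    off = p
    for qi in q:
        blocks.append(slice(off, off + qi))
        off += qi

    for n_iter in range(1, max_iter + 1):
        M = TtT / sigma2_e
        for sl, qi, s2 in zip(blocks, q, sigma2):
            M[sl, sl] += np.eye(qi) / s2
        try:
            L = np.linalg.cholesky(M)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"mixed-model equations singular: {exc}") from exc
        rhs = Tty / sigma2_e
        sol = np.linalg.solve(M, rhs)
        beta = sol[:p]
        u = [sol[sl] for sl in blocks]

        Cinv_diag_tr = []
        Minv = np.linalg.inv(M)
        for sl in blocks:
            Cinv_diag_tr.append(float(np.trace(Minv[sl, sl])))

        # restricted log-likelihood via the MME determinant identity
        # -2 lR = ln|R| + ln|G| + ln|C*| + y'Py
        ypy = (yty - sol @ Tty) / sigma2_e
        logdet_M = 2.0 * float(np.sum(np.log(np.diag(L))))
        ll = -0.5 * (
            n * np.log(sigma2_e)
            + sum(qi * np.log(s2) for qi, s2 in zip(q, sigma2))
            + logdet_M
            + ypy
        )

        # EM updates: sigma2_i <- (u'u + tr Var(u - u_hat)_ii) / q_i,
        # sigma2_e <- (y'y - sol' T'y) / (n - p)
        new_sigma2 = []
        for ui, qi, tr in zip(u, q, Cinv_diag_tr):
            new_sigma2.append(float((ui @ ui + tr) / qi))
        new_sigma2_e = float((yty - sol @ Tty) / (n - p))

        sigma2 = [max(s, 1e-12) for s in new_sigma2]
        sigma2_e = max(new_sigma2_e, 1e-12)

        if abs(ll - ll_old) < tol:
            converged = True
            ll_old = ll
            break
        ll_old = ll

    if not converged and n_iter >= max_iter:
        # EM is monotone; hitting the cap on flat likelihoods is benign but
        # surfaced to the caller
        converged = False

    return {
        "beta": beta,
        "u": u,
        "sigma2": sigma2,
        "sigma2_e": sigma2_e,
        "loglik": float(ll_old),
        "n_iter": n_iter,
        "converged": converged,
    }
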