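"""Poisson log-link mixed model with a single random intercept factor.

This is the workhorse behind richness and abundance modelling: counts are
Poisson with log link, fixed effects for design factors (block, run,
organ, kingdom), a log-depth offset to absorb sequencing effort, and a
random intercept for host accession,

    y_i ~ Poisson(mu_i),  log mu_i = x_i' beta + offset_i + u_{g(i)},
    u ~ N(0, sigma2_u I).

The marginal likelihood is integrated over u by a Laplace approximation.
For a fixed variance sigma2_u, the joint mode of (beta, u) is found by
penalized iteratively reweighted least squares (PIRLS); the profiled
Laplace objective is then a smooth one-dimensional function of
log(sigma2_u), maximized by bounded Brent search.  Because the random
factor partitions the observations, Z'WZ is diagonal and each PIRLS step
is a dense solve of size (p + q).

The conditional modes of u at the optimum are the BLUPs used throughout
the pipeline (ordination, heritability, GWAS phenotypes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

__all__ = ["PoissonGLMMResult", "fit_poisson_glmm", "design_matrix"]


class GLMMConvergenceError(RuntimeError):
    """Raised when PIRLS fails to reach the requested gradient tolerance."""


@dataclass
class PoissonGLMMResult:
    beta: np.ndarray
    coef_names: list[str]
    blups: pd.Series          # conditional modes of u, indexed by group level
    sigma2_group: float       # variance of the random intercept
    loglik: float             # Laplace marginal log-likelihood
    eta: np.ndarray           # linear predictor incl. offset at the mode
    mu: np.ndarray
    offset: np.ndarray
    X: np.ndarray
    converged: bool
    n_obs: int

    @property
    def fixed_effects(self) -> pd.Series:
        return pd.Series(self.beta, index=self.coef_names)

    def var_fixed(self) -> float:
        """Variance of the fixed-effect linear predictor (offset excluded)."""
        return float(np.var(self.X @ self.beta))

    def mean_rate(self) -> float:
        """Geometric-mean Poisson rate, used for the log-link
        distribution-specific variance ln(1 + 1/rate)."""
        return float(np.exp(np.mean(self.eta)))


def design_matrix(
    frame: pd.DataFrame, factors: list[str], interactions: list[tuple[str, str]] = ()
) -> tuple[np.ndarray, list[str]]:
    """Build an intercept + treatment-coded design matrix from categoricals.

    ``interactions`` lists (outer, inner) pairs coded as inner nested in
    outer: one column per (outer level, non-reference inner level).
    Aliased (rank-deficient) columns are dropped.
    """
    cols = [np.ones(len(frame))]
    names = ["Intercept"]
    for fac in factors:
        dummies = pd.get_dummies(frame[fac].astype(str), prefix=fac, drop_first=True)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy(dtype=float))
            names.append(c)
    for outer, inner in interactions:
        combo = frame[outer].astype(str) + ":" + frame[inner].astype(str)
        # nested coding: within each outer level, drop the first inner level
        for lvl_outer in sorted(frame[outer].astype(str).unique()):
            inner_levels = sorted(
                frame.loc[frame[outer].astype(str) == lvl_outer, inner]
                .astype(str).unique()
            )
            for lvl_inner in inner_levels[1:]:
                key = f"{lvl_outer}:{lvl_inner}"
                cols.append((combo == key).to_numpy(dtype=float))
                names.append(f"{outer}[{lvl_outer}]:{inner}[{lvl_inner}]")
    X = np.column_stack(cols)
    # drop aliased columns (QR with pivoting via rank test)
    keep = _independent_columns(X)
    if len(keep) < X.shape[1]:
        dropped = [names[i] for i in range(X.shape[1]) if i not in keep]
        import logging

        logging.getLogger(__name__).warning(
            "dropping aliased design columns: %s", dropped
        )
    return X[:, keep], [names[i] for i in keep]


def _independent_columns(X: np.ndarray, tol: float = 1e-8) -> list[int]:
    keep: list[int] = []
    basis = np.empty((X.shape[0], 0))
    for j in range(X.shape[1]):
        col = X[:, j]
        if basis.shape[1]:
            resid = col - basis @ np.linalg.lstsq(basis, col, rcond=None)[0]
        else:
            resid = col
        if np.linalg.norm(resid) > tol * max(1.0, np.linalg.norm(col)):
            keep.append(j)
            basis = np.column_stack([basis, col])
    return keep


def _pirls(
    y: np.ndarray,
    X: np.ndarray,
    codes: np.ndarray,
    q: int,
    offset: np.ndarray,
    sigma2: float,
    beta0: np.ndarray,
    u0: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, bool]:
    """Penalized IRLS for the joint mode of (beta, u) at fixed sigma2."""
    n, p = X.shape
    beta, u = beta0.copy(), u0.copy()
    inv_s2 = 1.0 / sigma2
    eta = X @ beta + u[codes] + offset
    eta = np.clip(eta, -500, 500)
    dev_prev = np.inf
    for _ in range(max_iter):
        mu = np.exp(eta)
        w = mu
        z = (eta - offset) + (y - mu) / mu  # working response (offset removed)
        # normal equations for [X Z] with ridge I/sigma2 on the u block
        XtW = X.T * w
        A11 = XtW @ X
        A12 = np.zeros((p, q))
        np.add.at(A12.T, codes, (X * w[:, None]))
        d = np.bincount(codes, weights=w, minlength=q)
        rhs1 = XtW @ z
        rhs2 = np.bincount(codes, weights=w * z, minlength=q)
        A = np.block([[A11, A12], [A12.T, np.diag(d + inv_s2)]])
        rhs = np.concatenate([rhs1, rhs2])
        try:
            sol = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            sol = np.linalg.lstsq(A, rhs, rcond=None)[0]
        beta, u = sol[:p], sol[p:]
        eta = np.clip(X @ beta + u[codes] + offset, -500, 500)
        mu = np.exp(eta)
        dev = -2.0 * (np.sum(y * eta - mu) - 0.5 * inv_s2 * np.sum(u**2))
        if abs(dev - dev_prev) < tol * (abs(dev) + 1.0):
            # gradient check at the mode
            g_beta = X.T @ (y - mu)
            g_u = np.bincount(codes, weights=y - mu, minlength=q) - u * inv_s2
            gnorm = np.sqrt(np.sum(g_beta**2) + np.sum(g_u**2))
            return beta, u, eta, mu, gnorm < 1e-4 * (1.0 + np.sum(y))
        dev_prev = dev
    return beta, u, eta, mu, False


def _laplace_loglik(
    y, X, codes, q, offset, sigma2, beta0, u0
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, np.ndarray, bool]:
    beta, u, eta, mu, ok = _pirls(y, X, codes, q, offset, sigma2, beta0, u0)
    d = np.bincount(codes, weights=mu, minlength=q)
    # log det of the u-block Hessian after profiling beta is approximated by
    # the (diagonal) Z'WZ + I/sigma2 term, as in the standard Laplace GLMM
    logdet = np.sum(np.log(d * sigma2 + 1.0))
    ll = (
        np.sum(y * eta - mu - gammaln(y + 1.0))
        - 0.5 * np.sum(u**2) / sigma2
        - 0.5 * logdet
    )
    return float(ll), beta, u, eta, mu, ok


def fit_poisson_glmm(
    y: np.ndarray,
    X: np.ndarray,
    groups: pd.Series | np.ndarray,
    offset: np.ndarray | None = None,
    coef_names: list[str] | None = None,
    log_sigma2_bounds: tuple[float, float] = (-12.0, 4.0),
    tol: float = 1e-8,
) -> PoissonGLMMResult:
    """Fit the Poisson GLMM by Laplace approximation.

    Parameters
    ----------
    y : counts (non-negative integers).
    X : fixed-effect design matrix, including the intercept column.
    groups : group label per observation (the random-intercept factor).
    offset : known log-exposure term, default zeros.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = len(y)
    if offset is None:
        offset = np.zeros(n)
    offset = np.asarray(offset, dtype=float)
    groups = pd.Series(np.asarray(groups))
    levels, codes = np.unique(groups.to_numpy(), return_inverse=True)
    q = len(levels)
    if coef_names is None:
        coef_names = [f"x{j}" for j in range(X.shape[1])]

    beta0 = np.zeros(X.shape[1])
    # crude start: intercept at log mean rate
    rate = max(np.mean(y) / max(np.mean(np.exp(offset)), 1e-12), 1e-8)
    beta0[0] = np.log(rate)
    u0 = np.zeros(q)

    state: dict = {}

    def negll(log_s2: float) -> float:
        s2 = np.exp(log_s2)
        b0 = state.get("beta", beta0)
        v0 = state.get("u", u0)
        ll, beta, u, eta, mu, ok = _laplace_loglik(
            y, X, codes, q, offset, s2, b0, v0
        )
        state.update(beta=beta, u=u)
        return -ll

    res = minimize_scalar(
        negll, bounds=log_sigma2_bounds, method="bounded",
        options={"xatol": tol ** 0.5},
    )
    sigma2 = float(np.exp(res.x))
    # treat an optimum pinned at the lower bound as sigma2 -> 0
    if res.x <= log_sigma2_bounds[0] + 1e-6:
        sigma2 = np.exp(log_sigma2_bounds[0])
    ll, beta, u, eta, mu, ok = _laplace_loglik(
        y, X, codes, q, offset, sigma2, state.get("beta", beta0),
        state.get("u", u0),
    )
    if not ok:
        raise GLMMConvergenceError(
            "PIRLS did not converge at the selected variance; "
            f"sigma2={sigma2:.3g}"
        )
    blups = pd.Series(u, index=levels, name="blup")
    report_sigma2 = 0.0 if res.x <= log_sigma2_bounds[0] + 1e-6 else sigma2
    return PoissonGLMMResult(
        beta=beta,
        coef_names=list(coef_names),
        blups=blups,
        sigma2_group=report_sigma2,
        loglik=float(ll),
        eta=eta,
        mu=mu,
        offset=offset,
        X=X,
        converged=bool(ok),
        n_obs=n,
    )
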