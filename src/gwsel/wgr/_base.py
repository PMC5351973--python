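"""Shared machinery for kernel/marker mixed models.

The linear models here all reduce to

    y = X b + u + e,    u ~ N(0, K sigma_u^2),   e ~ N(0, I sigma_e^2),

with K a positive semidefinite kernel (marker cross-products, a VanRaden G,
or an RKHS Gaussian kernel).  Variance components are estimated by spectral
REML: after projecting out the fixed effects, the restricted likelihood is a
function of the single ratio delta = sigma_e^2 / sigma_u^2 through the
eigenvalues of the projected kernel, so the fit is a 1-D optimization plus
one eigendecomposition (the same profiling used by rrBLUP's ``mixed.solve``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.linalg import eigh, qr

from ..io import MarkerMatrix


def as_dose_matrix(X):
    """Accept a MarkerMatrix or an array of allele doses; return (doses, ids).

    Dominant markers in a MarkerMatrix are expanded to {0, 2} dose
    equivalents; a plain array is taken to be dose-coded already.
    """
    if isinstance(X, MarkerMatrix):
        return X.doses(), list(X.marker_ids)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("genotype input must be 2-D")
    return arr, None


def align_markers(doses, marker_ids, train_ids):
    """Reorder columns of ``doses`` to match the training marker order."""
    if marker_ids is None or train_ids is None:
        if doses.shape[1] != (len(train_ids) if train_ids else doses.shape[1]):
            raise ValueError("marker count mismatch and no ids to align by")
        return doses
    pos = {m: i for i, m in enumerate(marker_ids)}
    missing = [m for m in train_ids if m not in pos]
    if missing:
        raise ValueError(f"markers absent from new genotypes: {missing[:10]}")
    idx = [pos[m] for m in train_ids]
    return doses[:, idx]


@dataclass
class KernelFit:
    """Result of a spectral-REML kernel mixed-model fit."""

    beta_fixed: np.ndarray              # GLS fixed-effect solution
    mu: float                           # first fixed effect (intercept)
    sigma2_u: float
    sigma2_e: float
    delta: float                        # sigma_e^2 / sigma_u^2
    loglik: float                       # restricted log-likelihood (up to const)
    u_hat: np.ndarray                   # BLUP for every individual (n,)
    alpha: np.ndarray                   # (K_oo + delta I)^-1 (y_o - X_o b), obs scale
    observed: np.ndarray                # boolean mask of phenotyped individuals


def _reml_delta(theta, eta2, n_minus_p, log10_bounds=(-8.0, 10.0)):
    """Profile REML criterion over delta on the projected spectrum."""

    def crit(log10_delta):
        delta = 10.0 ** log10_delta
        denom = theta + delta
        s = np.sum(eta2 / denom)
        return np.sum(np.log(denom)) + n_minus_p * np.log(s)

    def dcrit(log10_delta):
        # derivative of crit with respect to delta (not log-delta): the root
        # localizes the optimum far more sharply than comparing flat
        # criterion values near the minimum
        delta = 10.0 ** log10_delta
        denom = theta + delta
        s0 = np.sum(eta2 / denom)
        s1 = np.sum(eta2 / denom ** 2)
        return np.sum(1.0 / denom) - n_minus_p * s1 / s0

    grid = np.linspace(log10_bounds[0], log10_bounds[1], 73)
    vals = [crit(g) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    best = None
    if dcrit(lo) < 0 < dcrit(hi):
        best = optimize.brentq(dcrit, lo, hi, xtol=1e-14, rtol=8.9e-16)
    if best is None or crit(best) > vals[i]:
        res = optimize.minimize_scalar(
            crit, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-12},
        )
        best = res.x if res.fun <= vals[i] else grid[i]
    # profile criterion (up to additive constants) at the optimum
    return 10.0 ** best, -0.5 * crit(best)


def solve_kernel_model(K, y, X=None, delta=None, var_components=None) -> KernelFit:
    """Fit the kernel mixed model, allowing missing y (test individuals).

    Parameters
    ----------
    K : (n, n) PSD kernel over *all* individuals.
    y : (n,) phenotype vector; NaN marks individuals to predict.
    X : (n, p) fixed-effect design; default a column of ones.
    delta : fix the variance ratio instead of estimating it by REML.
    var_components : (sigma2_u, sigma2_e) to fix both scales.
    """
    K = np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float)
    n_all = y.shape[0]
    if K.shape != (n_all, n_all):
        raise ValueError("kernel shape inconsistent with phenotype length")
    if X is None:
        X = np.ones((n_all, 1))
    obs = np.isfinite(y)
    if obs.sum() < 3:
        raise ValueError("need at least 3 phenotyped individuals")
    Ko = K[np.ix_(obs, obs)]
    Xo = X[obs]
    yo = y[obs]
    n, p = Xo.shape

    if np.var(yo) < 1e-14:
        # degenerate constant response: return a valid null fit
        beta = np.zeros(p)
        beta[0] = yo.mean()
        return KernelFit(beta, beta[0], 0.0, 0.0, np.inf, 0.0,
                         np.zeros(n_all), np.zeros(n), obs)

    if var_components is not None:
        s2u, s2e = var_components
        delta = s2e / s2u

    if delta is None:
        # project out fixed effects with an orthonormal null-space basis
        Q, _ = qr(Xo, mode="full")
        Q2 = Q[:, p:]
        theta, V = eigh(Q2.T @ Ko @ Q2)
        theta = np.clip(theta, 0.0, None)
        eta = V.T @ (Q2.T @ yo)
        delta, loglik = _reml_delta(theta, eta ** 2, n - p)
        sigma2_u = float(np.sum(eta ** 2 / (theta + delta)) / (n - p))
        sigma2_e = delta * sigma2_u
    else:
        sigma2_u = var_components[0] if var_components is not None else np.nan
        sigma2_e = var_components[1] if var_components is not None else np.nan
        loglik = np.nan

    # GLS fixed effects and BLUP through the eigendecomposition of Ko
    w, U = eigh(Ko)
    w = np.clip(w, 0.0, None)
    dinv = 1.0 / (w + delta)
    Ut_y = U.T @ yo
    Ut_X = U.T @ Xo
    XtViX = Ut_X.T @ (dinv[:, None] * Ut_X)
    XtViy = Ut_X.T @ (dinv * Ut_y)
    beta = np.linalg.solve(XtViX, XtViy)
    resid = yo - Xo @ beta
    alpha = U @ (dinv * (U.T @ resid))
    u_hat = np.empty(n_all)
    u_hat[obs] = Ko @ alpha
    if (~obs).any():
        u_hat[~obs] = K[np.ix_(~obs, obs)] @ alpha
    if var_components is None and delta is not None and not np.isfinite(loglik):
        loglik = np.nan
    if np.isnan(sigma2_u):
        # delta fixed without explicit scales: profile sigma2_u given delta
        sigma2_u = float(resid @ alpha / (n - p))
        sigma2_e = delta * sigma2_u
    return KernelFit(beta, float(beta[0]), float(sigma2_u), float(sigma2_e),
                     float(delta), float(loglik) if np.isfinite(loglik) else np.nan,
                     u_hat, alpha, obs)
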