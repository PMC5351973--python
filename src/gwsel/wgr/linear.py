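"""Closed-form whole-genome regressions: RR-BLUP, G-BLUP and RKHS.

All three are scikit-learn-style estimators: ``fit(X, y)`` with X a dose
matrix (or :class:`~gwsel.io.MarkerMatrix`), ``predict(X)`` returning
intercept + genetic value, and fitted attributes with trailing underscores.
``y`` may contain NaN for individuals to be predicted (the genomic-selection
validation set): they contribute genotypes, never phenotypes.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator, RegressorMixin

from ..relmat import RelationshipMatrix
from ._base import KernelFit, align_markers, as_dose_matrix, solve_kernel_model


class _DoseModel(BaseEstimator, RegressorMixin):
    """Common plumbing: training-frequency centering and marker alignment."""

    def _ingest(self, X, y):
        doses, marker_ids = as_dose_matrix(X)
        y = np.asarray(y, dtype=float)
        if len(y) != doses.shape[0]:
            raise ValueError("phenotype length does not match genotype rows")
        obs = np.isfinite(y)
        p = doses[obs].mean(axis=0) / 2.0
        self.freqs_ = p
        self.marker_ids_ = marker_ids
        self.denom_ = 2.0 * float(np.sum(p * (1.0 - p)))
        return doses - 2.0 * p, y, obs

    def _new_centered(self, X):
        doses, marker_ids = as_dose_matrix(X)
        doses = align_markers(doses, marker_ids, self.marker_ids_)
        if doses.shape[1] != len(self.freqs_):
            raise ValueError(
                f"expected {len(self.freqs_)} markers, got {doses.shape[1]}"
            )
        return doses - 2.0 * self.freqs_


class RRBLUP(_DoseModel):
    """Ridge-regression BLUP of marker effects.

    Every marker gets the same effect variance sigma_beta^2 (the classic
    V_G/M assumption); the shrinkage ratio lambda = sigma_e^2/sigma_beta^2 is
    estimated by spectral REML on the marker model unless fixed via
    ``lambda_`` or ``var_components``.  Marker effects solve the penalized
    normal equations (Z'Z + lambda I) beta = Z'(y - mu).
    """

    def __init__(self, lambda_=None, var_components=None):
        self.lambda_ = lambda_
        self.var_components = var_components

    def fit(self, X, y):
        Zc, y, obs = self._ingest(X, y)
        Zo = Zc[obs]
        K = Zo @ Zo.T
        kf = solve_kernel_model(
            K, y[obs], delta=self.lambda_, var_components=self.var_components
        )
        self.mu_ = kf.mu
        self.sigma2_beta_ = kf.sigma2_u
        self.sigma2_e_ = kf.sigma2_e
        self.delta_ = kf.delta
        self.loglik_ = kf.loglik
        if np.isfinite(kf.delta) and Zo.shape[1] <= 4000:
            # primal (marker-space) solve of the penalized normal equations
            A = Zo.T @ Zo
            A[np.diag_indices_from(A)] += kf.delta
            c, low = cho_factor(A)
            self.beta_ = cho_solve((c, low), Zo.T @ (y[obs] - self.mu_))
        elif np.isfinite(kf.delta):
            self.beta_ = Zo.T @ kf.alpha          # dual route for very wide panels
        else:
            self.beta_ = np.zeros(Zo.shape[1])    # constant y: no signal
        self.gebv_ = Zc @ self.beta_
        sigma2_g = self.sigma2_beta_ * self.denom_
        tot = sigma2_g + self.sigma2_e_
        self.sigma2_g_ = sigma2_g
        self.h2_ = sigma2_g / tot if tot > 0 else 0.0
        return self

    def predict_gebv(self, X):
        return self._new_centered(X) @ self.beta_

    def predict(self, X):
        return self.mu_ + self.predict_gebv(X)


class GBLUP(_DoseModel):
    """Genomic BLUP through the VanRaden relationship matrix.

    ``fit(X, y)`` builds G = ZZ'/(2*sum p q) from the dose matrix (allele
    frequencies taken from the phenotyped individuals only) and solves the
    animal-model mixed-model equations in spectral form; individuals with
    missing phenotypes get GEBVs through the off-diagonal block of G.  Pass
    ``kernel="precomputed"`` to supply G (or any PSD kernel) directly.
    """

    def __init__(self, kernel="vanraden", var_components=None):
        self.kernel = kernel
        self.var_components = var_components

    def fit(self, X, y):
        if self.kernel == "precomputed":
            if isinstance(X, RelationshipMatrix):
                K = X.values
            else:
                K = np.asarray(X, dtype=float)
            y = np.asarray(y, dtype=float)
            self.freqs_ = None
            self.marker_ids_ = None
            self.denom_ = None
            self._Ztrain = None
        else:
            Zc, y, _ = self._ingest(X, y)
            if self.denom_ <= 0:
                raise ZeroDivisionError("monomorphic panel: VanRaden denominator 0")
            K = (Zc @ Zc.T) / self.denom_
            self._Ztrain = Zc
        kf = solve_kernel_model(K, y, var_components=self.var_components)
        self._finish(kf, K)
        return self

    def _finish(self, kf: KernelFit, K):
        self.mu_ = kf.mu
        self.sigma2_g_ = kf.sigma2_u
        self.sigma2_e_ = kf.sigma2_e
        self.delta_ = kf.delta
        self.loglik_ = kf.loglik
        self.gebv_ = kf.u_hat
        self.alpha_ = kf.alpha
        self.observed_ = kf.observed
        self.K_ = K
        tot = self.sigma2_g_ + self.sigma2_e_
        self.h2_ = self.sigma2_g_ / tot if tot > 0 else 0.0

    def predict_gebv(self, X):
        if self.kernel == "precomputed":
            raise ValueError(
                "precomputed-kernel G-BLUP predicts only individuals inside the "
                "supplied kernel (use NaN phenotypes at fit time)"
            )
        Zc_new = self._new_centered(X)
        K_cross = (Zc_new @ self._Ztrain[self.observed_].T) / self.denom_
        return K_cross @ self.alpha_

    def predict(self, X):
        return self.mu_ + self.predict_gebv(X)


class RKHS(_DoseModel):
    """Reproducing-kernel Hilbert-space regression with a Gaussian kernel.

    Genetic values are a Gaussian process with covariance proportional to
    K_ij = exp(-h * d_ij^2 / median(d^2)), where d_ij is the Euclidean
    distance between marker-dose vectors and the median is over the
    phenotyped individuals (the bandwidth ``h`` then acts on a scale-free
    quantity).  Fitting reuses the G-BLUP machinery with K in place of G.
    """

    def __init__(self, bandwidth=1.0, var_components=None):
        self.bandwidth = bandwidth
        self.var_components = var_components

    @staticmethod
    def _sqdist(A, B):
        aa = np.sum(A ** 2, axis=1)[:, None]
        bb = np.sum(B ** 2, axis=1)[None, :]
        return np.maximum(aa + bb - 2.0 * A @ B.T, 0.0)

    def fit(self, X, y):
        if self.bandwidth <= 0:
            raise ValueError("RKHS bandwidth must be > 0")
        doses, marker_ids = as_dose_matrix(X)
        y = np.asarray(y, dtype=float)
        obs = np.isfinite(y)
        self.marker_ids_ = marker_ids
        self._train_doses = doses
        D2 = self._sqdist(doses, doses)
        off = D2[np.ix_(obs, obs)][~np.eye(int(obs.sum()), dtype=bool)]
        med = float(np.median(off))
        self.median_d2_ = med if med > 0 else 1.0
        K = np.exp(-self.bandwidth * D2 / self.median_d2_)
        kf = solve_kernel_model(K, y, var_components=self.var_components)
        self.mu_ = kf.mu
        self.sigma2_g_ = kf.sigma2_u
        self.sigma2_e_ = kf.sigma2_e
        self.delta_ = kf.delta
        self.loglik_ = kf.loglik
        self.gebv_ = kf.u_hat
        self.alpha_ = kf.alpha
        self.observed_ = kf.observed
        self.K_ = K
        tot = self.sigma2_g_ + self.sigma2_e_
        self.h2_ = self.sigma2_g_ / tot if tot > 0 else 0.0
        return self

    def predict_gebv(self, X):
        doses, marker_ids = as_dose_matrix(X)
        doses = align_markers(doses, marker_ids, self.marker_ids_)
        D2 = self._sqdist(doses, self._train_doses[self.observed_])
        K_cross = np.exp(-self.bandwidth * D2 / self.median_d2_)
        return K_cross @ self.alpha_

    def predict(self, X):
        return self.mu_ + self.predict_gebv(X)


def backsolve_marker_effects(fit: GBLUP, geno=None) -> np.ndarray:
    """RR-BLUP-consistent marker effects behind a fitted G-BLUP.

    With G = ZZ'/c the unique decomposition of the GEBVs into marker effects
    is beta = Z' G^{-1} gebv / c, which for a VanRaden fit collapses to
    beta = Z' alpha / c using the stored mixed-model solution.  For
    precomputed-kernel fits pass the genotypes to rebuild Z (the solve is
    ridge-stabilized if G is singular).
    """
    if getattr(fit, "_Ztrain", None) is not None:
        Zo = fit._Ztrain[fit.observed_]
        return (Zo.T @ fit.alpha_) / fit.denom_
    if geno is None:
        raise ValueError("precomputed-kernel fit: genotypes required to backsolve")
    doses, _ = as_dose_matrix(geno)
    p = doses[fit.observed_].mean(axis=0) / 2.0
    Zc = doses - 2.0 * p
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    G = fit.K_[np.ix_(fit.observed_, fit.observed_)].copy()
    G[np.diag_indices_from(G)] += 1e-8 * np.trace(G) / G.shape[0]
    c, low = cho_factor(G)
    sol = cho_solve((c, low), fit.gebv_[fit.observed_])
    return (Zc[fit.observed_].T @ sol) / denom
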