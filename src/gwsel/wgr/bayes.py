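"""Bayesian whole-genome regression estimators (the "Bayesian alphabet").

Five hierarchical priors on marker effects, all sampled by single-site
Gibbs (see :mod:`._gibbs`):

* :class:`BRR` — Bayesian ridge: one common effect variance, scaled-inv-chi2.
* :class:`BayesA` — one variance per marker, scaled-inv-chi2.
* :class:`BayesB` — spike-and-slab with per-marker slab variances and the
  zero-proportion ``pi`` estimated from the data (Beta(1,1) prior).
* :class:`BayesCpi` — spike-and-slab with a common slab variance and
  estimated ``pi``.
* :class:`BLASSO` — Bayesian LASSO: double-exponential shrinkage via
  marker-specific tau_j^2 and a Gamma-distributed lambda^2.

``pi`` throughout is the probability that a marker has zero effect.

Hyperprior scales default to the prior-R2 heuristic (a scaled-inv-chi2 mode
matching 50% of the phenotypic variance assigned to markers, nu = 4), except
BLASSO's residual prior which defaults to scale 1 with 4 degrees of freedom.
The default chain is 20,000 burn-in + 40,000 iterations thinned by 10; tests
and cross-validation loops pass much shorter chains explicitly.
"""

from __future__ import annotations

import numpy as np

from . import _gibbs
from ._gibbs import run_gibbs
from .linear import _DoseModel

DEFAULT_CHAIN = (20000, 40000, 10)


class _GibbsWGR(_DoseModel):
    """Shared fit machinery for the Gibbs-sampled marker models."""

    _method = None

    def __init__(self, chain=DEFAULT_CHAIN, seed=0, prior_r2=0.5,
                 nu_b=4.0, nu_e=4.0, S_b=None, S_e=None,
                 pi_init=0.5, estimate_pi=True,
                 var_components=None, lambda2=None,
                 bl_shape=1.1, bl_rate=None, save_beta_samples=False):
        self.chain = chain
        self.seed = seed
        self.prior_r2 = prior_r2
        self.nu_b = nu_b
        self.nu_e = nu_e
        self.S_b = S_b
        self.S_e = S_e
        self.pi_init = pi_init
        self.estimate_pi = estimate_pi
        self.var_components = var_components   # (sigma2_beta, sigma2_e) fixed
        self.lambda2 = lambda2                 # fix BLASSO lambda^2
        self.bl_shape = bl_shape
        self.bl_rate = bl_rate
        self.save_beta_samples = save_beta_samples

    def _hyper(self, y, Zc):
        vary = float(np.var(y, ddof=1))
        # total marker variance sum_j var(z_j): links sigma2_beta to genetic variance
        sum_var = max(float(np.sum(Zc ** 2) / max(len(y), 1)), 1e-12)
        r2 = self.prior_r2
        # scaled-inv-chi2 with mode v: S = v (nu + 2) / nu
        S_e = self.S_e
        if S_e is None:
            S_e = vary * (1 - r2) * (self.nu_e + 2) / self.nu_e
        S_b = self.S_b
        if S_b is None:
            slab_frac = 1.0 - self.pi_init if self._method in (
                _gibbs.BAYES_B, _gibbs.BAYES_CPI) else 1.0
            S_b = vary * r2 / max(sum_var * slab_frac, 1e-12) \
                * (self.nu_b + 2) / self.nu_b
        lambda2_init = self.lambda2
        if lambda2_init is None:
            lambda2_init = 2.0 * sum_var * (1 - r2) / max(r2, 1e-12)
        bl_rate = self.bl_rate
        if bl_rate is None:
            bl_rate = (self.bl_shape - 1.0) / max(lambda2_init, 1e-12)
        fix = self.var_components is not None
        return {
            "S_e": S_e, "nu_e": self.nu_e, "S_b": S_b, "nu_b": self.nu_b,
            "pi_init": self.pi_init, "estimate_pi": self.estimate_pi,
            "fix_variances": fix,
            "s2b_fix": self.var_components[0] if fix else 0.0,
            "s2e_fix": self.var_components[1] if fix else 0.0,
            "bl_shape": self.bl_shape, "bl_rate": bl_rate,
            "lambda2_init": lambda2_init,
            "fix_lambda": self.lambda2 is not None,
        }

    def fit(self, X, y):
        Zc, y, obs = self._ingest(X, y)
        Zo = Zc[obs]
        yo = y[obs]
        hyper = self._hyper(yo, Zo)
        if self.var_components is not None:
            hyper["s2b_fix"], hyper["s2e_fix"] = self.var_components
        res = run_gibbs(yo, Zo, self._method, self.chain, self.seed, hyper,
                        save_beta=self.save_beta_samples)
        self.mu_ = float(res["mu_samples"].mean())
        self.beta_ = res["beta_mean"]
        self.beta_sd_ = res["beta_sd"]
        self.gebv_ = Zc @ self.beta_
        self.sigma2_e_ = float(res["sigma2_e_samples"].mean())
        self.sigma2_g_ = float(res["varg_samples"].mean())
        h2_draws = res["varg_samples"] / (
            res["varg_samples"] + res["sigma2_e_samples"]
        )
        self.h2_ = float(h2_draws.mean())
        self.pi_ = float(res["pi_samples"].mean())
        if self._method == _gibbs.BLASSO:
            self.lambda2_ = float(res["hyper_samples"].mean())
        else:
            self.sigma2_beta_ = float(res["hyper_samples"].mean())
        self.samples_ = {
            "mu": res["mu_samples"],
            "sigma2_e": res["sigma2_e_samples"],
            "varg": res["varg_samples"],
            "pi": res["pi_samples"],
            "hyper": res["hyper_samples"],
        }
        if self.save_beta_samples:
            self.samples_["beta"] = res["beta_samples"]
        self.convergence_flag_ = self._split_chain_flag(res)
        return self

    @staticmethod
    def _split_chain_flag(res, threshold=0.2):
        """Report-only diagnostic: relative drift of variance-parameter means
        between the two halves of the saved chain."""
        flags = {}
        for name in ("sigma2_e_samples", "varg_samples"):
            s = res[name]
            if len(s) < 4:
                flags[name] = False
                continue
            half = len(s) // 2
            a, b = s[:half].mean(), s[half:].mean()
            scale = max(abs(a) + abs(b), 1e-300)
            flags[name] = abs(a - b) / (0.5 * scale) > threshold
        return any(flags.values())

    def predict_gebv(self, X):
        return self._new_centered(X) @ self.beta_

    def predict(self, X):
        return self.mu_ + self.predict_gebv(X)


class BRR(_GibbsWGR):
    """Bayesian ridge regression: common marker variance V_G/M."""

    _method = _gibbs.BRR


class BayesA(_GibbsWGR):
    """Per-marker effect variances with scaled-inverse-chi-square priors."""

    _method = _gibbs.BAYES_A


class BayesB(_GibbsWGR):
    """Spike-and-slab with per-marker slab variances; pi estimated."""

    _method = _gibbs.BAYES_B


class BayesCpi(_GibbsWGR):
    """Spike-and-slab with a common slab variance; pi estimated jointly."""

    _method = _gibbs.BAYES_CPI


class BLASSO(_GibbsWGR):
    """Bayesian LASSO (double-exponential marker shrinkage)."""

    _method = _gibbs.BLASSO

    def __init__(self, chain=DEFAULT_CHAIN, seed=0, prior_r2=0.5,
                 nu_b=4.0, nu_e=4.0, S_b=None, S_e=1.0,
                 pi_init=0.5, estimate_pi=True,
                 var_components=None, lambda2=None,
                 bl_shape=1.1, bl_rate=None, save_beta_samples=False):
        super().__init__(chain=chain, seed=seed, prior_r2=prior_r2,
                         nu_b=nu_b, nu_e=nu_e, S_b=S_b, S_e=S_e,
                         pi_init=pi_init, estimate_pi=estimate_pi,
                         var_components=var_components, lambda2=lambda2,
                         bl_shape=bl_shape, bl_rate=bl_rate,
                         save_beta_samples=save_beta_samples)
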