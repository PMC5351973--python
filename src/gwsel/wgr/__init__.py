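"""Whole-genome regression models for genomic selection.

Eight methods share a common estimator interface (``fit(X, y)`` /
``predict(X)`` / ``predict_gebv(X)``, scikit-learn conventions):

====================  =============================================
name                  estimator
====================  =============================================
``rrblup``            :class:`~gwsel.wgr.linear.RRBLUP`
``gblup``             :class:`~gwsel.wgr.linear.GBLUP`
``brr``               :class:`~gwsel.wgr.bayes.BRR`
``bayesA``            :class:`~gwsel.wgr.bayes.BayesA`
``bayesB``            :class:`~gwsel.wgr.bayes.BayesB`
``bayesCpi``          :class:`~gwsel.wgr.bayes.BayesCpi`
``blasso``            :class:`~gwsel.wgr.bayes.BLASSO`
``rkhs``              :class:`~gwsel.wgr.linear.RKHS`
====================  =============================================

The module-level ``fit_*`` functions are thin wrappers kept for script use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .bayes import BLASSO, BRR, BayesA, BayesB, BayesCpi
from .linear import GBLUP, RKHS, RRBLUP, backsolve_marker_effects

METHODS = ("rrblup", "gblup", "brr", "bayesA", "bayesB", "bayesCpi",
           "blasso", "rkhs")

# figure-legend style two-letter codes, in display order
METHOD_CODES = {
    "bayesA": "BA", "bayesB": "BB", "bayesCpi": "BC", "brr": "BR",
    "blasso": "BL", "gblup": "GB", "rkhs": "RK", "rrblup": "RB",
}

_BAYESIAN = {"brr": BRR, "bayesA": BayesA, "bayesB": BayesB,
             "bayesCpi": BayesCpi, "blasso": BLASSO}


@dataclass
class WGRSpec:
    """Declarative description of one whole-genome regression run."""

    method: str = "gblup"
    chain: tuple = (20000, 40000, 10)      # burn-in, saved iterations, thin
    hyper: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        burn, n_iter, thin = self.chain
        if burn < 0 or n_iter <= 0 or thin < 1:
            raise ValueError("chain lengths must be positive and thin >= 1")


def make_model(spec: WGRSpec):
    """Instantiate the estimator described by a :class:`WGRSpec`."""
    if spec.method == "rrblup":
        return RRBLUP(**spec.hyper)
    if spec.method == "gblup":
        return GBLUP(**spec.hyper)
    if spec.method == "rkhs":
        return RKHS(**spec.hyper)
    cls = _BAYESIAN[spec.method]
    return cls(chain=spec.chain, seed=spec.seed, **spec.hyper)


def fit_model(method_or_spec, X, y):
    """Fit one model; accepts a method name or a full :class:`WGRSpec`."""
    spec = (method_or_spec if isinstance(method_or_spec, WGRSpec)
            else WGRSpec(method=method_or_spec))
    return make_model(spec).fit(X, y)


def fit_rrblup(y, geno, **kw):
    return RRBLUP(**kw).fit(geno, y)


def fit_gblup(y, G_or_geno, precomputed=False, **kw):
    kernel = "precomputed" if precomputed else "vanraden"
    return GBLUP(kernel=kernel, **kw).fit(G_or_geno, y)


def fit_bayesian(y, geno, spec: WGRSpec):
    if spec.method not in _BAYESIAN:
        raise ValueError(f"{spec.method!r} is not a Bayesian-alphabet method")
    return make_model(spec).fit(geno, y)


def fit_rkhs(y, geno, **kw):
    return RKHS(**kw).fit(geno, y)


def predict_gebv(fit, geno_new):
    """Genetic values for new genotypes from any fitted model."""
    return fit.predict_gebv(geno_new)


__all__ = [
    "RRBLUP", "GBLUP", "RKHS", "BRR", "BayesA", "BayesB", "BayesCpi",
    "BLASSO", "WGRSpec", "METHODS", "METHOD_CODES", "make_model",
    "fit_model", "fit_rrblup", "fit_gblup", "fit_bayesian", "fit_rkhs",
    "predict_gebv", "backsolve_marker_effects",
]
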