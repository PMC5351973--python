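"""EM-REML variance components for the two trial designs, plus the derived
genetic parameters.

Models
------
Germplasm bank (randomized complete blocks)::

    y = X r + Z a + W p + e

Diallel (adds a full-sib family / dominance term)::

    y = X r + Z a + W p + T f + e

with r fixed block effects, a random additive genotype effects (identity or
genomic-relationship covariance), p the random block-by-genotype (plot)
interaction, f random family effects, and e the residual.  When every plot
cell holds at most one observation, p is confounded with e and is dropped
with a warning.

Two estimators are provided.  The default is EM-REML (Henderson's iterative
mixed-model-equation updates): robust at the very small sample sizes these
trials have, guaranteed to keep components nonnegative, and with a
monotonically non-decreasing restricted likelihood.  The unconstrained
alternative maximizes the restricted likelihood directly over the components
with no sign constraint (for balanced designs this coincides with the
ANOVA estimator); it exists because subtraction-style estimation can drive
the residual negative — and heritability above 1 — when the genetic variance
is large and n is small, a pathology worth reproducing rather than hiding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, cholesky, eigh

from .io import PhenotypeTable, ValidationError
from .relmat import RelationshipMatrix

logger = logging.getLogger("gwsel")


class ConvergenceError(RuntimeError):
    """REML failed to converge; carries the iteration trajectory."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


@dataclass
class MixedModelSpec:
    """Which trial model to assemble."""

    design: str = "germplasm"           # {germplasm, diallel}
    use_grm: bool = False
    drop_unidentifiable: bool = True
    # Falconer half-sib conversion: when the genotype term indexes half-sib
    # families (open-pollinated accessions), the additive variance on the
    # individual scale is 4x the between-family component.  The phenotypic
    # variance stays the sum of the *fitted* (observational) components, so
    # with plot-mean records and a small residual the reported heritability
    # sigma2_a / sigma2_p can exceed 1 — the classic small-n pathology of
    # subtraction-style estimation.
    additive_multiplier: float = 1.0

    def __post_init__(self):
        if self.design not in ("germplasm", "diallel"):
            raise ValidationError(f"unknown design: {self.design!r}")
        if self.additive_multiplier <= 0:
            raise ValidationError("additive_multiplier must be positive")


@dataclass
class ModelData:
    """Assembled mixed model: response, fixed design, random terms."""

    y: np.ndarray
    X: np.ndarray                       # fixed blocks, one column per level
    terms: dict                         # name -> (Z, L) with A = L L' (L=None: identity)
    levels: dict                        # name -> level labels
    block_levels: list
    trait: str
    design: str
    additive_multiplier: float = 1.0

    @property
    def n(self):
        return len(self.y)


def build_design(pheno: PhenotypeTable, trait: str, spec: MixedModelSpec,
                 grm: RelationshipMatrix = None) -> ModelData:
    """Assemble X (blocks), Z (genotypes), W (plots) and T (families)."""
    df = pheno.subset(experiment=spec.design, trait=trait).data
    if df.empty:
        raise ValidationError(f"no records for {spec.design}/{trait}")
    if df["block"].isna().any():
        raise ValidationError("records without a block assignment")
    y = df["value"].to_numpy(dtype=float)
    n = len(y)

    def incidence(labels):
        levels = list(pd.unique(labels))
        index = {l: i for i, l in enumerate(levels)}
        Z = np.zeros((n, len(levels)))
        Z[np.arange(n), [index[l] for l in labels]] = 1.0
        return Z, levels

    X, block_levels = incidence(df["block"])
    Za, geno_levels = incidence(df["plant_id"])
    terms, levels = {}, {}

    La = None
    if spec.use_grm:
        if grm is None:
            raise ValidationError("use_grm=True requires a relationship matrix")
        pos = {p: i for i, p in enumerate(grm.plant_ids)}
        missing = [g for g in geno_levels if g not in pos]
        if missing:
            raise ValidationError(f"genotypes absent from GRM: {missing[:5]}")
        idx = [pos[g] for g in geno_levels]
        A = grm.values[np.ix_(idx, idx)]
        La = cholesky(A + 1e-8 * np.eye(len(idx)), lower=True)
    terms["additive"] = (Za, La)
    levels["additive"] = geno_levels

    plot_labels = df["block"].astype(str) + ":" + df["plant_id"].astype(str)
    counts = plot_labels.value_counts()
    if counts.max() > 1 or not spec.drop_unidentifiable:
        Wp, plot_levels = incidence(plot_labels)
        terms["plot"] = (Wp, None)
        levels["plot"] = plot_levels
    else:
        logger.warning(
            "block x genotype term dropped: one observation per plot cell "
            "(confounded with the residual)"
        )

    if spec.design == "diallel":
        Tf, fam_levels = incidence(df["family"])
        if len(fam_levels) < 2:
            raise ValidationError("diallel model needs >= 2 families")
        terms["family"] = (Tf, None)
        levels["family"] = fam_levels

    for name, (Z, _) in terms.items():
        if Z.shape[1] < 2:
            raise ValidationError(f"random term {name!r} has < 2 levels")
    return ModelData(y, X, terms, levels, block_levels, trait, spec.design,
                     spec.additive_multiplier)


@dataclass
class VarianceComponents:
    """Estimated components and the genetic parameters derived from them."""

    sigma2_a: float
    sigma2_e: float
    sigma2_f: float = np.nan            # family (diallel only)
    sigma2_b: float = np.nan            # block x genotype (plot) variance
    sigma2_p: float = np.nan            # phenotypic: sum of fitted components
    h2_a: float = np.nan
    cv_g: float = np.nan
    cv_e: float = np.nan
    cv_r: float = np.nan
    loglik: float = np.nan
    n_iter: int = 0
    converged: bool = True
    trace: pd.DataFrame = field(default=None, repr=False)

    def components(self) -> dict:
        out = {"sigma2_a": self.sigma2_a}
        if np.isfinite(self.sigma2_f):
            out["sigma2_f"] = self.sigma2_f
        if np.isfinite(self.sigma2_b):
            out["sigma2_b"] = self.sigma2_b
        out["sigma2_e"] = self.sigma2_e
        return out


_TERM_FIELD = {"additive": "sigma2_a", "plot": "sigma2_b", "family": "sigma2_f"}


def _aitken_limit(x1, x2, x3):
    """Aitken delta-squared extrapolation of a (near-)geometric sequence.

    EM components heading for the zero boundary decay harmonically (a 1/t
    crawl that never reaches it); the extrapolated limit identifies them so
    they can be pinned at zero instead of stalling the iteration.
    """
    d1, d2 = x2 - x1, x3 - x2
    denom = d2 - d1
    if denom == 0.0:
        return x3
    return x3 - d2 * d2 / denom


def _pack(model, comps, sigma2_e, loglik, n_iter, converged, trace):
    vc = VarianceComponents(sigma2_a=np.nan, sigma2_e=sigma2_e,
                            loglik=loglik, n_iter=n_iter, converged=converged,
                            trace=trace)
    for name, val in comps.items():
        setattr(vc, _TERM_FIELD[name], val)
    # sigma2_p is the sum of the fitted (observational) components; sigma2_a
    # may sit on the individual additive scale via the half-sib conversion
    vc.sigma2_p = float(sum(comps.values()) + sigma2_e)
    vc.sigma2_a = model.additive_multiplier * vc.sigma2_a
    vc.h2_a = vc.sigma2_a / vc.sigma2_p if vc.sigma2_p != 0 else np.nan
    return vc


def _em_reml(model: ModelData, tol, max_iter):
    """Henderson EM-REML on the mixed-model equations (monotone, >= 0)."""
    y, X = model.y, model.X
    n, p = X.shape
    names = list(model.terms)
    Zs = []
    for name in names:
        Z, L = model.terms[name]
        Zs.append(Z @ L if L is not None else Z)
    qs = [Z.shape[1] for Z in Zs]
    W = np.hstack([X] + Zs)
    WtW = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)
    # block index ranges of each random term inside the MME
    offsets = p + np.concatenate([[0], np.cumsum(qs)[:-1]]).astype(int)
    blocks = [(int(offsets[k]), int(offsets[k] + qs[k])) for k in range(len(qs))]

    vary = float(np.var(y, ddof=1))
    floor = max(vary, 1e-12) * 1e-10
    q_tot = sum(qs)
    qs_arr = np.asarray(qs, dtype=float)

    def step(comps, s2e):
        """One EM sweep from (comps, s2e): returns updates and input loglik."""
        lam = s2e / np.maximum(comps, floor)
        M = WtW.copy()
        for k, (a, b) in enumerate(blocks):
            M[np.arange(a, b), np.arange(a, b)] += lam[k]
        c, low = cho_factor(M)
        sol = cho_solve((c, low), Wty)
        Cinv = cho_solve((c, low), np.eye(M.shape[0]))
        resid_ss = yty - 2 * sol @ Wty + sol @ WtW @ sol
        ypy = (yty - sol @ Wty) / s2e
        logdet_m = 2.0 * float(np.sum(np.log(np.diag(c))))
        loglik = -0.5 * ((n - p - q_tot) * np.log(s2e)
                         + float(np.sum(qs_arr * np.log(np.maximum(comps, floor))))
                         + logdet_m + ypy)
        new = np.empty_like(comps)
        tr_sum = 0.0
        for k, (a, b) in enumerate(blocks):
            t_hat = sol[a:b]
            tr_k = float(np.trace(Cinv[a:b, a:b]))
            new[k] = (t_hat @ t_hat + s2e * tr_k) / qs[k]
            tr_sum += lam[k] * tr_k
        s2e_new = float((resid_ss + s2e * ((p + q_tot) - tr_sum)) / n)
        return np.maximum(new, floor), max(s2e_new, floor), loglik

    comps = np.full(len(qs), vary / (len(qs) + 1))
    s2e = vary / (len(qs) + 1)
    trace_rows, history = [], []
    loglik = -np.inf
    for it in range(1, max_iter + 1):
        new, s2e_new, loglik = step(comps, s2e)
        trace_rows.append((it, *comps, s2e, loglik))
        history.append((comps.copy(), s2e))
        # guarded Aitken acceleration (see the single-term variant)
        if len(history) >= 3 and it % 5 == 0:
            h1, h2, h3 = history[-3:]
            cand_c = np.maximum(
                np.array([_aitken_limit(h1[0][k], h2[0][k], h3[0][k])
                          for k in range(len(qs))]), floor)
            cand_e = max(_aitken_limit(h1[1], h2[1], h3[1]), floor)
            cc, ce, cll = step(cand_c, cand_e)
            if cll >= loglik - 1e-10 * abs(loglik):
                new, s2e_new, loglik = cc, ce, cll
                history.clear()
        total = max(float(np.sum(comps) + s2e), floor)
        zero_tol = 1e-7 * total
        changes = [abs(s2e_new - s2e)]
        for k in range(len(qs)):
            if not (comps[k] < zero_tol and new[k] < zero_tol):
                changes.append(abs(new[k] - comps[k]))
        delta = max(changes) / total
        comps, s2e = new, s2e_new
        if delta < tol:
            break
    else:
        trace = _trace_frame(trace_rows, names)
        raise ConvergenceError(
            f"EM-REML did not converge in {max_iter} iterations", trace)
    trace = _trace_frame(trace_rows, names)
    return dict(zip(names, comps)), s2e, loglik, it, trace


def _em_reml_single(model: ModelData, tol, max_iter):
    """Spectral EM-REML for a single random term.

    Absorbing the fixed effects reduces each EM sweep to O(q^2) after one
    eigendecomposition of the absorbed cross-product, which makes the
    500-genotype recovery studies cheap.  Identical updates to
    :func:`_em_reml`, just a different factorization.
    """
    y, X = model.y, model.X
    n, p = X.shape
    (name,), = (list(model.terms),)
    Z, L = model.terms[name]
    Zt = Z @ L if L is not None else Z
    q = Zt.shape[1]

    XtX = X.T @ X
    cX, lowX = cho_factor(XtX)
    XtZ = X.T @ Zt
    Xty = X.T @ y
    S = Zt.T @ Zt - XtZ.T @ cho_solve((cX, lowX), XtZ)
    c_tilde = Zt.T @ y - XtZ.T @ cho_solve((cX, lowX), Xty)
    d, U = eigh((S + S.T) / 2.0)
    d = np.clip(d, 0.0, None)
    Uc = U.T @ c_tilde
    yty = float(y @ y)
    _, logdet_xx = np.linalg.slogdet(XtX)

    vary = float(np.var(y, ddof=1))
    floor = max(vary, 1e-12) * 1e-10

    Zty = Zt.T @ y

    def step(s2a, s2e):
        """One EM sweep from (s2a, s2e): returns updates and the input loglik."""
        lam = s2e / max(s2a, floor)
        w = 1.0 / (d + lam)
        t_hat = U @ (w * Uc)
        beta = cho_solve((cX, lowX), Xty - XtZ @ t_hat)
        resid = y - X @ beta - Zt @ t_hat
        tr_c = float(np.sum(w))
        ypy = (yty - beta @ Xty - t_hat @ Zty) / s2e
        loglik = -0.5 * ((n - p - q) * np.log(s2e) + q * np.log(max(s2a, floor))
                         + logdet_xx + float(np.sum(np.log(d + lam))) + ypy)
        s2a_new = (t_hat @ t_hat + s2e * tr_c) / q
        s2e_new = (float(resid @ resid) + s2e * ((p + q) - lam * tr_c)) / n
        return max(s2a_new, floor), max(s2e_new, floor), loglik

    s2a, s2e = vary / 2.0, vary / 2.0
    trace_rows, history = [], []
    loglik = -np.inf
    for it in range(1, max_iter + 1):
        s2a_new, s2e_new, loglik = step(s2a, s2e)
        trace_rows.append((it, s2a, s2e, loglik))
        history.append((s2a, s2e))
        # guarded Aitken acceleration: boundary-bound components decay as a
        # 1/t crawl; extrapolate and accept only if the likelihood agrees
        if len(history) >= 3 and it % 5 == 0:
            (a1, e1), (a2, e2), (a3, e3) = history[-3:]
            cand = (max(_aitken_limit(a1, a2, a3), floor),
                    max(_aitken_limit(e1, e2, e3), floor))
            ca, ce, cll = step(*cand)
            if cll >= loglik - 1e-10 * abs(loglik):
                s2a_new, s2e_new, loglik = ca, ce, cll
                history.clear()
        total = max(s2a + s2e, floor)
        zero_tol = 1e-7 * total
        delta = abs(s2e_new - s2e) / total
        if not (s2a < zero_tol and s2a_new < zero_tol):
            delta = max(delta, abs(s2a_new - s2a) / total)
        s2a, s2e = s2a_new, s2e_new
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"EM-REML did not converge in {max_iter} iterations",
            _trace_frame(trace_rows, [name]))
    return {name: float(s2a)}, float(s2e), loglik, it, _trace_frame(trace_rows, [name])


def _trace_frame(rows, names):
    cols = ["iteration"] + [_TERM_FIELD[n] for n in names] + ["sigma2_e", "loglik"]
    return pd.DataFrame(rows, columns=cols)


def _reml_nll_direct(theta, y_proj, Ms_proj):
    """-2 restricted log-likelihood at possibly-negative components.

    Works on the fixed-effect complement (y and the covariance structures
    pre-multiplied by an orthonormal null-space basis of X'), which is the
    exact restricted likelihood and — crucially — only requires the
    *projected* covariance to be positive definite, so a negative residual
    component stays feasible whenever the genetic covariance dominates the
    projected space.
    """
    m = y_proj.shape[0]
    V = theta[-1] * np.eye(m)
    for k, M in enumerate(Ms_proj):
        V += theta[k] * M
    try:
        c, low = cho_factor(V)
    except (np.linalg.LinAlgError, ValueError):
        return np.inf
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(c))))
    return logdet_v + float(y_proj @ cho_solve((c, low), y_proj))


def _direct_reml(model: ModelData, tol, max_iter):
    """Unconstrained REML by direct likelihood maximization (Nelder-Mead)."""
    y, X = model.y, model.X
    n, p = X.shape
    from scipy.linalg import qr as _qr

    Q, _ = _qr(X, mode="full")
    Q2 = Q[:, p:]
    y_proj = Q2.T @ y
    names = list(model.terms)
    Ms = []
    for name in names:
        Z, L = model.terms[name]
        Zt = Z @ L if L is not None else Z
        Zp = Q2.T @ Zt
        Ms.append(Zp @ Zp.T)
    # start from the constrained EM solution
    try:
        em = _em_reml_single if len(names) == 1 else _em_reml
        comps0, s2e0, _, _, _ = em(model, max(tol, 1e-6), max_iter)
        x0 = np.array([comps0[n] for n in names] + [s2e0])
    except ConvergenceError:
        v = float(np.var(y, ddof=1))
        x0 = np.full(len(names) + 1, v / (len(names) + 1))
    scale = max(float(np.var(y, ddof=1)), 1e-12)
    res = optimize.minimize(
        _reml_nll_direct, x0, args=(y_proj, Ms), method="Nelder-Mead",
        options={"xatol": tol * scale, "fatol": 1e-10, "maxiter": 20000,
                 "maxfev": 20000},
    )
    if not np.isfinite(res.fun):
        raise ConvergenceError("direct REML failed (non-finite likelihood)")
    theta = res.x
    comps = dict(zip(names, theta[:-1]))
    return comps, float(theta[-1]), -0.5 * float(res.fun), int(res.nit), None


def reml_fit(model: ModelData, constrain: bool = True,
             tol: float = 1e-8, max_iter: int = 2000) -> VarianceComponents:
    """Estimate variance components by REML.

    ``constrain=True`` (default) runs EM-REML: components stay nonnegative
    and the restricted likelihood is non-decreasing (available per-iteration
    in ``.trace``).  ``constrain=False`` maximizes the restricted likelihood
    without sign constraints, so components — typically the residual — may
    go negative and the derived heritability may exceed 1.
    """
    for name, (Z, _) in model.terms.items():
        if Z.shape[1] < 2:
            raise ValidationError(f"random term {name!r} has < 2 levels")
    if np.linalg.matrix_rank(model.X) < model.X.shape[1]:
        raise ValidationError("singular fixed-effects design")
    if constrain:
        if len(model.terms) == 1:
            comps, s2e, ll, nit, trace = _em_reml_single(model, tol, max_iter)
        else:
            comps, s2e, ll, nit, trace = _em_reml(model, tol, max_iter)
    else:
        comps, s2e, ll, nit, trace = _direct_reml(model, tol, max_iter)
    return _pack(model, comps, s2e, ll, nit, True, trace)


def genetic_parameters(vc: VarianceComponents, trait_mean: float) -> VarianceComponents:
    """Fill in h2, CVg, CVe and CVr from the fitted components.

    h2 = sigma_a^2 / sigma_p^2; CVg = 100 sqrt(sigma_a^2)/mean;
    CVe = 100 sqrt(sigma_e^2)/mean; CVr = CVg/CVe.  Negative components
    (unconstrained fits) make the corresponding CV undefined (NaN, with a
    warning); a zero residual makes CVr infinite.
    """
    if vc.sigma2_p is None or not np.isfinite(vc.sigma2_p) or vc.sigma2_p <= 0:
        raise ValueError("sigma2_p must be positive")
    if trait_mean == 0:
        raise ValueError("trait mean must be nonzero for coefficients of variation")
    vc.h2_a = vc.sigma2_a / vc.sigma2_p
    if vc.sigma2_a < 0:
        logger.warning("negative additive variance: CVg undefined")
        vc.cv_g = np.nan
    else:
        vc.cv_g = 100.0 * np.sqrt(vc.sigma2_a) / abs(trait_mean)
    if vc.sigma2_e < 0:
        logger.warning("negative residual variance: CVe undefined")
        vc.cv_e = np.nan
    elif vc.sigma2_e == 0:
        vc.cv_e = 0.0
    else:
        vc.cv_e = 100.0 * np.sqrt(vc.sigma2_e) / abs(trait_mean)
    if vc.cv_e == 0:
        vc.cv_r = 0.0 if vc.cv_g == 0 else np.inf
        if np.isinf(vc.cv_r):
            logger.warning("zero residual CV: CVr reported as infinite")
    else:
        vc.cv_r = vc.cv_g / vc.cv_e
    return vc


def indirect_selection_threshold(r_A: float, H_X: float, L_X: float) -> float:
    """Longest genomic-selection cycle that still beats phenotypic selection.

    Selection response per unit time favors the genomic program whenever
    L_Y < (r_A / H_X) L_X, with r_A the genomic prediction accuracy, H_X the
    phenotypic selection accuracy and L_X the phenotypic cycle length; the
    returned value is that break-even cycle length.
    """
    if H_X <= 0:
        raise ValueError("phenotypic accuracy H_X must be > 0")
    return (r_A / H_X) * L_X


def fit_experiment(pheno: PhenotypeTable, trait: str, design: str,
                   grm: RelationshipMatrix = None, use_grm: bool = False,
                   constrain: bool = True, tol: float = 1e-8,
                   max_iter: int = 2000,
                   additive_multiplier: float = 1.0) -> VarianceComponents:
    """Assemble, fit and summarize one experiment/trait in a single call."""
    spec = MixedModelSpec(design=design, use_grm=use_grm,
                          additive_multiplier=additive_multiplier)
    model = build_design(pheno, trait, spec, grm=grm)
    vc = reml_fit(model, constrain=constrain, tol=tol, max_iter=max_iter)
    mean = float(np.mean(model.y))
    if mean != 0 and vc.sigma2_p > 0:
        vc = genetic_parameters(vc, mean)
    return vc


def table_of_parameters(results: dict) -> pd.DataFrame:
    """Arrange {(experiment, trait): VarianceComponents} into a long table."""
    rows = []
    for (experiment, trait), vc in results.items():
        rows.append({
            "experiment": experiment, "trait": trait,
            "sigma2_a": vc.sigma2_a, "sigma2_f": vc.sigma2_f,
            "sigma2_b": vc.sigma2_b, "sigma2_e": vc.sigma2_e,
            "sigma2_p": vc.sigma2_p, "h2_a": vc.h2_a,
            "cv_g": vc.cv_g, "cv_e": vc.cv_e, "cv_r": vc.cv_r,
        })
    return pd.DataFrame(rows)
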