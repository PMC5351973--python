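"""Single-site Gibbs samplers for the Bayesian-alphabet marker models.

One numba-compiled kernel covers BRR, Bayes A, Bayes B, Bayes Cpi and the
Bayesian LASSO; the methods differ only in the per-marker prior variance and
in whether a spike-and-slab indicator is sampled.  The marker matrix is
passed Fortran-ordered so column sweeps touch contiguous memory.

Conventions
-----------
* ``pi`` is the probability that a marker has ZERO effect (the spike mass),
  i.e. the proportion of markers associated with zero phenotypic variance.
  Some software uses the complementary convention; this package does not.
* Variance priors are scaled inverse chi-square: sigma^2 ~ S*nu / chi2_nu.
* The Bayesian LASSO uses beta_j ~ N(0, sigma_e^2 tau_j^2),
  tau_j^2 ~ Exp(lambda^2/2) via the inverse-Gaussian conditional on
  1/tau_j^2, and lambda^2 ~ Gamma(shape, rate).
"""

from __future__ import annotations

import numpy as np
from numba import njit

BRR, BAYES_A, BAYES_B, BAYES_CPI, BLASSO = 0, 1, 2, 3, 4


@njit(cache=True)
def _rinvgauss(mu, lam):
    v = np.random.standard_normal()
    w = v * v
    x1 = mu + (mu * mu * w) / (2.0 * lam) - (mu / (2.0 * lam)) * np.sqrt(
        4.0 * mu * lam * w + mu * mu * w * w
    )
    if x1 <= 1e-300:
        x1 = 1e-300
    if np.random.random() <= mu / (mu + x1):
        return x1
    return mu * mu / x1


@njit(cache=True)
def _gibbs_core(y, Z, method, n_burn, n_iter, thin, seed,
                S_e, nu_e, S_b, nu_b, pi_init, estimate_pi,
                fix_variances, s2b_fix, s2e_fix,
                bl_shape, bl_rate, lambda2_init, fix_lambda, save_beta):
    np.random.seed(seed)
    n, m = Z.shape
    c = np.zeros(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += Z[i, j] * Z[i, j]
        c[j] = s

    mu = y.mean()
    beta = np.zeros(m)
    e = y - mu
    sigma2_e = s2e_fix if fix_variances else max(np.var(y) * 0.5, 1e-12)
    sigma2_b = s2b_fix if fix_variances else S_b
    sigma2_j = np.full(m, S_b)
    tau2 = np.ones(m)
    lambda2 = lambda2_init
    pi = pi_init

    n_saved = (n_iter + thin - 1) // thin
    beta_sum = np.zeros(m)
    beta2_sum = np.zeros(m)
    mu_s = np.zeros(n_saved)
    s2e_s = np.zeros(n_saved)
    varg_s = np.zeros(n_saved)
    pi_s = np.zeros(n_saved)
    hyper_s = np.zeros(n_saved)        # sigma2_b / mean sigma2_j / lambda2
    beta_chain = np.zeros((n_saved if save_beta else 1, m))
    k = 0

    for it in range(n_burn + n_iter):
        # intercept
        rbar = mu + e.mean()
        mu_new = rbar + np.random.standard_normal() * np.sqrt(sigma2_e / n)
        d = mu - mu_new
        for i in range(n):
            e[i] += d
        mu = mu_new

        # marker sweep
        for j in range(m):
            cj = c[j]
            if cj <= 0.0:
                continue
            rhs = 0.0
            for i in range(n):
                rhs += Z[i, j] * e[i]
            rhs += cj * beta[j]
            if method == BRR or method == BAYES_A or method == BLASSO:
                if method == BRR:
                    lam_j = sigma2_e / sigma2_b
                elif method == BAYES_A:
                    lam_j = sigma2_e / sigma2_j[j]
                else:
                    lam_j = 1.0 / tau2[j]
                denom = cj + lam_j
                bnew = rhs / denom + np.random.standard_normal() * np.sqrt(
                    sigma2_e / denom
                )
            else:
                s2 = sigma2_j[j] if method == BAYES_B else sigma2_b
                v0 = cj * sigma2_e
                v1 = cj * cj * s2 + cj * sigma2_e
                log_odds = (0.5 * (np.log(v0) - np.log(v1))
                            + 0.5 * rhs * rhs * (1.0 / v0 - 1.0 / v1)
                            + np.log(1.0 - pi) - np.log(pi))
                if log_odds > 35.0:
                    p_in = 1.0
                elif log_odds < -35.0:
                    p_in = 0.0
                else:
                    p_in = 1.0 / (1.0 + np.exp(-log_odds))
                if np.random.random() < p_in:
                    lam_j = sigma2_e / s2
                    denom = cj + lam_j
                    bnew = rhs / denom + np.random.standard_normal() * np.sqrt(
                        sigma2_e / denom
                    )
                else:
                    bnew = 0.0
            diff = bnew - beta[j]
            if diff != 0.0:
                for i in range(n):
                    e[i] -= Z[i, j] * diff
            beta[j] = bnew

        # variance / hyperparameter updates
        if method == BAYES_A:
            for j in range(m):
                sigma2_j[j] = (nu_b * S_b + beta[j] * beta[j]) / np.random.chisquare(
                    nu_b + 1.0
                )
        elif method == BAYES_B:
            for j in range(m):
                if beta[j] != 0.0:
                    sigma2_j[j] = (nu_b * S_b + beta[j] * beta[j]) / \
                        np.random.chisquare(nu_b + 1.0)
                else:
                    sigma2_j[j] = (nu_b * S_b) / np.random.chisquare(nu_b)
        elif method == BRR:
            if not fix_variances:
                ssb = 0.0
                for j in range(m):
                    ssb += beta[j] * beta[j]
                sigma2_b = (nu_b * S_b + ssb) / np.random.chisquare(nu_b + m)
        elif method == BAYES_CPI:
            ssb = 0.0
            m1 = 0
            for j in range(m):
                if beta[j] != 0.0:
                    ssb += beta[j] * beta[j]
                    m1 += 1
            sigma2_b = (nu_b * S_b + ssb) / np.random.chisquare(nu_b + m1)
        else:  # BLASSO
            sumtau2 = 0.0
            for j in range(m):
                b2 = beta[j] * beta[j]
                if b2 < 1e-12:
                    b2 = 1e-12
                itau = _rinvgauss(np.sqrt(lambda2 * sigma2_e / b2), lambda2)
                tau2[j] = 1.0 / itau
                sumtau2 += tau2[j]
            if not fix_lambda:
                lambda2 = np.random.gamma(
                    bl_shape + m, 1.0 / (bl_rate + 0.5 * sumtau2)
                )

        if (method == BAYES_B or method == BAYES_CPI) and estimate_pi:
            m1 = 0
            for j in range(m):
                if beta[j] != 0.0:
                    m1 += 1
            pi = np.random.beta(1.0 + (m - m1), 1.0 + m1)

        if not fix_variances:
            sse = 0.0
            for i in range(n):
                sse += e[i] * e[i]
            if method == BLASSO:
                extra = 0.0
                for j in range(m):
                    extra += beta[j] * beta[j] / tau2[j]
                sigma2_e = (sse + extra + nu_e * S_e) / np.random.chisquare(
                    n + m + nu_e
                )
            else:
                sigma2_e = (sse + nu_e * S_e) / np.random.chisquare(n + nu_e)
        if not np.isfinite(sigma2_e) or not np.isfinite(mu):
            raise RuntimeError("Gibbs chain diverged (non-finite state)")

        # save thinned post-burn-in samples
        if it >= n_burn and (it - n_burn) % thin == 0:
            for j in range(m):
                beta_sum[j] += beta[j]
                beta2_sum[j] += beta[j] * beta[j]
            if save_beta:
                for j in range(m):
                    beta_chain[k, j] = beta[j]
            g = Z @ beta
            gm = g.mean()
            vg = 0.0
            for i in range(n):
                vg += (g[i] - gm) ** 2
            varg_s[k] = vg / (n - 1)
            mu_s[k] = mu
            s2e_s[k] = sigma2_e
            pi_s[k] = pi
            if method == BAYES_A or method == BAYES_B:
                hyper_s[k] = sigma2_j.mean()
            elif method == BLASSO:
                hyper_s[k] = lambda2
            else:
                hyper_s[k] = sigma2_b
            k += 1

    return beta_sum, beta2_sum, mu_s, s2e_s, varg_s, pi_s, hyper_s, beta_chain, k


def run_gibbs(y, Z, method, chain, seed, hyper, save_beta=False):
    """Python-side wrapper: order the matrix, run the kernel, pack results."""
    n_burn, n_iter, thin = chain
    Zf = np.asfortranarray(Z, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    out = _gibbs_core(
        y, Zf, method, int(n_burn), int(n_iter), int(thin), int(seed),
        float(hyper["S_e"]), float(hyper["nu_e"]),
        float(hyper["S_b"]), float(hyper["nu_b"]),
        float(hyper["pi_init"]), bool(hyper["estimate_pi"]),
        bool(hyper["fix_variances"]), float(hyper["s2b_fix"]),
        float(hyper["s2e_fix"]), float(hyper["bl_shape"]),
        float(hyper["bl_rate"]), float(hyper["lambda2_init"]),
        bool(hyper["fix_lambda"]), bool(save_beta),
    )
    beta_sum, beta2_sum, mu_s, s2e_s, varg_s, pi_s, hyper_s, beta_chain, k = out
    beta_mean = beta_sum / k
    beta_var = np.maximum(beta2_sum / k - beta_mean ** 2, 0.0)
    return {
        "beta_mean": beta_mean,
        "beta_sd": np.sqrt(beta_var),
        "mu_samples": mu_s[:k],
        "sigma2_e_samples": s2e_s[:k],
        "varg_samples": varg_s[:k],
        "pi_samples": pi_s[:k],
        "hyper_samples": hyper_s[:k],
        "beta_samples": beta_chain[:k] if save_beta else None,
        "n_saved": k,
    }
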