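"""RR-BLUP, G-BLUP and RKHS: closed-form oracles, model equivalences,
backsolved marker effects, and prediction contracts."""

import numpy as np
import pytest

from gwsel.relmat import compute_grm
from gwsel.simdata import SimConfig, sim_founder_genotypes, sim_phenotypes
from gwsel.wgr import GBLUP, RKHS, RRBLUP, backsolve_marker_effects

from conftest import tiny_matrix


def _sim(seed, n=80, m=300, h2=0.5, n_qtl=30):
    cfg = SimConfig(n_founders=n, n_markers=m, n_qtl=n_qtl, target_h2=h2,
                    seed=seed, block_count=1, genetic_sd=1.0)
    geno = sim_founder_genotypes(cfg)
    pheno, truth = sim_phenotypes(geno, cfg)
    y = pheno.plant_means("trait", geno.plant_ids).to_numpy()
    return geno, y, truth


class TestRRBLUP:
    def test_constant_y_null_fit(self):
        g = tiny_matrix([[0, 1], [2, 1], [1, 0], [0, 2]])
        fit = RRBLUP().fit(g, np.full(4, 3.5))
        assert np.allclose(fit.beta_, 0.0)
        assert fit.mu_ == pytest.approx(3.5)

    def test_fixed_lambda_matches_normal_equations(self):
        # 3 plants x 2 markers, lambda fixed: direct inversion oracle
        g = tiny_matrix([[0, 2], [1, 1], [2, 0]])
        y = np.array([1.0, 2.0, 4.0])
        lam = 2.5
        fit = RRBLUP(lambda_=lam).fit(g, y)
        p = g.doses().mean(axis=0) / 2.0
        Z = g.doses() - 2 * p
        beta_oracle = np.linalg.solve(Z.T @ Z + lam * np.eye(2),
                                      Z.T @ (y - y.mean()))
        assert np.allclose(fit.beta_, beta_oracle, atol=1e-10)
        assert fit.mu_ == pytest.approx(y.mean())

    def test_duplicate_plants_equal_gebv(self):
        g = tiny_matrix([[0, 2, 1], [0, 2, 1], [2, 0, 1], [1, 1, 0]])
        y = np.array([1.0, 1.0, 3.0, 2.0])
        fit = RRBLUP().fit(g, y)
        assert fit.gebv_[0] == pytest.approx(fit.gebv_[1], abs=1e-10)


class TestGBLUP:
    def test_identity_kernel_univariate_blup(self):
        # G = I with fixed variances: gebv_i = h2 * (y_i - mean)
        rng = np.random.default_rng(0)
        y = rng.normal(size=12)
        K = np.eye(12)
        fit = GBLUP(kernel="precomputed", var_components=(3.0, 1.0)).fit(K, y)
        h2 = 3.0 / 4.0
        resid = y - fit.mu_
        assert np.allclose(fit.gebv_, h2 * resid, atol=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_equivalence_with_rrblup(self, seed):
        geno, y, _ = _sim(seed)
        rb = RRBLUP().fit(geno, y)
        gb = GBLUP().fit(geno, y)
        assert np.max(np.abs(rb.gebv_ - gb.gebv_)) < 1e-6

    def test_masked_phenotypes_predicted_through_g(self):
        # a single observed plant: its GEBV shrinks toward zero and
        # relatives' predictions are proportional to their G entries
        geno, y, _ = _sim(5, n=20, m=100)
        y_masked = np.full_like(y, np.nan)
        y_masked[0] = y[0]
        y_masked[1] = y[1]
        y_masked[2] = y[2]
        fit = GBLUP().fit(geno, y_masked)
        assert np.all(np.isfinite(fit.gebv_))
        # BLUP projection: unobserved gebv = G_cross @ alpha
        G = fit.K_
        pred = G[3:, :3] @ fit.alpha_
        assert np.allclose(fit.gebv_[3:], pred, atol=1e-10)

    def test_predict_matches_training(self):
        geno, y, _ = _sim(7, n=40, m=120)
        fit = GBLUP().fit(geno, y)
        assert np.allclose(fit.predict_gebv(geno), fit.gebv_, atol=1e-8)


class TestRKHS:
    def test_linear_limit_vs_gblup_structure(self):
        # tiny bandwidth: exp(-h d2/med) ~ 1 - h d2/med, an affine transform
        # of the linear kernel, so GEBV correlation with G-BLUP approaches 1
        geno, y, _ = _sim(9, n=60, m=150)
        gb = GBLUP().fit(geno, y)
        rk = RKHS(bandwidth=0.05).fit(geno, y)
        assert np.corrcoef(gb.gebv_, rk.gebv_)[0, 1] > 0.99

    def test_small_bandwidth_collapses_to_intercept(self):
        # h small enough that K rounds to the all-ones matrix: the genetic
        # term carries no contrasts and the model is intercept-only
        geno, y, _ = _sim(10, n=30, m=80)
        rk = RKHS(bandwidth=1e-20).fit(geno, y)
        assert np.allclose(rk.K_, 1.0)
        assert np.var(rk.gebv_) < np.var(y) * 1e-3

    def test_duplicate_plants_identical_predictions(self):
        g = tiny_matrix([[0, 2, 1], [0, 2, 1], [2, 0, 0], [1, 1, 2]])
        y = np.array([1.0, 1.0, 3.0, 2.0])
        rk = RKHS().fit(g, y)
        assert rk.gebv_[0] == pytest.approx(rk.gebv_[1], abs=1e-10)

    def test_invalid_bandwidth(self):
        g = tiny_matrix([[0, 1], [2, 1], [1, 1]])
        with pytest.raises(ValueError):
            RKHS(bandwidth=0.0).fit(g, np.array([1.0, 2.0, 3.0]))


class TestBacksolve:
    def test_reproduces_rrblup_effects(self):
        geno, y, _ = _sim(11)
        rb = RRBLUP().fit(geno, y)
        gb = GBLUP().fit(geno, y)
        beta = backsolve_marker_effects(gb)
        assert np.max(np.abs(beta - rb.beta_)) < 1e-6

    def test_round_trip_gebv(self):
        geno, y, _ = _sim(12, n=50, m=200)
        gb = GBLUP().fit(geno, y)
        beta = backsolve_marker_effects(gb)
        p = geno.doses()[gb.observed_].mean(axis=0) / 2.0
        Zc = geno.doses() - 2 * p
        assert np.max(np.abs(Zc @ beta - gb.gebv_)) < 1e-6

    def test_null_gebv_zero_effects(self):
        g = tiny_matrix([[0, 1], [2, 1], [1, 0], [1, 2]])
        gb = GBLUP().fit(g, np.full(4, 2.0))
        beta = backsolve_marker_effects(gb)
        assert np.allclose(beta, 0.0)


class TestPrediction:
    def test_identical_new_plant_identical_prediction(self):
        geno, y, _ = _sim(13, n=30, m=90)
        fit = RRBLUP().fit(geno, y)
        one = geno.select_plants([4])
        clone = tiny_matrix(one.values.copy(), marker_type=one.marker_type)
        clone.marker_ids = one.marker_ids
        pred = fit.predict_gebv(one)
        assert pred[0] == pytest.approx(fit.gebv_[4], abs=1e-10)

    def test_marker_order_invariance(self):
        geno, y, _ = _sim(14, n=30, m=60)
        fit = RRBLUP().fit(geno, y)
        perm = np.random.default_rng(3).permutation(geno.n_markers)
        shuffled = geno.select_markers(perm)
        assert np.allclose(fit.predict_gebv(shuffled),
                           fit.predict_gebv(geno), atol=1e-10)

    def test_marker_mismatch_rejected(self):
        geno, y, _ = _sim(15, n=30, m=60)
        fit = RRBLUP().fit(geno, y)
        with pytest.raises(ValueError, match="absent"):
            fit.predict_gebv(geno.select_markers(range(50)))


class TestFunctionalWrappers:
    def test_wrappers_delegate_to_estimators(self):
        from gwsel.wgr import (WGRSpec, fit_bayesian, fit_gblup, fit_model,
                               fit_rkhs, fit_rrblup, predict_gebv)
        geno, y, _ = _sim(21, n=30, m=60)
        rb = fit_rrblup(y, geno)
        assert np.allclose(rb.gebv_, RRBLUP().fit(geno, y).gebv_)
        gb = fit_gblup(y, geno)
        assert np.allclose(predict_gebv(gb, geno), gb.gebv_, atol=1e-8)
        rk = fit_rkhs(y, geno, bandwidth=2.0)
        assert np.isfinite(rk.h2_)
        spec = WGRSpec(method="brr", chain=(50, 100, 1), seed=1)
        br = fit_bayesian(y, geno, spec)
        assert br.beta_.shape == (60,)
        fm = fit_model(spec, geno, y)
        assert np.array_equal(fm.beta_, br.beta_)
        with pytest.raises(ValueError):
            fit_bayesian(y, geno, WGRSpec(method="gblup"))
        with pytest.raises(ValueError):
            WGRSpec(method="nope")
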