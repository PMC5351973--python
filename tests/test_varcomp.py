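"""Design assembly, EM-REML against closed forms, genetic parameters, and
the indirect-selection threshold."""

import numpy as np
import pandas as pd
import pytest

from gwsel.io import PhenotypeTable, ValidationError
from gwsel.relmat import compute_grm
from gwsel.simdata import (SimConfig, make_study_like_dataset,
                           sim_germplasm_trial, sim_halfsib_trial)
from gwsel.varcomp import (MixedModelSpec, VarianceComponents, build_design,
                           genetic_parameters, indirect_selection_threshold,
                           reml_fit)


def _pheno(rows):
    return PhenotypeTable(pd.DataFrame(rows, columns=[
        "plant_id", "experiment", "family", "block", "trait", "value"]))


class TestBuildDesign:
    def test_incidence_structure(self):
        rows = [(f"g{g}", "germplasm", "NA", f"B{b}", "T", float(g + b))
                for b in range(2) for g in range(3)]
        md = build_design(_pheno(rows), "T", MixedModelSpec("germplasm"))
        assert md.X.shape == (6, 2)
        Za, _ = md.terms["additive"]
        assert Za.shape == (6, 3)
        assert np.all(md.X.sum(axis=1) == 1.0)
        assert np.all(Za.sum(axis=1) == 1.0)

    def test_diallel_family_term(self, study_data):
        md = build_design(study_data.pheno, "GY", MixedModelSpec("diallel"))
        Tf, _ = md.terms["family"]
        assert Tf.shape[1] == 3
        md_g = build_design(study_data.pheno, "GY", MixedModelSpec("germplasm"))
        assert "family" not in md_g.terms

    def test_plot_term_dropped_when_single_obs(self):
        rows = [(f"g{g}", "germplasm", "NA", f"B{b}", "T", float(g))
                for b in range(2) for g in range(4)]
        md = build_design(_pheno(rows), "T", MixedModelSpec("germplasm"))
        assert "plot" not in md.terms


class TestEMREML:
    def test_matches_balanced_anova(self):
        # balanced RCB: unconstrained REML == ANOVA estimator; the EM path
        # must land on the same interior optimum
        pheno, _ = sim_germplasm_trial(120, 3, sigma2_a=50.0, sigma2_e=20.0,
                                       block_sd=2.0, seed=3)
        md = build_design(pheno, "trait", MixedModelSpec("germplasm"))
        vc = reml_fit(md, tol=1e-12, max_iter=20000)
        piv = pheno.data.pivot_table(index="plant_id", columns="block",
                                     values="value").to_numpy()
        g, b = piv.shape
        resid = piv - piv.mean(1, keepdims=True) - piv.mean(0) + piv.mean()
        msw = (resid ** 2).sum() / ((g - 1) * (b - 1))
        msb = b * np.var(piv.mean(1), ddof=1)
        assert vc.sigma2_e == pytest.approx(msw, rel=1e-6)
        assert vc.sigma2_a == pytest.approx((msb - msw) / b, rel=1e-6)

    def test_loglik_monotone(self):
        pheno, _ = sim_germplasm_trial(60, 2, 30.0, 60.0, seed=5)
        md = build_design(pheno, "trait", MixedModelSpec("germplasm"))
        vc = reml_fit(md)
        ll = vc.trace["loglik"].to_numpy()
        assert np.all(np.diff(ll) >= -1e-8 * np.maximum(np.abs(ll[:-1]), 1.0))

    def test_null_additive_variance_recovered(self):
        ratios = []
        for rep in range(20):
            pheno, _ = sim_germplasm_trial(40, 2, sigma2_a=0.0, sigma2_e=100.0,
                                           seed=200 + rep)
            md = build_design(pheno, "trait", MixedModelSpec("germplasm"))
            vc = reml_fit(md)
            ratios.append(vc.sigma2_a / vc.sigma2_p)
        assert np.median(ratios) < 0.05

    def test_multi_term_diallel_fit(self, study_data):
        grm = compute_grm(study_data.geno)
        md = build_design(study_data.pheno, "W100S",
                          MixedModelSpec("diallel", use_grm=True), grm=grm)
        vc = reml_fit(md)
        assert vc.sigma2_a >= 0 and vc.sigma2_f >= 0 and vc.sigma2_e > 0
        assert vc.sigma2_p == pytest.approx(
            vc.sigma2_a + vc.sigma2_f + vc.sigma2_e)
        ll = vc.trace["loglik"].to_numpy()
        assert np.all(np.diff(ll) >= -1e-8 * np.maximum(np.abs(ll[:-1]), 1.0))

    def test_phenotypic_variance_identity(self):
        pheno, _ = sim_germplasm_trial(50, 2, 40.0, 80.0, seed=9)
        md = build_design(pheno, "trait", MixedModelSpec("germplasm"))
        vc = reml_fit(md)
        assert vc.sigma2_p == pytest.approx(vc.sigma2_a + vc.sigma2_e)

    def test_singular_fixed_design_rejected(self):
        rows = [(f"g{g}", "germplasm", "NA", "B1", "T", float(g))
                for g in range(5)]
        md = build_design(_pheno(rows), "T", MixedModelSpec("germplasm"))
        md.X = np.hstack([md.X, md.X])       # duplicated block column
        with pytest.raises(ValidationError, match="singular"):
            reml_fit(md)


class TestUnconstrained:
    def test_halfsib_pathology_h2_above_one(self):
        # plot-mean half-sib records, near-zero residual, Falconer 4x
        # conversion: reported h2 exceeds 1 (the small-n pathology)
        pheno, _ = sim_halfsib_trial(40, 2, sigma2_a=100.0, sigma2_e=1.0,
                                     seed=1)
        md = build_design(pheno, "trait",
                          MixedModelSpec("germplasm", additive_multiplier=4.0))
        vc = reml_fit(md, constrain=False)
        assert vc.h2_a > 1.0
        # implied subtraction residual sigma2_p - sigma2_a - sigma2_b < 0
        assert vc.sigma2_p - vc.sigma2_a < 0

    def test_constrained_never_negative(self):
        pheno, _ = sim_halfsib_trial(30, 2, 100.0, 1.0, seed=2)
        md = build_design(pheno, "trait", MixedModelSpec("germplasm"))
        vc = reml_fit(md, constrain=True)
        assert vc.sigma2_a >= 0 and vc.sigma2_e >= 0


class TestGeneticParameters:
    def test_hand_example(self):
        vc = VarianceComponents(sigma2_a=25.0, sigma2_e=100.0)
        vc.sigma2_p = 125.0
        vc = genetic_parameters(vc, trait_mean=50.0)
        assert vc.cv_g == pytest.approx(10.0)
        assert vc.cv_e == pytest.approx(20.0)
        assert vc.cv_r == pytest.approx(0.5)
        assert vc.h2_a == pytest.approx(0.2)

    def test_zero_residual_limit(self):
        vc = VarianceComponents(sigma2_a=10.0, sigma2_e=0.0)
        vc.sigma2_p = 10.0
        vc = genetic_parameters(vc, 5.0)
        assert vc.h2_a == pytest.approx(1.0)
        assert np.isinf(vc.cv_r)

    def test_null_additive(self):
        vc = VarianceComponents(sigma2_a=0.0, sigma2_e=10.0)
        vc.sigma2_p = 10.0
        vc = genetic_parameters(vc, 5.0)
        assert vc.h2_a == 0.0 and vc.cv_g == 0.0 and vc.cv_r == 0.0

    def test_negative_additive_flagged(self):
        vc = VarianceComponents(sigma2_a=-5.0, sigma2_e=10.0)
        vc.sigma2_p = 5.0
        vc = genetic_parameters(vc, 5.0)
        assert np.isnan(vc.cv_g)


class TestIndirectSelection:
    @pytest.mark.parametrize("r_A,H_X,L_X,expected", [
        (0.5, 0.5, 12.0, 12.0),    # equal accuracy: equal cycle allowed
        (0.6, 0.3, 12.0, 24.0),
        (0.0, 0.4, 12.0, 0.0),
    ])
    def test_threshold(self, r_A, H_X, L_X, expected):
        assert indirect_selection_threshold(r_A, H_X, L_X) == pytest.approx(expected)

    def test_zero_accuracy_rejected(self):
        with pytest.raises(ValueError):
            indirect_selection_threshold(0.5, 0.0, 12.0)
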