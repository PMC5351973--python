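import numpy as np
import pytest

from gwsel.io import MarkerMatrix
from gwsel.simdata import SimConfig, make_study_like_dataset, sim_founder_genotypes, sim_phenotypes


@pytest.fixture(scope="session")
def study_data():
    """One study-like dataset (78 x 1248, two traits) shared across tests."""
    return make_study_like_dataset(seed=11)


@pytest.fixture(scope="session")
def small_sim():
    """A small unit-scale single-trait simulation: 60 plants x 120 markers."""
    cfg = SimConfig(n_founders=60, n_markers=120, n_qtl=20, target_h2=0.5,
                    seed=4, block_count=1, genetic_sd=1.0)
    geno = sim_founder_genotypes(cfg)
    pheno, truth = sim_phenotypes(geno, cfg)
    y = pheno.plant_means("trait", geno.plant_ids).to_numpy()
    return geno, y, truth


def tiny_matrix(values, marker_type=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return MarkerMatrix(values,
                        [f"p{i}" for i in range(n)],
                        [f"m{j}" for j in range(m)],
                        marker_type)
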