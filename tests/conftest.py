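"""Shared fixtures: seeded synthetic cohorts and fitted models.

The "standard" cohort uses the reference study conditions (24 patients,
2000 genes, effect size 2 log2 units, NB dispersion 0.05); the "small"
cohort is a fast variant for structural tests.
"""

import numpy as np
import pytest

from chemoresistome.model import ChemoresistomeModel
from chemoresistome.simulate import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        n_patients=12, n_genes=300, n_pathways=12,
        pathway_size_range=(8, 20),
        resistant_pathway_ids=("PW001", "PW002"),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    model = ChemoresistomeModel.from_cohort(
        small_cohort, n_boot=500, min_bimodal_patients=3)
    return model.fit()


@pytest.fixture(scope="session")
def standard_config():
    return SyntheticConfig(seed=7)  # 24 patients, 2000 genes, effect 2, phi 0.05


@pytest.fixture(scope="session")
def standard_cohort(standard_config):
    return generate_cohort(standard_config)


@pytest.fixture(scope="session")
def standard_fit(standard_cohort):
    model = ChemoresistomeModel.from_cohort(standard_cohort, seed=7)
    return model.fit(compute_scores=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
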