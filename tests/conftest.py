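import numpy as np
import pytest

from iluq.chem import parse_ion_pair
from iluq.experiments import run_ru_experiment
from iluq.synthetic import GeneratorSpec, generate_ion_library, generate_property_dataset

ACCEPTANCE_SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def ammonium_chloride():
    return parse_ion_pair("[NH4+].[Cl-]", "nh4cl")


@pytest.fixture(scope="session")
def tma_acetate():
    return parse_ion_pair("C[N+](C)(C)C.CC(=O)[O-]", "tma-oac")


@pytest.fixture(scope="session")
def small_library():
    """A small in-domain ion library (12 cations x 10 anions), seeded."""
    spec = GeneratorSpec(n_cations=12, n_anions=10, seed=11)
    return generate_ion_library(spec)


@pytest.fixture(scope="session")
def small_dataset(small_library):
    """A 60-record noiseless viscosity dataset with known ground truth."""
    spec = GeneratorSpec(n_cations=12, n_anions=10, seed=11, noise_sd=1e-12,
                         n_records=60)
    ds, truth = generate_property_dataset(small_library, spec)
    return ds, truth


@pytest.fixture(scope="session")
def ru_runs():
    """The three seeded synthetic RU studies shared by the heavier tests.

    Training the four-representation suite dominates suite runtime, so the
    three runs are computed once per session and reused.
    """
    return {seed: run_ru_experiment(seed=seed) for seed in ACCEPTANCE_SEEDS}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
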