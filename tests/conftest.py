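import warnings

import numpy as np
import pytest

from nmrpattern import (CohortDesign, DummyY, assemble_table,
                        default_species_design, scale_columns, simulate_cohort)
from nmrpattern.synthetic import _SAPONINS, _SECOIRIDOIDS


def small_species_design(seed: int = 0, noise_sd: float = 0.005) -> CohortDesign:
    """Scaled-down 20/8/8 analogue of the default three-class design."""
    full = default_species_design(seed=seed)
    return CohortDesign(
        class_sizes={"cLJF": 20, "wLJF": 8, "LF": 8},
        concentration_means=full.concentration_means,
        concentration_cv=full.concentration_cv,
        noise_sd=noise_sd,
        seed=seed,
    )


@pytest.fixture(scope="session")
def species_design():
    return default_species_design(seed=7)


@pytest.fixture(scope="session")
def species_table(species_design):
    """Full 100-sample bucketed cohort (77/10/13), TMS-normalized."""
    return assemble_table(simulate_cohort(species_design))


@pytest.fixture(scope="session")
def small_table():
    """36-sample three-class table for the cheaper model tests."""
    return assemble_table(simulate_cohort(small_species_design(seed=3)))


@pytest.fixture(scope="session")
def small_scaled(small_table):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        X, rec = scale_columns(small_table.values, "uv")
    return X, rec, DummyY.from_labels(small_table.labels)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
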