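"""Shared fixtures: one small synthetic study reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from sagersf.covariates import covariate_grid, extract_covariates
from sagersf.design import DEFAULT_SEASONS, build_design
from sagersf.fitting import assign_available_groups
from sagersf.synthetic import (STUDY_INTERVAL, DEFAULT_TRUTH, LandscapeConfig,
                               generate_energy_field, generate_landscape,
                               simulate_telemetry)


@pytest.fixture(scope="session")
def landscape():
    return generate_landscape(LandscapeConfig(shape=(90, 90)), seed=7)


@pytest.fixture(scope="session")
def energy(landscape):
    return generate_energy_field(landscape, n_wells=12, n_clusters=2, seed=3)


@pytest.fixture(scope="session")
def breeding_grid(landscape, energy):
    return covariate_grid(landscape, 150.8, energy=energy, study_interval=STUDY_INTERVAL)


@pytest.fixture(scope="session")
def telemetry(landscape, energy):
    return simulate_telemetry(landscape, energy, DEFAULT_TRUTH,
                              n_birds=18, relocations_per_bird=90, seed=11)


@pytest.fixture(scope="session")
def breeding_table(landscape, energy, telemetry):
    """Fit-ready breeding-season covariate table from the small study."""
    design, _ = build_design(telemetry, landscape.extent, seasons=DEFAULT_SEASONS,
                             n_available={"breeding": 1500, "summer": 800, "winter": 1200},
                             seed=5)
    sub = design[design["season"] == "breeding"].reset_index(drop=True)
    tab = extract_covariates(sub, 150.8, landscape, energy=energy,
                             study_interval=STUDY_INTERVAL)
    return assign_available_groups(tab, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
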