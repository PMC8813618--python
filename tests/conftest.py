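"""Shared fixtures: one small synthetic study reused across test modules."""

import warnings

import numpy as np
import pytest

from mkmeta.profiles import arcsine_sqrt, to_relative
from mkmeta.synthdata import SimulationConfig, combined_table, generate_study


@pytest.fixture(scope="session")
def small_study():
    """3 cohorts x 15/class, two kingdoms, 10 planted markers, mild batch effect."""
    cfg = SimulationConfig(
        n_cohorts=3,
        samples_per_cohort_per_class=15,
        n_features_per_kingdom={"bacteria": 30, "fungi": 20},
        n_markers_per_kingdom={"bacteria": 6, "fungi": 4},
        marker_log_fold_effect=1.2,
        batch_sd=0.3,
        zero_inflation=0.05,
        library_size_mean=20000,
        seed=11,
    )
    tables, meta, truth = generate_study(cfg)
    return cfg, tables, meta, truth


@pytest.fixture(scope="session")
def small_combined(small_study):
    _, tables, meta, truth = small_study
    return combined_table(tables), meta, truth


@pytest.fixture(scope="session")
def small_transformed(small_combined):
    """Arcsine-sqrt transformed matrix of the small study (samples x features)."""
    table, meta, truth = small_combined
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        x = arcsine_sqrt(to_relative(table))
    return x, meta, truth


@pytest.fixture(autouse=True)
def _quiet_numeric_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=RuntimeWarning)
        warnings.filterwarnings("ignore", category=UserWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(0)
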