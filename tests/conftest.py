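import numpy as np
import pandas as pd
import pytest

from opsel import lmm, synth

from opsel.selection_metrics import build_selection_table
from opsel.survey_io import build_band_seasons, validate_sightings


@pytest.fixture(scope="session")
def small_config():
    """A reduced island: fewer bands and years, cheap to simulate."""
    return synth.IslandConfig(n_years=3, occasions_per_year=8, seed=11)


@pytest.fixture(scope="session")
def small_truth():
    return synth.TruthParams(n_bands_per_year=30)


@pytest.fixture(scope="session")
def small_dataset(small_config, small_truth):
    return synth.simulate_dataset(small_config, small_truth)


@pytest.fixture(scope="session")
def small_sightings(small_dataset):
    records, _ = validate_sightings(small_dataset.sightings)
    return records


@pytest.fixture(scope="session")
def small_bands(small_sightings):
    return build_band_seasons(small_sightings)


@pytest.fixture(scope="session")
def small_table(small_dataset, small_sightings, small_bands, small_config):
    table, _ = build_selection_table(
        small_bands, small_sightings, small_dataset.island.ponds,
        small_dataset.island.polygon, small_config.precip_by_year())
    return table


@pytest.fixture(scope="session")
def grouped_lmm_data():
    """Balanced random-intercept data with a known covariate effect."""
    rng = np.random.default_rng(7)
    n_g, reps = 30, 4
    g = np.repeat(np.arange(n_g), reps)
    x = rng.normal(size=n_g * reps)
    yr = np.tile([2008, 2009, 2010, 2011], n_g)
    y = 0.4 * x + rng.normal(0, 0.3, n_g)[g] + rng.normal(0, 0.5, n_g * reps)
    return pd.DataFrame(dict(male_id=g, year=yr, y=y, x=x))


@pytest.fixture(scope="session")
def grouped_lmm_fit(grouped_lmm_data):
    return lmm.fit_lmm(grouped_lmm_data, lmm.ModelSpec("y", covariate="x"))
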