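import numpy as np
import pandas as pd
import pytest

import songnorms as sn


@pytest.fixture(scope="session")
def small_bivariate_data():
    """A small simulated bivariate study: 40 individuals, mixed contexts."""
    cfg = sn.SimulationConfig(n_individuals=40, songs_per_recording=(10, 20),
                              n_years=3, prop_repeated=0.3, seed=123)
    params = sn.default_true_parameters()
    songs, recordings, truth = sn.simulate_dataset(cfg, params)
    return songs, recordings, truth, params, cfg


@pytest.fixture(scope="session")
def small_univariate_fit(small_bivariate_data):
    """A short univariate SL fit with two chains, reused across tests."""
    songs = small_bivariate_data[0]
    spec = sn.ModelSpec(responses=("SL",))
    design = sn.build_design(songs, spec)
    chains = sn.ChainConfig(1600, 400, 4, n_chains=2, seed=7)
    draws = sn.gibbs_sample(design, spec, chains)
    return design, spec, chains, draws


def make_song_frame(n, seed=0, contexts=("male", "female", "none")):
    """Ad-hoc song table with valid structure, one individual per row."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "individual_id": [f"b{i:03d}" for i in range(n)],
        "recording_id": [f"r{i:03d}" for i in range(n)],
        "context": rng.choice(list(contexts), n),
        "song_order": np.arange(n) % 7 + 1,
        "age": rng.integers(0, 2, n),
        "date": rng.integers(0, 27, n),
        "year": rng.integers(0, 3, n),
        "position": rng.uniform(0, 100, n),
        "SL": rng.normal(0, 1, n),
        "MF": rng.normal(0, 1, n),
    })
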