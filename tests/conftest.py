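import numpy as np
import pytest

import pmwave as pw


@pytest.fixture(scope="session")
def small_scene():
    """A 60x60 km scene, 6 hours, 70 monitors; shared read-only across tests."""
    cfg = pw.SceneConfig(n_rows=60, n_cols=60, n_hours=6, n_reference_sites=10,
                         n_lowcost_sites=60, seed=3)
    truth = pw.simulate_fields(cfg)
    sites = pw.place_sites(cfg, seed=4)
    obs = pw.sample_observations(truth, sites, seed=5)
    return cfg, truth, sites, obs


@pytest.fixture(scope="session")
def small_model(small_scene):
    """A fitted PM2.5 model on the small scene (no AOD gaps, modest forest)."""
    cfg, truth, sites, obs = small_scene
    model = pw.PM25Model.from_fields(truth.true_aod, truth.met, obs,
                                     forest_config=pw.ForestConfig(n_trees=120, seed=7))
    return model, model.fit()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
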