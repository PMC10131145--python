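import numpy as np
import pytest

import lurmap.synthetic_city as sc
import lurmap.pipeline as pl


@pytest.fixture(scope="session")
def small_scene():
    """Compact 4 km metropolis shared by feature/exposure tests."""
    cfg = sc.SceneConfig(extent=(0.0, 0.0, 4000.0, 4000.0),
                         n_radial_roads=10, n_local_roads=25)
    return sc.generate_city(cfg, seed=42)


@pytest.fixture(scope="session")
def met_table():
    return sc.generate_meteorology(seed=7)


@pytest.fixture(scope="session")
def small_campaign():
    """Reduced end-to-end campaign (6 fixed + 40 rotating sites, 4 km scene)."""
    return pl.run_campaign(
        seed=11,
        scene_config=sc.SceneConfig(extent=(0.0, 0.0, 4000.0, 4000.0),
                                    n_radial_roads=10, n_local_roads=25),
        sampling_config=sc.SamplingConfig(n_fixed=6, n_rotating=40),
    )
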