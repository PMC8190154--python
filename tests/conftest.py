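import datetime as dt

import pytest

from fieldet import synthetic_data as sd


@pytest.fixture(scope="session")
def small_config():
    """Homogeneous 16x16 scene over a 3-month season, noise-free."""
    return sd.SyntheticConfig(
        grid_shape=(16, 16),
        season_start=dt.date(2019, 5, 1),
        season_end=dt.date(2019, 7, 31),
        n_patches=0,
        noise_sd=0.0,
        closure_gap_fraction=0.2,
        cloud_prob=0.3,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_scene(small_config):
    """(config, stack, met, tower, truth, boundary) for the small scene."""
    cfg = small_config
    stack = sd.gen_ndvi_stack(cfg)
    met = sd.gen_met_series(cfg)
    r, c = sd.tower_pixel(cfg)
    tower, truth = sd.gen_tower_record(cfg, sd.ndvi_series_at(stack, r, c), met)
    return cfg, stack, met, tower, truth, sd.gen_boundary(cfg)
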