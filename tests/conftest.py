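import numpy as np
import pytest

from hsichem import (
    GeneratorConfig,
    ROISelection,
    calibrate_reflectance,
    make_sample_table,
    make_scene_for_record,
    noise_free,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Small, fast scene configuration with all noise sources active."""
    return GeneratorConfig(
        n_rows=32, n_cols=32, n_bands=64, n_panelists=2, n_replicates=1, seed=7
    )


@pytest.fixture
def clean_config(small_config):
    """Same geometry, every stochastic nuisance off."""
    return noise_free(small_config)


@pytest.fixture
def clean_scene(clean_config):
    record = make_sample_table(clean_config)[0]
    return make_scene_for_record(clean_config, record)


@pytest.fixture
def reflectance_cube(clean_scene):
    return calibrate_reflectance(
        clean_scene.raw_cube, clean_scene.dark_frame, clean_scene.white_frame
    )


@pytest.fixture
def roi_small():
    return ROISelection(height=16, width=16)
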