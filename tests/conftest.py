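import numpy as np
import pytest

from traqg import DEFAULT_SENSOR, FOVConfig, preset_config


@pytest.fixture
def sensor():
    return DEFAULT_SENSOR


@pytest.fixture
def small_config():
    """A quick-to-render FOV used by most image tests."""
    return FOVConfig(height_px=128, width_px=128, n_cells=4, seed=11)


@pytest.fixture
def clean_config():
    """Noiseless, uniform-GSH FOV: every forward-model identity is exact."""
    return FOVConfig(
        height_px=128,
        width_px=128,
        n_cells=4,
        gsh_sd_mM=0.0,
        gsh_mean_mM=10.0,
        background_fp=0.0,
        background_sir=0.0,
        read_noise_sd=0.0,
        shot_noise=False,
        expression_sigma=0.3,
        seed=3,
    )


@pytest.fixture
def nucleus_fovs():
    """Ten default nucleus-preset FOVs with ground truth (~150 cells)."""
    out = []
    for i in range(10):
        cfg = preset_config("nucleus", seed=100 + i)
        import traqg

        out.append((cfg, *traqg.generate_fov(cfg)))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
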