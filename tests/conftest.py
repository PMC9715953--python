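import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pshgmargin as pm

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def zero_noise_phantom():
    """Small noise-free phantom: (config, truth, stack)."""
    cfg = pm.PhantomConfig(
        image_height=256,
        image_width=256,
        tile_size=64,
        boundary_column=128,
        noise="none",
        background_level=0.0,
        seed=7,
    )
    truth = pm.generate_phantom(cfg)
    stack = pm.synthesize_stack(truth, cfg)
    return cfg, truth, stack


@pytest.fixture(scope="session")
def small_pipeline_result():
    """Full pipeline on a reduced 512x512 phantom (64-px tiles, 8x8 grid)."""
    pcfg = pm.PhantomConfig(
        image_height=512, image_width=512, tile_size=64, boundary_column=256
    )
    return pm.analyze_phantom(pm.PipelineConfig(phantom=pcfg, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
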