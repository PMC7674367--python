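import numpy as np
import pytest

from cytomorph.synthetic import (LayerSpec, PopulationEffectSpec, SlideConfig,
                                 generate_cell_table)


@pytest.fixture(scope="session")
def null_table():
    """Cell table with no population effects but real animal random effects."""
    return generate_cell_table(PopulationEffectSpec(), seed=123)


@pytest.fixture(scope="session")
def small_granule_slide():
    """A 300×300 µm slide with 60 well-separated granules."""
    from cytomorph.synthetic import generate_slide
    cfg = SlideConfig(
        width_um=300, height_um=300, noise_sd=0.02,
        layers=[LayerSpec("granular", {"granule": 60}, clustering=0.0,
                          min_center_spacing_um=18.0)],
        seed=21)
    return generate_slide(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
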