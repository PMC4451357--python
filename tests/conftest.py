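import numpy as np
import pytest

from eigenbrain import EffectRegion, PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def strong_phantom():
    """Small cohort with one strong effect region (magnitude >> noise)."""
    config = PhantomConfig(
        shape=(24, 24, 24),
        n_nc=8,
        n_ad=6,
        effect_regions=(EffectRegion(center=(12, 12, 12), radius=3.0, magnitude=50.0),),
        noise_sd=1.0,
        seed=11,
    )
    dataset, truth = generate_phantom(config)
    return config, dataset, truth


@pytest.fixture(scope="session")
def null_phantom():
    """Cohort with no class effect at all."""
    config = PhantomConfig(
        shape=(16, 16, 16), n_nc=6, n_ad=5, effect_regions=(), noise_sd=1.0, seed=5
    )
    dataset, truth = generate_phantom(config)
    return config, dataset, truth
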