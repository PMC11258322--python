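import math

import numpy as np
import pytest

from psoce import PhantomConfig, ProcessingParams


@pytest.fixture
def params() -> ProcessingParams:
    return ProcessingParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def small_slab(
    seed: int = 0,
    n_z: int = 100,
    n_x: int = 48,
    n_y: int = 1,
    scatterer_density: float = 2.0,
    snr_db: float = math.inf,
    decorrelation: float = 0.0,
    **kwargs,
) -> PhantomConfig:
    """A flat-slab corneal phantom small enough for exhaustive checks."""
    defaults = dict(
        n_z=n_z,
        n_x=n_x,
        n_y=n_y,
        delta=4.48,
        pitch_x=12.0,
        pitch_y=120.0,
        anterior_apex_depth=45.0,
        corneal_thickness=350.0,
        curvature_radius=math.inf,
        scatterer_density=scatterer_density,
        snr_db=snr_db,
        decorrelation=decorrelation,
        seed=seed,
    )
    defaults.update(kwargs)
    return PhantomConfig(**defaults)


@pytest.fixture
def slab_config() -> PhantomConfig:
    return small_slab()
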