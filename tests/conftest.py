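from __future__ import annotations

import numpy as np
import pytest

from thgq import PhantomSpec, PipelineConfig, analyze_image, generate_phantom


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A 600x600 phantom small enough for repeated full-pipeline runs."""
    return PhantomSpec(image_shape=(600, 600), n_cells=10, n_fibers=10,
                       n_granules=6, rng_seed=123)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def small_analysis(small_phantom):
    img, _ = small_phantom
    return analyze_image(img, PipelineConfig())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
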