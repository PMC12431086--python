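import numpy as np
import pytest

from bloomscale.config import default_pipeline_config
from bloomscale.synthetic import distance_to_scale, generate_scene, random_scene_spec


@pytest.fixture(scope="session")
def pipeline_config():
    return default_pipeline_config()


@pytest.fixture(scope="session")
def scene_and_truth():
    """One deterministic mixed-color rosette scene at the 60 cm scale."""
    rng = np.random.default_rng(7)
    spec = random_scene_spec(rng, "T1", "C1", distance_to_scale(60))
    return generate_scene(spec)


def rect_mask(shape, r0, r1, c0, c1):
    m = np.zeros(shape, dtype=bool)
    m[r0:r1, c0:c1] = True
    return m
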