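import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def desk_gen_cfg():
    from vhsnet.synthdata import GeneratorConfig
    return GeneratorConfig.desk(seed=42)


@pytest.fixture(scope="session")
def small_dataset_dir(tmp_path_factory, desk_gen_cfg):
    """A 24-sample synthetic dataset written to disk once per session."""
    from vhsnet.synthdata import generate_dataset
    out = tmp_path_factory.mktemp("synthdata")
    manifest = generate_dataset(desk_gen_cfg, 24, out)
    return out, manifest


def random_keypoint_set(rng, scale=100.0):
    """A random valid KeyPointSet (distinct points, non-degenerate EF)."""
    from vhsnet.geometry import KeyPointSet, Point
    while True:
        pts = rng.uniform(0, scale, size=(6, 2))
        a, b, c, d, e, f = pts
        if (np.linalg.norm(a - b) > 1e-3 and np.linalg.norm(c - d) > 1e-3
                and np.linalg.norm(e - f) > 1e-3):
            return KeyPointSet(*(Point(*p) for p in pts))
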