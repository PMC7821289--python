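import numpy as np
import pytest

from fibrequant import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small rendered cohort shared across tests: 4 participants x 2 images."""
    cfg = SimulationConfig(
        n_participants=4,
        images_per_participant=2,
        image_shape=(256, 256),
        rng_seed=123,
    )
    return generate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_footprint(rng, n_min=1, n_max=60, span=25):
    """Connected-ish random pixel blob for geometry/merge tests."""
    n = int(rng.integers(n_min, n_max + 1))
    pts = {(int(rng.integers(span)), int(rng.integers(span)))}
    while len(pts) < n:
        r, c = list(pts)[int(rng.integers(len(pts)))]
        dr, dc = int(rng.integers(-1, 2)), int(rng.integers(-1, 2))
        pts.add((max(r + dr, 0), max(c + dc, 0)))
    return np.array(sorted(pts), dtype=np.intp)
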