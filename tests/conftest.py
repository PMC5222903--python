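import numpy as np
import pytest

import vfinterp as vf


@pytest.fixture(scope="session")
def od_grid() -> vf.TestGrid:
    return vf.generate_test_grid("OD")


@pytest.fixture(scope="session")
def os_grid() -> vf.TestGrid:
    return vf.generate_test_grid("OS")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_points(rng: np.random.Generator, n: int, span: float = 60.0) -> np.ndarray:
    """Scattered (x, y, z) triplets with smooth-ish z in a realistic dB range."""
    xy = rng.uniform(-span, span, (n, 2))
    z = 30.0 - 0.25 * np.hypot(xy[:, 0], xy[:, 1]) + rng.normal(0, 2.0, n)
    return np.column_stack([xy, np.clip(z, 0.0, 35.0)])


@pytest.fixture()
def small_cloud(rng) -> np.ndarray:
    return random_points(rng, 20)


@pytest.fixture(scope="session")
def noisy_exam_pair(od_grid):
    """Two replicate examinations of one eye plus their truth field."""
    model = vf.HovModel()
    e1 = vf.simulate_exam(model, od_grid, 2.5, 7, replicate_index=1)
    e2 = vf.simulate_exam(model, od_grid, 2.5, 8, replicate_index=2)
    truth = vf.average_truth([e1, e2])
    return e1, e2, truth
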