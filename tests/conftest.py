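import numpy as np
import pytest

from benthoscan.config import RunConfig


@pytest.fixture(scope="session")
def cfg() -> RunConfig:
    return RunConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_polygon(rng: np.random.Generator, n_vertices: int = 12) -> np.ndarray:
    """Simple star-shaped polygon: random radii at sorted angles about a centre."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = rng.uniform(5.0, 40.0, n_vertices)
    centre = rng.uniform(50, 100, 2)
    pts = np.column_stack(
        [centre[0] + radii * np.sin(angles), centre[1] + radii * np.cos(angles)]
    )
    return pts
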