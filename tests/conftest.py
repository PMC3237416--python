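import numpy as np
import pytest

from adrcat import RatingsMatrix, default_tree


@pytest.fixture(scope="session")
def tree():
    return default_tree()


@pytest.fixture()
def rng():
    return np.random.default_rng(20111214)


@pytest.fixture()
def small_matrix():
    """6 cases x 3 raters with one missing cell and all four categories."""
    codes = np.array(
        [
            [1, 1, 2],
            [2, 2, 2],
            [3, 4, 3],
            [4, 4, 4],
            [2, 3, np.nan],
            [3, 3, 3],
        ]
    )
    return RatingsMatrix.from_codes(codes)


@pytest.fixture()
def panel_matrix(rng):
    """40 cases x 7 raters, moderately concordant, no missing cells."""
    latent = rng.integers(1, 5, size=40)
    noise = rng.integers(-1, 2, size=(40, 7))
    return RatingsMatrix.from_codes(np.clip(latent[:, None] + noise, 1, 4).astype(float))
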