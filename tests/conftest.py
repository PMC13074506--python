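import numpy as np
import pytest

from teaspec import SyntheticConfig, generate_dataset
from teaspec.models import CVConfig


@pytest.fixture(scope="session")
def small_table():
    """12 samples/season x 3 seasons x 3 states = 108 rows, fixed seed."""
    return generate_dataset(SyntheticConfig(samples_per_season=12, seed=42))


@pytest.fixture(scope="session")
def fresh_spring(small_table):
    return small_table.select(season="spring", state="fresh")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def correlated_index_matrix(n, rng, n_cols=100, noise=0.3):
    """Synthetic stand-in for a screened-index matrix: every column carries
    the latent signal with |r| ~ 0.6-0.95, as screened indices do."""
    s = rng.normal(size=n)
    load = rng.uniform(0.6, 0.95, size=n_cols) * rng.choice([-1.0, 1.0], size=n_cols)
    cols = load * s[:, None] + np.sqrt(1.0 - load**2) * rng.normal(size=(n, n_cols))
    y = 22.0 + 2.0 * s + noise * rng.normal(size=n)
    return cols, y


@pytest.fixture()
def cv3():
    return CVConfig(n_folds=3, seed=9)
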