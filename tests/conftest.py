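import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fegsnet.physchem import load_default_table
from fegsnet.sequence_io import LabeledDataset, ProteinSequence
from fegsnet.synthetic import GeneratorConfig, generate_dataset

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def default_table():
    return load_default_table()


@pytest.fixture(scope="session")
def small_table(default_table):
    """First 6 properties: same code paths, fast."""
    return default_table.subset(6)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Short two-class dataset for featurizer plumbing tests."""
    data = generate_dataset(
        GeneratorConfig(n_pos=5, n_neg=5, length_range=(30, 60), effect=0.5, seed=7)
    )
    return data


@pytest.fixture()
def gaussian_problem():
    """Cheap, separable numeric classification problem for cascade tests."""
    rng = np.random.default_rng(11)
    n = 30
    X = np.vstack(
        [rng.normal(0.0, 1.0, (n, 8)), rng.normal(2.5, 1.0, (n, 8))]
    )
    y = np.array([0] * n + [1] * n)
    return X, y


def make_sequences(n, rng, min_len=20, max_len=60):
    from fegsnet.sequence_io import AMINO_ACIDS

    out = []
    for i in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        out.append(
            ProteinSequence(
                f"s{i}", "".join(rng.choice(list(AMINO_ACIDS), size=length))
            )
        )
    return out
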