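import numpy as np
import pytest

import radcurve as rc
from radcurve.tps_io import stack_configurations


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def unit_circle_outline():
    t = np.linspace(0, 2 * np.pi, 100, endpoint=False)
    return np.column_stack([np.cos(t), np.sin(t)])


@pytest.fixture(scope="session")
def two_group_dataset():
    """Synthetic two-group outlines with a clear mean-shape offset."""
    model = rc.OutlineModel(
        delta=0.08, noise_sd=0.02, n_per_group=8, seed=1,
        group_names=["sprawled", "parasagittal"],
    )
    records, table = rc.generate_outlines(model)
    return stack_configurations(records), table["group"].to_numpy()


@pytest.fixture(scope="session")
def aligned_toy(two_group_dataset):
    X, labels = two_group_dataset
    result = rc.gpa(X)
    return result, labels


def random_configuration(rng, k=21, spread=1.0):
    return rng.normal(0.0, spread, size=(k, 2))


def similarity_transform(pts, theta=0.0, scale=1.0, shift=(0.0, 0.0)):
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    return scale * pts @ rot.T + np.asarray(shift)
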