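import numpy as np
import pytest

from caco2qspr.datatable import DescriptorTable
from caco2qspr.synthetic import SyntheticSpec, generate


@pytest.fixture
def linear_table():
    """Noiseless linear table: y exactly linear in a 5-descriptor support."""
    table, truth = generate(SyntheticSpec(
        n=100, p=12, support_size=5, noise_sd=0.0, nonlinear_fraction=0.0, seed=7))
    return table, truth


@pytest.fixture
def noisy_table():
    """Realistic small table: sparse signal, mild nonlinearity, noise."""
    table, truth = generate(SyntheticSpec(
        n=200, p=15, support_size=5, noise_sd=0.3, nonlinear_fraction=0.3, seed=11))
    return table, truth


def make_table(X, y, prefix="d"):
    X = np.asarray(X, dtype=float)
    return DescriptorTable(
        ids=[f"c{i+1}" for i in range(X.shape[0])],
        descriptor_names=[f"{prefix}{j+1}" for j in range(X.shape[1])],
        X=X,
        y=np.asarray(y, dtype=float),
    )
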