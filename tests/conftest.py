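import numpy as np
import pandas as pd
import pytest

from fatebind.normalization import SignalMatrix
from fatebind.synth import GeneratorConfig, generate_workspace


def small_config(seed=5, **overrides):
    """A scaled-down generator config for fast unit tests."""
    base = dict(
        n_sites={
            "A_specific_acquired": 60, "A_specific_retained": 60,
            "B_specific_acquired": 60, "B_specific_retained": 60,
            "lineage": 30, "housekeeping": 30, "progenitor_specific": 30,
        },
        chrom_lengths={"chr1": 250_000, "chr2": 250_000},
        n_cells_per_branch=80,
        n_background_genes=400,
    )
    base.update(overrides)
    return GeneratorConfig(seed=seed, **base)


@pytest.fixture(scope="session")
def small_workspace():
    return generate_workspace(small_config())


@pytest.fixture(scope="session")
def default_workspace():
    """The full-size default study conditions; shared across slow tests."""
    return generate_workspace(GeneratorConfig(seed=1))


@pytest.fixture()
def toy_matrix():
    """A 4-site x 4-sample matrix with hand-set values and metadata."""
    values = pd.DataFrame(
        np.array([[10.0, 20.0, 0.0, 5.0],
                  [100.0, 200.0, 50.0, 25.0],
                  [1.0, 2.0, 3.0, 4.0],
                  [0.0, 0.0, 0.0, 0.0]]),
        index=[f"s{i}" for i in range(4)],
        columns=["a1", "a2", "b1", "b2"],
    )
    samples = pd.DataFrame(
        {
            "condition": ["A", "A", "B", "B"],
            "timepoint": ["t", "t", "t", "t"],
            "replicate": [1, 2, 1, 2],
            "depth": [1e6, 2e6, 5e5, 2.5e5],
            "frip": [0.5, 0.5, 0.4, 0.4],
        },
        index=values.columns,
    )
    return SignalMatrix(values=values, samples=samples)
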