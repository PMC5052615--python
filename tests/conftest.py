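import numpy as np
import pandas as pd
import pytest

from mgskit.differential import differential_features
from mgskit.io import AbundanceMatrix, CohortLabels
from mgskit.profiling import gene_relative_abundance
from mgskit.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic two-cohort dataset at the default study conditions."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_abundance(default_dataset):
    ds = default_dataset
    return gene_relative_abundance(ds.counts, ds.genes)


@pytest.fixture(scope="session")
def default_diff(default_dataset, default_abundance):
    return differential_features(default_abundance, default_dataset.labels)


def make_abundance(values, feature_ids=None, sample_ids=None, relative=False):
    values = np.asarray(values, dtype=float)
    feature_ids = feature_ids or [f"f{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return AbundanceMatrix(
        pd.DataFrame(values, index=feature_ids, columns=sample_ids),
        relative=relative,
    )


def make_labels(groups):
    return CohortLabels(
        pd.Series(list(groups), index=[f"s{j}" for j in range(len(groups))])
    )
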