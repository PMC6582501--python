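import numpy as np
import pandas as pd
import pytest

from ctcpanel import CountMatrix, CriterionParams, table2_fixture


@pytest.fixture(scope="session")
def table2():
    return table2_fixture()


@pytest.fixture
def params():
    return CriterionParams()


def random_toy_matrix(rng, max_genes=10, n_samples=6):
    """Small random CountMatrix with >=1 tumor and >=1 control sample.

    Counts are small integers so ties and QC-floor removals are common.
    """
    n_genes = int(rng.integers(3, max_genes + 1))
    n_tumor = int(rng.integers(1, n_samples))
    n_control = n_samples - n_tumor
    counts = rng.integers(0, 30, size=(n_genes, n_samples))
    # guarantee every sample retains at least one gene after the QC floor
    counts[0, :] = np.maximum(counts[0, :], 5)
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    groups = pd.Series(
        ["tumor"] * n_tumor + ["control"] * n_control, index=samples
    )
    return CountMatrix(pd.DataFrame(counts, index=genes, columns=samples), groups)
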