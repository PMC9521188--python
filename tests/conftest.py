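import numpy as np
import pandas as pd
import pytest

from ptiseq import (
    CountMatrix,
    TimeCourseDesign,
    default_truth,
    simulate_counts,
)


@pytest.fixture(scope="session")
def design_small():
    return TimeCourseDesign(n_genes=300)


@pytest.fixture(scope="session")
def truth_small(design_small):
    return default_truth(design_small, seed=11)


@pytest.fixture(scope="session")
def counts_small(design_small, truth_small):
    cm, manifest = simulate_counts(design_small, truth_small)
    return cm, manifest


def two_group_counts(n_genes, mu, phi, n_per_group=3, seed=0, mu_alt=None, n_signal=None):
    """NB counts for a 0 h vs 3 h two-group layout.

    With ``mu_alt`` the first ``n_signal`` genes (default: all) get mean
    ``mu_alt`` in the 3 h group; keep n_signal << n_genes so TMM
    normalization is not confounded by a global shift.
    """
    rng = np.random.default_rng(seed)
    r = 1.0 / phi
    y0 = rng.negative_binomial(r, r / (r + mu), size=(n_genes, n_per_group))
    y1 = rng.negative_binomial(r, r / (r + mu), size=(n_genes, n_per_group))
    if mu_alt is not None:
        ns = n_genes if n_signal is None else n_signal
        y1[:ns] = rng.negative_binomial(r, r / (r + mu_alt), size=(ns, n_per_group))
    y = np.hstack([y0, y1])
    cols = [f"s{i}" for i in range(2 * n_per_group)]
    sheet = pd.DataFrame(
        {
            "timepoint_h": [0.0] * n_per_group + [3.0] * n_per_group,
            "replicate": list(range(1, n_per_group + 1)) * 2,
        },
        index=cols,
    )
    genes = [f"g{i:05d}" for i in range(n_genes)]
    return CountMatrix(pd.DataFrame(y, index=genes, columns=cols), sheet)
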