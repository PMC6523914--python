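import numpy as np
import pandas as pd
import pytest

from dmrscan import MethylationDataset


def make_dataset(meth, coverage, groups, positions=None, chromosome="chr1",
                 covariates=None):
    """Construct a small dataset from plain lists/arrays."""
    meth = np.asarray(meth)
    coverage = np.asarray(coverage)
    n, m = meth.shape
    if positions is None:
        positions = 1 + np.arange(m)
    sites = pd.DataFrame({"chromosome": chromosome,
                          "position": np.asarray(positions, dtype=np.int64)})
    samples = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "group": list(groups),
    })
    names = ()
    if covariates is not None:
        for k, v in covariates.items():
            samples[k] = v
        names = tuple(covariates)
    return MethylationDataset(sites=sites, samples=samples, meth=meth,
                              coverage=coverage, covariate_names=names)


@pytest.fixture
def four_sample_dataset():
    """2 cases (8/10, 6/10) vs 2 controls (2/10, 0/10), one site each.

    Pooled rate 0.4; adjusted group sums r_A = 6, r_U = -6, delta = 0.6.
    """
    return make_dataset(
        meth=[[8], [6], [2], [0]],
        coverage=[[10], [10], [10], [10]],
        groups=["A", "A", "U", "U"],
    )


@pytest.fixture
def two_site_dataset():
    """Same counts replicated at two sites 1 bp apart: delta = (0.6, 0.6)."""
    return make_dataset(
        meth=[[8, 8], [6, 6], [2, 2], [0, 0]],
        coverage=np.full((4, 2), 10),
        groups=["A", "A", "U", "U"],
        positions=[1, 2],
    )
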