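import numpy as np
import pandas as pd
import pytest

from herdstat.io import GenotypeDataset


def make_dataset(dosages, chrom=None, pos=None, groups=None, country=None):
    """Assemble a GenotypeDataset from plain arrays with sensible defaults."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    markers = pd.DataFrame(
        {
            "id": [f"m{j + 1}" for j in range(m)],
            "chrom": chrom if chrom is not None else ["chr1"] * m,
            "pos": pos if pos is not None else 1000 * (1 + np.arange(m)),
        }
    )
    samples = pd.DataFrame(
        {
            "id": [f"s{i + 1}" for i in range(n)],
            "group": groups if groups is not None else ["g1"] * n,
        }
    )
    if country is not None:
        samples["country"] = country
    return GenotypeDataset(dosages, markers, samples)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def small_panel(rng):
    """60 samples x 40 markers on two chromosomes, two groups, no missing."""
    dosages = rng.binomial(2, 0.4, (60, 40)).astype(float)
    return make_dataset(
        dosages,
        chrom=["chr1"] * 25 + ["chr2"] * 15,
        pos=list(1000 * (1 + np.arange(25))) + list(1000 * (1 + np.arange(15))),
        groups=["A"] * 30 + ["B"] * 30,
    )
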