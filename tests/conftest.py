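import numpy as np
import pandas as pd
import pytest

from rnaconcord import ExpressionMatrix, MultiSourceDataset, Unit


def make_matrix(values, unit=Unit.TPM, source="A", genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    samples = samples or [f"s{i + 1}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, index=genes, columns=samples)
    return ExpressionMatrix(data=df, unit=unit, source=source)


def random_tpm_dataset(rng, n_sources=None, n_genes=None, n_samples=None):
    """A random multi-source TPM-unit dataset with values spanning the DQ cuts."""
    n_sources = n_sources or rng.integers(2, 6)
    n_genes = n_genes or rng.integers(3, 21)
    n_samples = n_samples or rng.integers(3, 31)
    genes = [f"g{i + 1}" for i in range(n_genes)]
    samples = [f"s{i + 1}" for i in range(n_samples)]
    mats = []
    for s in range(n_sources):
        vals = rng.uniform(0, 64, size=(n_genes, n_samples))
        df = pd.DataFrame(vals, index=genes, columns=samples)
        mats.append(ExpressionMatrix(data=df, unit=Unit.TPM, source=f"P{s + 1}"))
    return MultiSourceDataset(mats)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_fpkm():
    return make_matrix([[1.0, 5.0], [3.0, 15.0], [4.0, 0.0]], unit=Unit.FPKM)
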