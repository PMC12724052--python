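import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from adipoproteo.io_formats import IntensityMatrix

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_matrix(values, samples=None, genes=None, peptides=None,
                reverse=None, contaminant=None, normalized=False):
    """Build a small IntensityMatrix from a 2-D array-like."""
    vals = np.asarray(values, dtype=float)
    n, p = vals.shape
    samples = samples or [f"S{j + 1}" for j in range(p)]
    accs = [f"P{i + 1:04d}" for i in range(n)]
    records = pd.DataFrame(
        {
            "accession": accs,
            "gene": genes if genes is not None else [f"G{i + 1}" for i in range(n)],
            "n_unique_peptides": peptides if peptides is not None else [2] * n,
            "is_reverse": reverse if reverse is not None else [False] * n,
            "is_contaminant": contaminant if contaminant is not None else [False] * n,
        }
    )
    values_df = pd.DataFrame(vals, index=pd.Index(accs, name="accession"), columns=samples)
    return IntensityMatrix(records=records, values=values_df, normalized=normalized)


@pytest.fixture
def toy_matrix():
    """3 proteins x 3 samples with hand-checkable values."""
    return make_matrix([[1.0, 2.0, 3.0], [10.0, 20.0, 30.0], [5.0, 5.0, 5.0]])


@pytest.fixture
def matrix_factory():
    return make_matrix
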