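import numpy as np
import pandas as pd
import pytest

from popstruct.cohort import GenotypeMatrix


def make_cohort(calls, sample_ids=None, chrom=None, pos=None, ids=None,
                ref=None, alt=None, **sample_cols):
    """Build a GenotypeMatrix from a raw call array with default metadata."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    sample_ids = sample_ids or [f"s{i + 1}" for i in range(n)]
    samples = pd.DataFrame({"id": sample_ids, **sample_cols})
    variants = pd.DataFrame(
        {
            "id": ids or [f"rs{j + 1}" for j in range(m)],
            "chrom": chrom or ["1"] * m,
            "pos": pos if pos is not None else [(j + 1) * 1000 for j in range(m)],
            "ref": ref or ["A"] * m,
            "alt": alt or ["G"] * m,
        }
    )
    return GenotypeMatrix(samples=samples, variants=variants, calls=calls)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_cohort():
    # 3 samples x 4 variants, one missing call
    return make_cohort([[0, 1, 2, 0], [1, 1, 0, -1], [2, 0, 1, 2]])
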