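import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from refstab.qpcr import CtMatrix


def make_ct_matrix(values, groups=None, genes=None, samples=None, efficiency=None):
    """Build a CtMatrix from a 2-d array; default one group for everything."""
    values = np.asarray(values, dtype=float)
    k, n = values.shape
    genes = genes or [f"G{i + 1:02d}" for i in range(k)]
    samples = samples or [f"S{j + 1:02d}" for j in range(n)]
    if groups is None:
        groups = ["grp"] * n
    data = pd.DataFrame(values, index=genes, columns=samples)
    return CtMatrix(
        data=data, groups=pd.Series(groups, index=samples), efficiency=efficiency
    )


def random_ct_matrix(rng, k=6, n=8, n_groups=2, sample_sd=0.6, gene_sd=0.4):
    """A random but realistically structured Ct matrix."""
    base = rng.uniform(20, 27, k)
    phi = rng.normal(0, sample_sd, n)
    ct = base[:, None] + phi[None, :] + rng.normal(0, gene_sd, (k, n))
    sizes = [n // n_groups] * n_groups
    sizes[-1] += n - sum(sizes)
    groups = [f"g{i + 1}" for i, s in enumerate(sizes) for _ in range(s)]
    return make_ct_matrix(ct, groups=groups)


@pytest.fixture
def rng():
    return np.random.default_rng(20230612)


@pytest.fixture
def small_matrix():
    """3 genes x 3 samples with hand-computable pairwise SDs."""
    return make_ct_matrix(
        [[20, 20, 20], [22, 23, 24], [25, 25, 26]], genes=["A", "B", "C"]
    )
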