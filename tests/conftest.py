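import numpy as np
import pandas as pd
import pytest

from gltdseq.io import CountMatrix


def make_count_matrix(counts, gene_ids=None, sample_ids=None, condition=None,
                      cohort="c1", treatment="vehicle"):
    """Build a CountMatrix from a plain array with minimal metadata."""
    counts = np.asarray(counts)
    n_genes, n_samples = counts.shape
    gene_ids = gene_ids or [f"g{i + 1}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"s{j + 1}" for j in range(n_samples)]
    if condition is None:
        half = n_samples // 2
        condition = ["control"] * half + ["ELS"] * (n_samples - half)
    meta = pd.DataFrame(
        {"cohort": cohort, "condition": condition, "treatment": treatment},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    frame = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    return CountMatrix(frame, meta)


@pytest.fixture
def two_sample_fixture():
    """The canonical median-of-ratios fixture: B = sqrt(2)-scaled A."""
    return make_count_matrix(np.array([[10, 20], [20, 40], [30, 60]]))


@pytest.fixture
def small_de_table():
    rng = np.random.default_rng(7)
    n = 40
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n)],
            "base_mean": rng.uniform(10, 1000, n),
            "log2fc": rng.normal(0, 1, n),
            "se": rng.uniform(0.1, 0.5, n),
            "pvalue": rng.uniform(0, 1, n),
            "padj": rng.uniform(0, 1, n),
        }
    )
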