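import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mitoskew import CountTable, NormalizedTable

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def tiny_counts() -> CountTable:
    """3 genes x 4 samples, 2 per group."""
    counts = pd.DataFrame(
        {"s1": [100, 0, 40], "s2": [120, 2, 35], "s3": [10, 90, 50], "s4": [14, 80, 45]},
        index=["MB", "CA3", "ACE"],
    )
    groups = pd.Series(["A", "A", "B", "B"], index=["s1", "s2", "s3", "s4"])
    return CountTable(counts=counts, groups=groups, group_levels=("A", "B"))


def make_normalized(values: np.ndarray, n_a: int, n_b: int,
                    gene_ids=None) -> NormalizedTable:
    """Wrap a raw matrix as a NormalizedTable with groups A/B."""
    values = np.asarray(values, dtype=float)
    samples = [f"A{i}" for i in range(1, n_a + 1)] + [f"B{i}" for i in range(1, n_b + 1)]
    genes = gene_ids or [f"g{i}" for i in range(1, values.shape[0] + 1)]
    frame = pd.DataFrame(values, index=genes, columns=samples)
    groups = pd.Series(["A"] * n_a + ["B"] * n_b, index=samples)
    return NormalizedTable(values=frame, groups=groups, group_levels=("A", "B"))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
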