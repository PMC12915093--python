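import numpy as np
import pytest

from idopnet.io_indices import (
    Combination,
    ExpressionDataset,
    SampleMeta,
    Segment,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def make_meta(n, combination=Combination.AA, segment=Segment.SCION):
    """Minimal valid metadata: 8 time points cycled, replicates numbered."""
    return [
        SampleMeta(f"s{i}", combination, segment, time=float(i % 8), replicate=i // 8)
        for i in range(n)
    ]


@pytest.fixture
def small_dataset(rng):
    values = rng.uniform(0.5, 20.0, size=(50, 10))
    return ExpressionDataset(values, [f"g{j}" for j in range(50)], make_meta(10))
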