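import numpy as np
import pandas as pd
import pytest

from dynprognet import ExpressionDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_dataset(values: np.ndarray, n_per_stage: tuple[int, ...],
                 genes: list[str] | None = None,
                 traits: pd.DataFrame | None = None) -> ExpressionDataset:
    """Wrap a raw matrix into a staged dataset (stages stage1, stage2, ...)."""
    g, s = values.shape
    assert sum(n_per_stage) == s
    genes = genes or [f"G{i:03d}" for i in range(g)]
    samples = [f"S{i:03d}" for i in range(s)]
    stage_of = {}
    order = []
    start = 0
    for k, n in enumerate(n_per_stage, 1):
        label = f"stage{k}"
        order.append(label)
        for j in range(start, start + n):
            stage_of[samples[j]] = label
        start += n
    return ExpressionDataset(
        values=pd.DataFrame(values, index=genes, columns=samples),
        stage_of=stage_of, stage_order=order, traits=traits)


@pytest.fixture
def three_stage_random(rng):
    """40 genes x (12+12+12) pure-noise samples."""
    return make_dataset(rng.standard_normal((40, 36)), (12, 12, 12))
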