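import numpy as np
import pandas as pd
import pytest

from droughtrank.datasets import load_daylily25
from droughtrank.trait_data import TraitMatrix


@pytest.fixture(scope="session")
def daylily():
    return load_daylily25()


def make_tidy(
    genotypes=("G1", "G2"),
    indices=("PH",),
    replicates=3,
    value_fn=None,
):
    """Build a fully crossed tidy frame; values default to a deterministic ramp."""
    if value_fn is None:
        def value_fn(g, ix, cond, rep):
            base = 10.0 * (hash((g, ix)) % 7 + 1) / 7.0 + rep
            return base * (0.8 if cond == "treatment" else 1.0)
    rows = [
        (g, ix, cond, rep, value_fn(g, ix, cond, rep))
        for g in genotypes
        for ix in indices
        for cond in ("control", "treatment")
        for rep in range(1, replicates + 1)
    ]
    return pd.DataFrame(
        rows, columns=["genotype", "index", "condition", "replicate", "value"]
    )


@pytest.fixture
def tiny_matrix():
    return TraitMatrix.from_tidy(make_tidy())


@pytest.fixture
def rng():
    return np.random.default_rng(20260905)
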