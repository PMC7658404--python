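import numpy as np
import pandas as pd
import pytest

from reopairs.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture
def tiny_expr():
    """3 genes x 4 samples with hand-checkable orderings."""
    return pd.DataFrame(
        [
            [5.0, 1.0, 3.0, 2.0],
            [2.0, 4.0, 1.0, 6.0],
            [1.0, 2.0, 2.0, 2.0],
        ],
        index=["gA", "gB", "gC"],
        columns=["s1", "s2", "s3", "s4"],
    )


@pytest.fixture
def tiny_labels():
    return pd.Series([1, 1, 2, 2], index=["s1", "s2", "s3", "s4"], name="group")


@pytest.fixture(scope="session")
def reference_cohort():
    """The reference training cohort: 2000 genes, 30 planted pairs, 60+120."""
    cfg = SyntheticConfig(seed=1)
    expr, labels, truth = generate_cohort(cfg)
    return expr, labels, truth


@pytest.fixture(scope="session")
def small_cohort():
    """A scaled-down cohort for fast pipeline-level tests."""
    cfg = SyntheticConfig(
        n_genes=300, n_planted_pairs=10, n_pos=30, n_neg=60, seed=7
    )
    expr, labels, truth = generate_cohort(cfg)
    return expr, labels, truth


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
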