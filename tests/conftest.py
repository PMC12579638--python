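import numpy as np
import pandas as pd
import pytest

from lrnet.io import build_rank_matrix
from lrnet.synthetic import SimulationConfig, simulate_interaction_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted-signal cohort reused by read-only tests."""
    cfg = SimulationConfig(
        n_samples_per_group=8,
        n_cell_types=3,
        n_lr_pairs=80,
        n_discriminative=5,
        rank_shift=40.0,
        missing_rate=0.15,
        seed=7,
    )
    records, annotations, truth = simulate_interaction_cohort(cfg)
    return cfg, records, annotations, truth


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    _, records, annotations, _ = small_cohort
    return build_rank_matrix(records, annotations)


@pytest.fixture()
def separable_data():
    """Two spherical Gaussian classes separated by 5 pooled sd (d=10, n=40)."""
    rng = np.random.default_rng(42)
    y = np.array(["A"] * 20 + ["B"] * 20)
    X = rng.normal(0.0, 1.0, size=(40, 10))
    X[y == "B"] += 5.0 / np.sqrt(10)
    return pd.DataFrame(X, columns=[f"f{j}" for j in range(10)]), y
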