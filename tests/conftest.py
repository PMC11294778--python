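from datetime import date

import numpy as np
import pytest

import glycontrol as g
from glycontrol import nn


@pytest.fixture(scope="session")
def small_cohort():
    """60 patients over four years: enough to exercise every stage cheaply."""
    cfg = g.CohortConfig(n_patients=60, start_date=date(2011, 1, 1), end_date=date(2015, 12, 31), seed=5)
    return g.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_instances(small_cohort):
    return g.build_instances(small_cohort, 2013)


@pytest.fixture(scope="session")
def tiny_arch():
    return nn.ArchConfig(d_model=16, n_heads=2, d_ff=32, encoder_layers=2, decoder_layers=2)


@pytest.fixture(scope="session")
def tiny_params(tiny_arch):
    return nn.init_params(tiny_arch, np.random.default_rng(0))


@pytest.fixture(scope="session")
def random_series():
    """A batch of random weekly grids with realistic sparsity."""
    rng = np.random.default_rng(42)
    values = rng.normal(7.1, 1.1, (8, 53))
    mask = rng.random((8, 53)) < 0.15
    mask[:, 26] = True  # every series observes at least one week
    mask[:, 52] = True
    return values, mask


@pytest.fixture(scope="session")
def tiny_fitted(small_instances):
    """A deliberately under-trained tiny model: cheap, but fully fitted
    (threshold, attention, persistence all work)."""
    X, y = g.instances_to_xy(small_instances)
    est = g.HbA1cTransformer(
        encoder_layers=1, decoder_layers=1, heads=2, hidden_size=16, ffn_hidden=32,
        batch_size=32, iterations=30, pretrain_iterations=30, random_state=3,
    )
    return est.fit(X, y), X, y
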