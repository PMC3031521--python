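import numpy as np
import pytest

import mitoevidence as me


@pytest.fixture
def path_net():
    """The path graph a - b - c."""
    return me.InteractionNetwork(["a", "b", "c"], [("a", "b"), ("b", "c")])


@pytest.fixture(scope="session")
def small_config():
    """A desk-scale cohort with planted structure in every data channel."""
    return me.SynthConfig(
        n_pos=60,
        n_neg=120,
        n_unknown=20,
        expression=me.ExpressionConfig(n_datasets=3, n_samples=30, rho=0.8),
        network=me.NetworkConfig(
            n_modules=4, module_size=15, p_within=0.9, p_background=0.01
        ),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_catalog(small_config):
    return me.generate_gold_standard(small_config)


@pytest.fixture(scope="session")
def small_calls(small_config, small_catalog):
    return me.generate_predictor_calls(
        small_catalog, small_config.profiles, seed=small_config.seed
    )


@pytest.fixture(scope="session")
def paper_scale_catalog():
    """Gold standard at the published training-set sizes (806 / 1,464)."""
    return me.generate_gold_standard(me.SynthConfig(n_pos=806, n_neg=1464, seed=11))


def brute_force_auc(scores, labels):
    """Mann-Whitney pair statistic with ties counted one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for s in pos:
        wins += (s > neg).sum() + 0.5 * (s == neg).sum()
    return wins / (len(pos) * len(neg))
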