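import numpy as np
import pytest

from samplingcost import GeneratorConfig, LinkingFunction, generate_rt_dataset, make_weightset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_weightset():
    return make_weightset([0.4, 0.3, 0.2, 0.1])


def random_weightsets(n_sets, k_values, seed):
    """Random positive WeightSets spanning a mix of scales."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_sets):
        k = int(rng.choice(k_values))
        w = rng.gamma(shape=1.0, scale=1.0, size=k + 1) + 1e-3
        out.append(make_weightset(w))
    return out


@pytest.fixture
def linear_link_data():
    """Modest-noise linear-link dataset at the default study design."""
    cfg = GeneratorConfig(
        linking=LinkingFunction.linear(250.0, 25.0),
        seed=77,
    )
    return cfg, generate_rt_dataset(cfg)
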