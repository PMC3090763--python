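import numpy as np
import pytest

from rbninfer import GeneratorConfig, random_network, random_trajectory, yeast_fixture


@pytest.fixture(scope="session")
def yeast():
    """Packaged budding-yeast cell-cycle benchmark."""
    return yeast_fixture()


@pytest.fixture()
def small_cfg():
    """Generator config small enough for exhaustive cross-checks."""
    def make(seed, n=4, m=6, noise=0.0, density=0.4):
        return GeneratorConfig(
            n=n, edge_density=density, sign_balance=0.5, selfdeg_prob=0.5,
            trajectory_length=m, noise_flip_prob=noise, seed=seed,
        )
    return make


@pytest.fixture()
def random_instance(small_cfg):
    """(network, trajectory) pair drawn from a seed."""
    def make(seed, **kw):
        cfg = small_cfg(seed, **kw)
        net = random_network(cfg)
        return net, random_trajectory(net, cfg)
    return make
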