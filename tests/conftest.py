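import numpy as np
import pytest

import emdeblur as ed


@pytest.fixture(scope="session")
def tiny_gen_cfg() -> ed.GeneratorConfig:
    """Smallest legal generator for CPU tests."""
    return ed.GeneratorConfig(base_channels=4, channel_multipliers=(1, 1, 1, 2, 2),
                              residual_blocks_per_scale=1)


@pytest.fixture(scope="session")
def tiny_disc_cfg() -> ed.DiscriminatorConfig:
    return ed.DiscriminatorConfig(n_layers=4, base_channels=8)


@pytest.fixture(scope="session")
def phantom_96() -> ed.Phantom:
    return ed.generate_phantom(ed.PhantomSpec(n_axons=5, height=96, width=96, seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def numerical_gradient(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar function of an array."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g
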