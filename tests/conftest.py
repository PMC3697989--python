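import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_stable_ar(order: int, rng: np.random.Generator,
                   max_modulus: float = 0.95) -> np.ndarray:
    """Random stationary AR coefficients via bounded-modulus pole pairs."""
    assert order % 2 == 0
    mods = rng.uniform(0.2, max_modulus, order // 2)
    angs = rng.uniform(0.05, np.pi - 0.05, order // 2)
    poles = np.concatenate([mods * np.exp(1j * angs), mods * np.exp(-1j * angs)])
    return -np.real(np.poly(poles))[1:]
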