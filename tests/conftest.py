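import numpy as np
import pytest

import seedpoint as sp


@pytest.fixture(scope="session")
def tiny_run_config():
    """Small CPU-trainable configuration used across tests."""
    return sp.RunConfig(
        preset="p2pnet", width_multiplier=0.125, fused_channels=32,
        head_channels=32, epochs=2, rng_seed=0,
    )


@pytest.fixture(scope="session")
def small_image():
    rng = np.random.default_rng(0)
    return rng.integers(0, 256, (64, 64, 3), dtype=np.uint8)


@pytest.fixture(scope="session")
def synth_samples():
    """Six small synthetic samples with annotations."""
    cfg = sp.SynthConfig(image_size=(96, 96), seeds_per_image=(5, 15), rng_seed=2)
    return sp.generate_samples(cfg, 6)


def numerical_gradient(f, x, eps=1e-3):
    """Central-difference gradient of scalar f at array x (float64)."""
    x = x.astype(np.float64)
    grad = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f(x)
        x[i] = orig - eps
        fm = f(x)
        x[i] = orig
        grad[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return grad
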