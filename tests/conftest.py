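import numpy as np
import pytest

from masunet import PhantomConfig, generate_phantom_dataset


def numerical_gradient(f, arr: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central finite differences of scalar-valued f() w.r.t. arr in place."""
    grad = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = arr[idx]
        arr[idx] = orig + eps
        fp = f()
        arr[idx] = orig - eps
        fm = f()
        arr[idx] = orig
        grad[idx] = (fp - fm) / (2 * eps)
    return grad


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_volumes():
    """Four small labeled phantom volumes (3 slices, 32x32)."""
    cfg = PhantomConfig(num_volumes=4, slices_per_volume=3, slice_size=32,
                        seed=11)
    return generate_phantom_dataset(cfg)


@pytest.fixture(scope="session")
def phantom_volumes():
    """Ten labeled phantom volumes at the generator's default geometry."""
    cfg = PhantomConfig(num_volumes=10, slices_per_volume=5, slice_size=64,
                        seed=3)
    return generate_phantom_dataset(cfg)
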