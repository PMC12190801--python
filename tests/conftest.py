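import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from thoraxcomp import PhantomSpec, generate_phantom, run_segmentation

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_phantom():
    """Zero-noise default phantom: (CTVolume, OrganMaskSet, GroundTruthComposition)."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def default_segmentation(default_phantom):
    """Full pipeline output on the zero-noise default phantom."""
    volume, masks, _ = default_phantom
    return run_segmentation(volume, masks)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)


def random_blob(rng, shape=(32, 32), n_seeds=4, radius=6):
    """A random 2-D organ-like mask: union of filled discs."""
    mask = np.zeros(shape, dtype=bool)
    gx, gy = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    for _ in range(n_seeds):
        cx, cy = rng.integers(radius, shape[0] - radius), rng.integers(radius, shape[1] - radius)
        r = rng.integers(2, radius)
        mask |= (gx - cx) ** 2 + (gy - cy) ** 2 <= r**2
    return mask
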