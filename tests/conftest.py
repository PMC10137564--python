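import numpy as np
import pytest

from ctrseg.phantom import PhantomParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def exact_params():
    """Noise-free, jitter-free geometry whose CTR is 0.375 in closed form."""
    return PhantomParams(
        width_px=256, height_px=256,
        lung_outer_left_frac=0.10, lung_outer_right_frac=0.90,
        heart_halfwidth_frac=0.15,
        noise_sd=0.0, blur_sigma_px=0.0, jitter_sd=0.0,
    )


@pytest.fixture
def desk_params():
    """Small jittered phantoms with every confounder, as used end to end."""
    return PhantomParams(
        width_px=64, height_px=64, jitter_sd=0.02,
        artifact_flags=frozenset({"catheter", "pacemaker", "effusion"}),
    )


def random_mask(rng, h=None, w=None, ensure_all_classes=False):
    """A random {0,1,2} mask, optionally guaranteed to contain every class."""
    h = h or int(rng.integers(4, 65))
    w = w or int(rng.integers(4, 65))
    mask = rng.integers(0, 3, size=(h, w)).astype(np.uint8)
    if ensure_all_classes:
        mask[rng.integers(h), rng.integers(w)] = 1
        mask[rng.integers(h), rng.integers(w)] = 2
    return mask
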