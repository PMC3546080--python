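import numpy as np
import pytest

from sbpquant import PhantomSpec, SegmentedImage, generate_phantom


def make_image(mask, pitch=1.0):
    return SegmentedImage(mask=np.asarray(mask, dtype=bool), pixel_pitch_um=pitch)


@pytest.fixture
def blank_384():
    return make_image(np.zeros((384, 384), bool), pitch=400.0 / 384.0)


@pytest.fixture(scope="session")
def small_phantoms():
    """A handful of small, quick phantoms shared across tests."""
    out = []
    for seed in range(5):
        spec = PhantomSpec(n_fibres=3, width_px=128, height_px=128, seed=seed)
        out.append(generate_phantom(spec))
    return out
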