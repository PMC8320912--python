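import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from epgkit.palatogram import PalateLayout, PalatogramFrame, PalatogramSequence
from epgkit.synthetic import PhantomSpec, build_phantom, planted_offsets
from epgkit.ct import segment_palate


@pytest.fixture(scope="session")
def layout():
    return PalateLayout.reading62()


@pytest.fixture
def random_frames(layout):
    """Factory: n random frames on the default layout with a given fill."""

    def make(n, p=0.3, seed=0):
        rng = np.random.default_rng(seed)
        frames = (rng.random((n, layout.n_rows, layout.max_width)) < p).astype(np.uint8)
        frames[:, ~layout.valid] = 0
        return frames

    return make


@pytest.fixture
def symmetric_frame(layout):
    """A mirror-symmetric frame: full outer ring of the palate active."""
    act = np.zeros((layout.n_rows, layout.max_width), np.uint8)
    for r in range(layout.n_rows):
        cols = np.flatnonzero(layout.valid[r])
        act[r, cols[0]] = act[r, cols[-1]] = 1
    act[0, layout.valid[0]] = 1
    act[-1, layout.valid[-1]] = 1
    return PalatogramFrame(act, layout)


@pytest.fixture(scope="session")
def phantom_zero():
    """Small noisy phantom with perfectly mirror-symmetric electrodes."""
    spec = PhantomSpec.small(seed=3)
    vol, truth = build_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def phantom_zero_segmented(phantom_zero):
    spec, vol, truth = phantom_zero
    return spec, truth, segment_palate(vol, plane_offset=spec.plane_x)


@pytest.fixture(scope="session")
def phantom_planted():
    """Small phantom with planted left-side offsets of known magnitudes."""
    spec0 = PhantomSpec.small(seed=3)
    offsets = planted_offsets(spec0, mean_mag=4.5, sd_mag=1.8, seed=7)
    spec = PhantomSpec.small(seed=3, offsets=offsets)
    vol, truth = build_phantom(spec)
    return spec, offsets, vol, truth


@pytest.fixture(scope="session")
def phantom_planted_segmented(phantom_planted):
    spec, offsets, vol, truth = phantom_planted
    return spec, offsets, truth, segment_palate(vol, plane_offset=spec.plane_x)
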