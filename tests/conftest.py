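import numpy as np
import pytest

from osteotile import synth


@pytest.fixture(scope="session")
def archetypes():
    return synth.default_archetypes()


@pytest.fixture(scope="session")
def one_tile_per_class(archetypes):
    """A single rendered tile of each archetype, shared across tests."""
    return {lab: synth.synth_tile(archetypes[lab], seed=7, tin=f"F_{lab}")
            for lab in synth.CLASS_LABELS}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_blob_binary(rng, size=64, n_blobs=12, r_max=6):
    """Random binary image of overlapping disks, for labeling/Euler oracles."""
    img = np.zeros((size, size), dtype=bool)
    for _ in range(n_blobs):
        r = rng.uniform(1.5, r_max)
        cy, cx = rng.uniform(0, size, 2)
        yy, xx = np.mgrid[:size, :size]
        img |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    return img
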