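import numpy as np
import pytest

from mcsquant import random_blob_scene, render_scene


@pytest.fixture
def filled_square():
    """5x5 filled square centered in a 9x9 grid."""
    m = np.zeros((9, 9), dtype=bool)
    m[2:7, 2:7] = True
    return m


def make_scene(seed, shape=(96, 96), n_mito=4, er_density=0.7):
    spec = random_blob_scene(n_mito=n_mito, er_density=er_density, rng_seed=seed,
                             shape=shape)
    mito, er, _ = render_scene(spec)
    return mito, er


def profiles_equal(a, b):
    return (np.array_equal(a.length_per_bin, b.length_per_bin)
            and a.len_con == b.len_con
            and a.n_con == b.n_con
            and a.n_segments == b.n_segments
            and a.len_mito == b.len_mito)
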