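import numpy as np
import pytest

import thinslice as ts


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_volume(rng):
    """A small random CT volume in HU with anisotropic spacing."""
    vox = rng.uniform(-1000, 400, size=(16, 12, 10)).astype(np.float32)
    return ts.CTVolume(vox, spacing=(4.0, 0.7, 0.7))


@pytest.fixture(scope="session")
def lungrads_table():
    """The pinned v2022 volume-threshold table used by all category tests."""
    table = ts.LungRADSTable.default()
    assert table.version == "v2022-simplified"
    return table


@pytest.fixture(scope="session")
def desk_training_run():
    """One shared scaled-down training run: 200 iterations on four
    64-slice phantoms (fixed seed), used by the training and end-to-end
    acceptance checks.

    Returns (initial checkpoint, trained checkpoint, history, train config).
    """
    from thinslice.training import checkpoint_from_generator

    cohort = ts.make_test_cohort(4, nodules_per_series=3, seed=101,
                                 shape=(64, 32, 32), volume_range=(15., 35.))
    cfg = ts.TrainConfig(seed=0, iterations=200)
    ckpt0 = checkpoint_from_generator(ts.build_generator(cfg.generator))
    ckpt, history = ts.train(cfg, [s.volume for s in cohort])
    return ckpt0, ckpt, history, cfg


@pytest.fixture(scope="session")
def heldout_phantoms():
    """Three held-out phantoms matching the training conditions."""
    return ts.make_test_cohort(3, nodules_per_series=1, seed=202,
                               shape=(64, 32, 32), volume_range=(15., 35.))
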