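import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_config():
    """Desk-scale configuration small enough for per-test training."""
    from dmpf.config import DMPFConfig

    cfg = DMPFConfig()
    cfg.model.channels = (4, 8)
    cfg.model.num_classes = 3
    cfg.train.patch_size = (8, 8, 8)
    cfg.train.stride = (8, 8, 8)
    cfg.train.batch_labeled = 2
    cfg.train.batch_unlabeled = 2
    cfg.train.iters_per_epoch = 3
    cfg.train.max_epochs = 2
    cfg.train.seed = 7
    return cfg


@pytest.fixture(scope="session")
def tiny_dataset():
    """Three-category 16^3 phantoms: 2 labeled, 2 unlabeled, 1 validation."""
    from dmpf.synthetic import PhantomSpec, generate_cohort
    from dmpf.trainer import Dataset

    spec = PhantomSpec(grid_size=(16, 16, 16),
                       target_voxel_fractions=(0.25, 0.03),
                       noise_sd=0.02, seed=11)
    cohort = generate_cohort(spec, 5)
    return Dataset(labeled=cohort[:2],
                   unlabeled=[v for v, _ in cohort[2:4]],
                   val=cohort[4:],
                   num_classes=spec.num_classes)
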