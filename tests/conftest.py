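import numpy as np
import pytest
from hypothesis import settings

from lggseg import (
    BinaryMask,
    NetworkSpec,
    PhantomConfig,
    TrainConfig,
    Volume,
    generate_cohort,
)
from lggseg.pipeline import TrainedModel, train_pipeline

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """Two easy-contrast phantoms, small enough for second-scale tests."""
    cfg = PhantomConfig(
        shape=(4, 48, 48),
        n_lesions=1,
        lesion_axes=((1.0, 1.5), (6.0, 9.0), (6.0, 9.0)),
        contrast=3.0,
        noise_sd=10.0,
        seed=7,
    )
    train_set, test_set = generate_cohort(2, 1, cfg)
    return train_set, test_set


@pytest.fixture(scope="session")
def tiny_trained(small_cohort):
    """A quickly trained width-reduced base-line model on the small cohort."""
    train_set, _ = small_cohort
    spec = NetworkSpec.from_variant("base", filters=(4, 8), fc_width=16)
    config = TrainConfig(epochs=3, batch_size=16, dropout_rate=0.25, seed=11)
    return train_pipeline(
        train_set, spec, config, n_per_slice=30, tumor_fraction=0.4, max_patches=600
    )


@pytest.fixture()
def block_volume():
    """Deterministic 48x48 volume: uniform brain with a bright square lesion."""
    rng = np.random.default_rng(5)
    vox = np.full((4, 48, 48), 100.0) + rng.normal(0, 5.0, (4, 48, 48))
    lab = np.zeros((4, 48, 48), dtype=np.uint8)
    lab[1:3, 18:30, 18:30] = 1
    vox[lab > 0] += 40.0
    return Volume(vox, subject_id="block"), BinaryMask(lab)
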