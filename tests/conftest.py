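"""Shared fixtures: desk-scale phantoms and a once-trained network.

Everything is generated programmatically; no test data ships with the
repository.  The "desk" scale (small grids, 32x32x48 crops, eighth-width
network with 3x3x3 kernels) keeps the full pipeline CPU-friendly while
exercising the identical code paths as the full-size configuration.
"""

from __future__ import annotations

import numpy as np
import pytest

from psoasvol.network import NetworkSpec
from psoasvol.preprocess import prepare_subject
from psoasvol.synthetic import PhantomSpec, generate_phantom
from psoasvol.training import TrainConfig, train_model

DESK_CROP_SHAPE = (32, 32, 48)
DESK_NETWORK = NetworkSpec(width_multiplier=0.125, conv_kernel=3)


def make_desk_subjects(n, seed=7, crop_shape=DESK_CROP_SHAPE, spec=None):
    """Generate n annotated desk phantoms prepared into crop pairs."""
    rng = np.random.default_rng(seed)
    spec = spec or PhantomSpec.desk(seed=seed)
    out = []
    for i in range(n):
        tl = rng.uniform(40.0, 70.0)
        tr = rng.uniform(40.0, 70.0)
        subj = generate_phantom(spec, tl, tr, subject_id=f"S{i:03d}")
        out.append((subj, prepare_subject(
            subj.volume, subj.landmarks, subj.left_mask, subj.right_mask,
            crop_shape=crop_shape, subject_id=subj.subject_id,
        )))
    return out


@pytest.fixture(scope="session")
def desk_subjects():
    """Eight desk phantoms with their prepared crops."""
    return make_desk_subjects(8)


@pytest.fixture(scope="session")
def trained_desk(desk_subjects):
    """Network trained on six desk phantoms (with shift augmentation,
    so translation behaviour is meaningful); two subjects held out.

    Returns ``(train_result, held_out_subject_pairs)``.
    """
    from psoasvol.augment import AugmentationSpec, build_training_set

    train_pairs = desk_subjects[:6]
    held_out = desk_subjects[6:]
    aug = AugmentationSpec(n_random_transforms=2, max_shift_inplane=6,
                           max_shift_outplane=8, seed=0)
    samples = build_training_set([crops for _, crops in train_pairs], aug)
    cfg = TrainConfig(learning_rate=1e-3, batch_size=3, epochs=8, seed=0)
    result = train_model(samples, cfg, DESK_NETWORK)
    return result, held_out


def blob_sample(shape=(16, 16, 16), seed=0, noise=0.02):
    """A single (intensities, mask) pair: bright ellipsoid on noise."""
    rng = np.random.default_rng(seed)
    zz = [np.linspace(-1, 1, s) for s in shape]
    grid = np.meshgrid(*zz, indexing="ij")
    r = sum((g / f) ** 2 for g, f in zip(grid, (0.5, 0.5, 0.7)))
    mask = (r <= 1.0).astype(np.uint8)
    x = 0.1 + 0.6 * mask + rng.normal(0, noise, shape)
    return np.clip(x, 0, 1).astype(np.float32), mask
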