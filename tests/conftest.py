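"""Shared fixtures: phantom pair construction and one smoke-scale GAN run.

The smoke run (edge-16 cubes, 16 training pairs, 30 epochs) takes roughly
half a minute on one CPU and is session-scoped so the training tests, the
end-to-end suppression tests and the learning acceptance check all share it.
"""

from __future__ import annotations

import numpy as np
import pytest

from airgap3d import cgan3d, model_eval
from airgap3d.pair_factory import TrainingPair
from airgap3d.phantom import (
    ArtifactSpec,
    PhantomSpec,
    generate_lung_phantom,
    inject_air_artifacts,
)

SMOKE_EDGE = 16


def make_phantom_pairs(n: int, seed0: int, edge: int = SMOKE_EDGE) -> list[TrainingPair]:
    """(artifact, clean) cube pairs with ground-truth masks."""
    pairs = []
    for i in range(n):
        clean = generate_lung_phantom(PhantomSpec(shape=(edge,) * 3, seed=seed0 + i))
        art, mask = inject_air_artifacts(clean, ArtifactSpec(
            n_bubbles=1, radius_range_vox=(2.0, 3.0), rim_thickness_vox=2,
            shape_irregularity=0.1, seed=1000 + seed0 + i))
        pairs.append(TrainingPair(source=art, target=clean, mask=mask))
    return pairs


SMOKE_GEN_SPEC = cgan3d.GeneratorSpec(cube_edge=SMOKE_EDGE,
                                      encoder_filters=(32, 64, 64, 64))
SMOKE_DISC_SPEC = cgan3d.DiscriminatorSpec(filters=(32, 64, 64, 64),
                                           strides=(2, 2, 2, 1))
SMOKE_TRAIN_CFG = cgan3d.TrainConfig(epochs=30, checkpoint_interval_epochs=10,
                                     save_initial=True, seed=11)


@pytest.fixture(scope="session")
def smoke_run():
    """Train the desk-scale cGAN once; return everything downstream tests need."""
    train_pairs = make_phantom_pairs(16, 0)
    test_pairs = make_phantom_pairs(4, 500)
    series = cgan3d.train(train_pairs, SMOKE_TRAIN_CFG, checkpoint_dir=None,
                          gen_spec=SMOKE_GEN_SPEC, disc_spec=SMOKE_DISC_SPEC)
    reports, best = model_eval.evaluate_checkpoints(series, test_pairs)
    return {
        "train_pairs": train_pairs,
        "test_pairs": test_pairs,
        "series": series,
        "reports": reports,
        "best": best,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
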