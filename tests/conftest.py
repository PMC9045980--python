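"""Shared fixtures: the desk-scale phantom study and its trained checkpoints.

Study conditions: 40 training cases at 128x128 (2 slices each, batch 4,
base width 8, 30 epochs, Tversky(0.3, 0.7), seed 42), an in-distribution
held-out set of 8 clean cases, and a shifted held-out set of 8 cases with
three bright distractor blobs outside the breast.  Training data contain no
distractors, so the distractor set probes robustness to background tissue
never seen in training — the scenario the ROI cascade exists for.  The
trained models are session-scoped so the learnability and two-stage
comparison properties share one set of checkpoints; checkpoint selection
uses validation DSC on the distractor set (selecting for robustness).
"""

import pytest

from raunet.nets import NetworkSpec
from raunet.phantom import PhantomConfig, generate_cases
from raunet.pipeline import TrainConfig, train_stage

DESK_SEED = 42
DESK_BASE = 8


@pytest.fixture(scope="session")
def desk_train():
    cfg = PhantomConfig(image_size=128, n_slices_per_case=2)
    return generate_cases(cfg, 40, seed=DESK_SEED)


@pytest.fixture(scope="session")
def clean_test():
    cfg = PhantomConfig(image_size=128, n_slices_per_case=2)
    return generate_cases(cfg, 8, seed=91)


@pytest.fixture(scope="session")
def distractor_test():
    cfg = PhantomConfig(image_size=128, n_slices_per_case=2, n_distractors=3)
    return generate_cases(cfg, 8, seed=43)


@pytest.fixture(scope="session")
def roi_checkpoint(desk_train):
    cfg = TrainConfig(epochs=8, seed=DESK_SEED, stage="roi")
    return train_stage(desk_train, NetworkSpec(base_channels=DESK_BASE), cfg)


@pytest.fixture(scope="session")
def tumor_checkpoint(desk_train, distractor_test):
    """Stage-2 RA-U-Net trained on ROI-masked slices (teacher forcing)."""
    cfg = TrainConfig(epochs=30, seed=DESK_SEED, stage="tumor", teacher_forcing=True)
    return train_stage(
        desk_train, NetworkSpec(base_channels=DESK_BASE), cfg, val_cases=distractor_test
    )


@pytest.fixture(scope="session")
def single_stage_checkpoint(desk_train, distractor_test):
    """Same architecture and protocol trained on raw full-frame slices."""
    cfg = TrainConfig(epochs=30, seed=DESK_SEED, stage="tumor", teacher_forcing=False)
    return train_stage(
        desk_train, NetworkSpec(base_channels=DESK_BASE), cfg, val_cases=distractor_test
    )
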