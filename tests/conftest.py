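"""Shared fixtures.

The end-to-end checks (training smoke, co-generation self-consistency,
coupled two-state sampling) share one toy model trained once per session on
the synthetic two-state family.  Problem sizes are kept small (L = 32,
hidden 64, 4 blocks) so the whole suite runs on one CPU in minutes.
"""

from dataclasses import dataclass

import numpy as np
import pytest

from duet.denoiser import DenoiserConfig, build_denoiser
from duet.synthetic import ToyFamilySpec, toy_dataset
from duet.training import TrainingPolicy, train

TOY_LENGTH = 32
TOY_SPEC = ToyFamilySpec(length=TOY_LENGTH, noise_sd=0.25, two_state=True)
TRAIN_STEPS = 5000


@dataclass
class TrainedToy:
    model: object
    spec: ToyFamilySpec
    history: list


@pytest.fixture(scope="session")
def trained_toy() -> TrainedToy:
    rng = np.random.default_rng(7)
    cfg = DenoiserConfig(n_blocks=4, hidden_dim=64, max_length=TOY_LENGTH)
    model = build_denoiser(cfg, rng)
    # heads start non-zero so both loss branches carry gradient from step 0
    model.head_logits.weight.data = rng.standard_normal((64, 21)) / 8
    model.head_struct.weight.data = rng.standard_normal((64, 3)) / 8
    model, ema, history = train(
        model, toy_dataset(TOY_SPEC), TrainingPolicy(), TRAIN_STEPS, rng,
        batch_size=16, lr=3e-3,
    )
    model.load_arrays(ema)
    return TrainedToy(model=model, spec=TOY_SPEC, history=history)
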