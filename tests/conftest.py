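import numpy as np
import pytest

import residiff as rd
from residiff.nn import TINY, build_denoiser
from residiff.train import LossConfig, TrainConfig, fit


@pytest.fixture(scope="session")
def default_schedule():
    return rd.build_schedule(T=15, p=0.3, gamma=2.0, kappa=0.04, beta_T=0.9999)


@pytest.fixture(scope="session")
def phantom64():
    return rd.make_phantom(rd.PhantomSpec(size=64, seed=3))


@pytest.fixture(scope="session")
def phantom32():
    return rd.make_phantom(rd.PhantomSpec(size=32, seed=5))


@pytest.fixture(scope="session")
def desk_scale_run(default_schedule):
    """Train the tiny denoiser on 200 seeded 32x32 factor-4 phantoms.

    Shared by the end-to-end learning checks; 1000 steps at the published
    batch size of 16, one CPU.
    Returns (model, schedule, loss trace, held-out test pairs).
    """
    splits = rd.make_dataset(
        220,
        rd.PhantomSpec(size=32, factors=(4.0, 4.0)),
        fractions=(200 / 220, 0.0, 20 / 220),
        master_seed=11,
    )
    model = build_denoiser(TINY, seed=0)
    cfg = TrainConfig(total_steps=1000, batch_size=16, lr_init=1e-3, warmup_steps=100, seed=0)
    model, trace = fit(splits["train"], model, default_schedule, LossConfig(), cfg)
    return model, default_schedule, trace, splits["test"]


def oracle_denoiser(pair):
    """A denoiser with perfect knowledge of the clean slice."""

    def predict(x_t, x_lr, t):
        return pair.x_hr

    return predict
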