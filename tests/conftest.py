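"""Shared fixtures: toy Gaussian diffusion model, tiny image model, phantoms.

The heavier fixtures are session-scoped so that unit tests and the
acceptance suite share one training run.
"""

from __future__ import annotations

import numpy as np
import pytest

from echoaug import ddpm, phantom
from echoaug.schedule import build_cosine_schedule, respace_schedule

# anatomy overrides that fit comfortably at very coarse renderings
SMALL_ANATOMY = dict(
    lv_long_semi_mm=(22.0, 30.0),
    lv_short_semi_mm=(11.0, 15.0),
    myo_thickness_mm=6.0,
)

TOY_MEAN = np.array([0.1, -0.2])
TOY_COV = np.array([[0.0625, 0.0375], [0.0375, 0.0625]])  # sd 0.25, rho 0.6


@pytest.fixture(scope="session")
def schedule_T50():
    return build_cosine_schedule(50)


@pytest.fixture(scope="session")
def toy_model():
    """Predictor trained on a 2-pixel bivariate Gaussian with T=50."""
    rng = np.random.default_rng(0)
    data = rng.multivariate_normal(TOY_MEAN, TOY_COV, size=20000)
    cfg = ddpm.TrainingConfig(
        T=50,
        n_steps=8000,
        batch_size=256,
        learning_rate=2e-3,
        hidden=(96, 96),
        seed=0,
    )
    predictor = ddpm.train(data, cfg)
    return {
        "predictor": predictor,
        "schedule": predictor.schedule,
        "mean": TOY_MEAN,
        "cov": TOY_COV,
        "config": cfg,
    }


@pytest.fixture(scope="session")
def phantom_sample_64():
    sample, truth = phantom.generate_sample(phantom.hunt4like(image_size=64), seed=11)
    return sample, truth


@pytest.fixture(scope="session")
def phantom_sample_128():
    sample, truth = phantom.generate_sample(phantom.hunt4like(image_size=128), seed=1)
    return sample, truth


@pytest.fixture(scope="session")
def image_model():
    """Tiny DDPM trained on four 32x32 phantoms, with a respaced sampling
    schedule for fast repainting."""
    cfg = phantom.hunt4like(image_size=32, **SMALL_ANATOMY)
    samples = [phantom.generate_sample(cfg, seed=i)[0] for i in range(4)]
    latents = np.stack([2.0 * s.image - 1.0 for s in samples])
    tcfg = ddpm.TrainingConfig(
        T=200, n_steps=800, batch_size=32, learning_rate=1e-3, hidden=(128,), seed=0
    )
    predictor = ddpm.train(latents, tcfg)
    sampling = respace_schedule(predictor.schedule, 25)
    return {
        "predictor": predictor,
        "schedule": predictor.schedule,
        "sampling_schedule": sampling,
        "samples": samples,
        "config": tcfg,
    }
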