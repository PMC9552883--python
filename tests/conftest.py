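"""Shared fixtures: model configuration and small synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from csoscillator import ModelConfig
from csoscillator.synth import CohortSpec, generate_cohort

SEED = 0


@pytest.fixture(scope="session")
def cfg() -> ModelConfig:
    return ModelConfig()


@pytest.fixture(scope="session")
def tiny_cohort(cfg):
    """Three subjects, zero observation noise, model-generated truth."""
    spec = CohortSpec(
        n_subjects=3, true_init_cbt_min=5.0, chronotype_sd=0.0,
        obs_noise_sd=0.0, seed=SEED,
    )
    return generate_cohort(spec, cfg)


@pytest.fixture(scope="session")
def noisy_cohort(cfg):
    """The chronotype-recovery study: n=20, true initial CBT_min 05:00,
    observation noise SD 0.25 h."""
    spec = CohortSpec(
        n_subjects=20, true_init_cbt_min=5.0, chronotype_sd=0.0,
        obs_noise_sd=0.25, seed=SEED,
    )
    return generate_cohort(spec, cfg)
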