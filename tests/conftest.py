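"""Shared fixtures: phantom cohorts and a trained desk-scale segmenter.

The trained model is session-scoped — one 20-epoch training run of the small
residual preset on ~200 phantom map slices feeds the learning, curriculum,
warm-start and translation tests.
"""

import numpy as np
import pytest

from cardiomapseg import phantom, training
from cardiomapseg.network import ModelConfig, build_model


@pytest.fixture(scope="session")
def cohort():
    """Small cohort with fitted maps for metric/contour tests."""
    return phantom.generate_phantom_cohort(10, seed=101)


@pytest.fixture(scope="session")
def clean_cohort():
    """Cases guaranteed free of C-shaped cavities (convex truth contours)."""
    return phantom.generate_phantom_cohort(
        18, seed=11, fit_maps=False,
        sampler=phantom.GeometrySamplerConfig(gap_probability=0.0),
    )


@pytest.fixture(scope="session")
def train_setup():
    """34 cases -> ~200 parametric-map slices plus their weighted stacks."""
    cases = phantom.generate_phantom_cohort(34, seed=5)
    samples = training.samples_from_cases(cases, include_weighted=True)
    split = training.split_cases([c.case_id for c in cases], seed=1)
    return cases, samples, split


@pytest.fixture(scope="session")
def train_config():
    return training.TrainConfig(
        epochs=20, curriculum_switch_epoch=9, restart_periods=(9, 11),
        batch_size=8, input_size=(64, 64), seed=0,
    )


@pytest.fixture(scope="session")
def trained(train_setup, train_config):
    """The 20-epoch reference training run (model, result, samples, split)."""
    _, samples, split = train_setup
    model = build_model(
        ModelConfig(encoder_kind="small-resnet", input_size=(64, 64)), seed=0
    )
    result = training.train(model, samples, split, train_config)
    return model, result, samples, split
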