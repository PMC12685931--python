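"""Shared fixtures.

Desk-scale geometry is 64x64 with the tiny encoder preset; the expensive
trained-model fixture is session-scoped so the learning-behaviour,
in-context and retrieval suites share a single training run.
"""

import numpy as np
import pytest

from icseg.model import InContextSegmenter, ModelConfig
from icseg.synthetic import generate_episode, generate_task
from icseg.training import desk_episode_stream, desk_train_config, train

SIZE = 64


@pytest.fixture(scope="session")
def tiny_model():
    """Freshly initialized tiny model at 64x64 geometry."""
    return InContextSegmenter(ModelConfig(image_size=SIZE, preset="tiny"), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def train_tasks():
    r = np.random.default_rng(0)
    return [generate_task(r, task_id=f"t{i}") for i in range(40)]


@pytest.fixture(scope="session")
def held_out_tasks():
    return [generate_task(np.random.default_rng(99 + i), task_id=f"ho{i}",
                          held_out=True) for i in range(5)]


@pytest.fixture(scope="session")
def random_episode():
    r = np.random.default_rng(7)
    task = generate_task(r, task_id="fixture-task")
    return generate_episode(task, 4, r, size=SIZE)


@pytest.fixture(scope="session")
def trained_model(train_tasks):
    """Tiny model trained for 2000 steps on synthetic episodes.

    One shared run (a few CPU-minutes) reused by the learning-behaviour,
    in-context and retrieval suites.  Registry tokens are disabled for this
    desk-scale run: at a 2x2 coarse attention grid they form an attention
    sink that silences the support pathway during optimization.
    """
    model = InContextSegmenter(
        ModelConfig(image_size=SIZE, preset="tiny", n_registry_tokens=0), seed=0)
    cfg = desk_train_config(steps=2000, seed=0)
    stream = desk_episode_stream(train_tasks, np.random.default_rng(1), size=SIZE)
    train(model, stream, cfg)
    return model
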