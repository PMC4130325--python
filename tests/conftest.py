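"""Shared fixtures.

The expensive end-to-end state (a trained scaled-down network, its scene
set, and the saliency-derived patches) is built once per session and shared
by the pipeline-level and acceptance tests.
"""

import numpy as np
import pytest

from visnetscenes import pipeline
from visnetscenes.config import test_profile

SESSION_SEED = 11


@pytest.fixture(scope="session")
def run_config():
    return test_profile(seed=SESSION_SEED)


@pytest.fixture(scope="session")
def trainset(run_config):
    return pipeline.build_trainset(run_config)


@pytest.fixture(scope="session")
def trained(run_config, trainset):
    """Scaled-down trained pipeline (network + readout + response tensor)."""
    return pipeline.train_pipeline(run_config, trainset=trainset)


@pytest.fixture(scope="session")
def untrained(run_config, trainset):
    """Same architecture and readout protocol with no invariance training."""
    return pipeline.train_pipeline(run_config, trainset=trainset, train=False)


@pytest.fixture(scope="session")
def scene_set(run_config):
    return pipeline.make_scene_set(run_config, run_config.n_scenes,
                                   seed=SESSION_SEED + 1)


@pytest.fixture(scope="session")
def scene_patches(scene_set, run_config):
    """Saliency fixations + V1 patches for the scene set (network-free)."""
    return pipeline.extract_scene_patches(scene_set, run_config)
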