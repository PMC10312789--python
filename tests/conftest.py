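"""Shared fixtures.

The trained desk-scale study is expensive (minutes of CPU), so it is built
once per session and shared by the reconstruction, OOD, and fine-tuning
tests.  Everything is seeded; no fixture touches the network or disk
outside tmp paths.
"""

import numpy as np
import pytest

from xlflow.pipeline import desk_geometry, finetune_study, ood_study, run_desk_study


@pytest.fixture(scope="session")
def geometry():
    return desk_geometry()


@pytest.fixture(scope="session")
def study():
    """A fully trained desk-scale study (10 training pairs, 2 levels)."""
    return run_desk_study(seed=1)


@pytest.fixture(scope="session")
def ood_results(study):
    return ood_study(study, seed=1)


@pytest.fixture(scope="session")
def finetune_results(study):
    return finetune_study(study, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
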