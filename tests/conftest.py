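"""Shared fixtures.

The heavy end-to-end experiment (6 strategies x 2 evaluation sets, n=200
simulated treatments per combination, 5 mm grid) runs once per session and is
shared by the acceptance tests that need plans, robust tables and evaluation
summaries.
"""

import numpy as np
import pytest

from bhrobust.config import ExperimentConfig
from bhrobust.deformation import BreathHoldDeformer
from bhrobust.dose import AnalyticDoseEngine
from bhrobust.experiment import run_experiment
from bhrobust.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def phantom5():
    """Default phantom geometry on a coarse 5 mm grid (fast tests)."""
    return generate_phantom(PhantomConfig(shape=(40, 36, 32), spacing=(5.0, 5.0, 5.0)),
                            seed=1)


@pytest.fixture(scope="session")
def phantom3():
    """Phantom at the default 3 mm spacing and extent (deformation suite)."""
    return generate_phantom(PhantomConfig(shape=(64, 56, 48), spacing=(3.0, 3.0, 3.0)),
                            seed=1)


@pytest.fixture(scope="session")
def deformer5(phantom5):
    return BreathHoldDeformer(phantom5)


@pytest.fixture(scope="session")
def deformer3(phantom3):
    return BreathHoldDeformer(phantom3)


@pytest.fixture(scope="session")
def engine():
    return AnalyticDoseEngine()


@pytest.fixture(scope="session")
def experiment_result():
    """One phantom x 6 plans x 2 evaluation sets x 200 treatments, 5 mm grid."""
    cfg = ExperimentConfig(n_samples=200, seed=1)
    cfg.phantom.shape = (40, 36, 32)
    cfg.phantom.spacing = (5.0, 5.0, 5.0)
    return run_experiment(cfg, progress=None)
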