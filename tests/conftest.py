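"""Shared fixtures: small simulated datasets and pipeline products."""

import numpy as np
import pytest

from tet2traj.evaluation import run_pipeline
from tet2traj.io import ExpressionMatrix
from tet2traj.simulate import SimulationConfig


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A small but signal-rich simulation: 400 cells per condition."""
    return SimulationConfig(n_cells=400, seed=7)


@pytest.fixture(scope="session")
def small_run(small_config):
    """Full pipeline products (pseudotime, bin profile, per-cell scores)."""
    return run_pipeline(small_config)


@pytest.fixture(scope="session")
def single_condition_run():
    """FLAG-only pipeline run used for ordering/projection tests."""
    return run_pipeline(SimulationConfig(n_cells=1000, conditions=("FLAG",), seed=13))


@pytest.fixture()
def tiny_counts() -> ExpressionMatrix:
    """Hand-sized 4 cells x 3 genes counts matrix."""
    values = np.array(
        [
            [5, 0, 2],
            [0, 0, 0],
            [3, 1, 0],
            [0, 4, 1],
        ],
        dtype=float,
    )
    return ExpressionMatrix(values, ["c1", "c2", "c3", "c4"], ["g1", "g2", "g3"], "counts")
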