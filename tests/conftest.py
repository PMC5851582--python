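"""Shared fixtures: one synthetic wet site carried through the land-sea stages.

Session scope keeps the expensive products (flow solve, plume stack) shared
across test modules; tests must not mutate fixture objects in place.
"""

from __future__ import annotations

import numpy as np
import pytest

from ridge2reef.brt import BRTConfig
from ridge2reef.grid import RasterGrid
from ridge2reef.pipeline import PipelineConfig, run_land_sea, run_pipeline
from ridge2reef.synth import generate_site


@pytest.fixture(scope="session")
def wet_site():
    return generate_site("wet", size=40, seed=11)


@pytest.fixture(scope="session")
def wet_stage(wet_site):
    return run_land_sea(wet_site)


@pytest.fixture(scope="session")
def wet_stack(wet_stage):
    return wet_stage.driver_stack


@pytest.fixture(scope="session")
def small_pipeline_result():
    cfg = PipelineConfig(
        preset="wet", size=30, seed=3, n_surveys=100,
        brt=BRTConfig(grid=((0.05, 3, 0.75),), max_trees=150),
    )
    return run_pipeline(cfg)


@pytest.fixture
def grid5():
    """A plain 5x5 grid of zeros, 10 m cells, origin at (0, 0)."""
    return RasterGrid(np.zeros((5, 5)), 10.0, (0.0, 0.0), units="m")
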