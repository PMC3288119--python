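"""Shared fixtures: a small two-group map and simulated populations."""

import numpy as np
import pandas as pd
import pytest

from diallelgg import simdata


@pytest.fixture(scope="session")
def small_map():
    return simdata.default_map(n_markers=12, n_linkage_groups=2)


@pytest.fixture(scope="session")
def framework_map():
    return simdata.default_map()


@pytest.fixture(scope="session")
def small_pop(small_map):
    design = simdata.DiallelDesign(
        females=("F1", "F2"),
        males=("M1", "M2"),
        crosses=(("c1", "F1", "M1", 20), ("c2", "F2", "M2", 20)),
    )
    return simdata.simulate_diallel(design, small_map, het_fraction=0.8, seed=42)


@pytest.fixture(scope="session")
def diallel_pop(framework_map):
    """Study-scale population: 4 crosses, 188 progeny, 252 markers."""
    return simdata.simulate_diallel(simdata.default_design(), framework_map, seed=42)
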