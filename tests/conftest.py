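"""Shared fixtures.

Expensive steady-state sweeps are session-scoped so the regime tests and
the acceptance battery reuse one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from rmeco import ModelParams, build_community, sweep_supply


#: Reduced supply grid spanning the same decade range as the figure-style
#: sweeps: enough points to see all three regimes, cheap enough for CI.
GRID = np.logspace(3, 9, 9)


@pytest.fixture(scope="session")
def default_params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def general_sweep():
    hosts, phages = build_community(2, "subset", "general")
    return sweep_supply("general", hosts, phages, ModelParams(), GRID), hosts, phages


@pytest.fixture(scope="session")
def parallel_sweep():
    hosts, phages = build_community(2, "subset", "parallel")
    return sweep_supply("parallel", hosts, phages, ModelParams(), GRID), hosts, phages


@pytest.fixture(scope="session")
def memory_sweep():
    hosts, phages = build_community(2, "subset", "memory")
    return sweep_supply("memory", hosts, phages, ModelParams(), GRID), hosts, phages


@pytest.fixture(scope="session")
def memory3_subset_sweep():
    hosts, phages = build_community(3, "subset", "memory")
    params = ModelParams().with_(m_v=0.75)
    return sweep_supply("memory", hosts, phages, params, GRID), hosts, phages


@pytest.fixture(scope="session")
def memory3_unique_sweep():
    hosts, phages = build_community(3, "unique", "memory")
    params = ModelParams().with_(m_v=0.75)
    return sweep_supply("memory", hosts, phages, params, GRID), hosts, phages


@pytest.fixture(scope="session")
def general3_sweep():
    hosts, phages = build_community(3, "subset", "general")
    return sweep_supply("general", hosts, phages, ModelParams(), GRID), hosts, phages


@pytest.fixture(scope="session")
def parallel3_sweep():
    hosts, phages = build_community(3, "subset", "parallel")
    return sweep_supply("parallel", hosts, phages, ModelParams(), GRID), hosts, phages
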