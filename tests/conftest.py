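"""Shared fixtures: tiny hand-checkable networks and the planted scenario."""

from __future__ import annotations

import pytest

from multitraj import (
    build_trajectories,
    default_scenario,
    optimize_parameters,
    resolution_sweep,
)
from multitraj.core import MultiplexNetwork

#: resolution grid used for the planted 300-gene scenario: spans the coarse
#: module scale, the submodule scale, and the fragmentation onset
SCENARIO_GRID = tuple(float(g) for g in range(1, 13))
SCENARIO_SEED = 0
SWEEP_SEED = 100


def triangle_edges(nodes):
    a, b, c = nodes
    return {tuple(sorted((a, b))): (1.0, None),
            tuple(sorted((a, c))): (1.0, None),
            tuple(sorted((b, c))): (1.0, None)}


@pytest.fixture(scope="session")
def two_triangles():
    """Single layer: two disjoint triangles abc / def."""
    edges = {**triangle_edges("abc"), **triangle_edges("def")}
    return MultiplexNetwork(tuple("abcdef"), {"L1": edges})


@pytest.fixture(scope="session")
def bridged_triangles():
    """Two triangles joined by the single bridge edge c-d."""
    edges = {**triangle_edges("abc"), **triangle_edges("def"), ("c", "d"): (1.0, None)}
    return MultiplexNetwork(tuple("abcdef"), {"L1": edges})


@pytest.fixture(scope="session")
def scenario():
    """Planted multiplex + cohort + resolution sweep + trajectories (shared)."""
    net, truth, cohort = default_scenario(seed=SCENARIO_SEED)
    profile = resolution_sweep(net, SCENARIO_GRID, seed=SWEEP_SEED)
    traj = build_trajectories(profile)
    return {"net": net, "truth": truth, "cohort": cohort, "profile": profile, "traj": traj}


@pytest.fixture(scope="session")
def optimized(scenario):
    """Full (theta, lambda) optimization on the planted scenario (shared)."""
    return optimize_parameters(scenario["cohort"], scenario["traj"])
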