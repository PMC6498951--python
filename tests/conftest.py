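"""Shared fixtures: default geometry/blood and cached expensive runs.

Simulation-backed fixtures are session-scoped: the calibrated model
context, the resting periodic solution and the constrained optima are
computed once and reused by the unit and acceptance tests.
"""

from __future__ import annotations

import warnings

import pytest

from ventopt.blood import BloodParams
from ventopt.geometry import MorphometryParams, VentilationPattern, build_tree
from ventopt.scenarios import ModelContext
from ventopt.transport import SolverConfig, TransportSolver


@pytest.fixture(scope="session")
def tree():
    return build_tree(MorphometryParams())


@pytest.fixture(scope="session")
def blood():
    return BloodParams()


@pytest.fixture()
def rest_pattern():
    return VentilationPattern(A=1.0, T=5.0)


#: Solver profile used by simulation-heavy tests: coarser than the package
#: default but (as the grid-refinement test shows) within a percent of it.
FAST_CFG = SolverConfig(nodes_per_branch=8, steps_per_cycle=120,
                        periodicity_tol=1e-5, max_cycles=40)

#: Very coarse profile for monotonicity/shape checks.
COARSE_CFG = SolverConfig(nodes_per_branch=5, steps_per_cycle=60,
                          periodicity_tol=1e-4, max_cycles=30)


@pytest.fixture(scope="session")
def fast_cfg():
    return FAST_CFG


@pytest.fixture(scope="session")
def coarse_cfg():
    return COARSE_CFG


@pytest.fixture(scope="session")
def ctx(tree):
    """Calibrated model context at the fast solver profile."""
    c = ModelContext(solver_config=FAST_CFG)
    c.calibrated_blood()
    return c


@pytest.fixture(scope="session")
def rest_periodic(ctx):
    """Resting periodic solution of the calibrated model (both gases)."""
    solver = TransportSolver(ctx.tree, VentilationPattern(A=1.0, T=5.0),
                             ctx.calibrated_blood(),
                             config=ctx.solver_config)
    return solver, solver.run_to_periodic()


@pytest.fixture(scope="session")
def rest_optimum(ctx):
    """Rest-demand constrained power optimum."""
    return ctx.optimize(ctx.rest_oxygen_flow())
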