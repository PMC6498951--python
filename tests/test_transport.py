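"""Transport solver: steady oracle, conservation, periodicity, fluxes."""

import warnings

import numpy as np
import pytest

from ventopt.blood import BloodParams
from ventopt.geometry import MorphometryParams, VentilationPattern, build_tree
from ventopt.transport import (CO2, O2, FlowResult, SolverConfig,
                               TransportSolver, adimensional_profile,
                               conductive_profile, respiratory_exchange_ratio)

from conftest import COARSE_CFG, FAST_CFG


def steady_error(nodes_per_branch: int, sink: float = 40.0) -> float:
    """Max node-wise gap between the u=0 numerical steady state and the
    closed-form conductive profile (tree without acinus, distal Dirichlet)."""
    tree = build_tree(MorphometryParams(n_acinar=0))
    cfg = SolverConfig(nodes_per_branch=nodes_per_branch, steps_per_cycle=10,
                       exchange=False, distal_bc="dirichlet",
                       distal_pressure=sink)
    solver = TransportSolver(tree, VentilationPattern(A=0.0, T=5.0),
                             BloodParams(), gases=(O2,), config=cfg)
    state = solver.initialize_state()
    for _ in range(80):
        state = solver.advance(state, 1e5)
    profile, _ = conductive_profile(tree, O2.P_air, sink)
    err = 0.0
    for g in range(tree.n_generations):
        xj = np.arange(1, cfg.nodes_per_branch + 1) * tree.length[g] / cfg.nodes_per_branch
        err = max(err, float(np.max(np.abs(
            state.P["O2"][solver.block_idx[g]] - profile(g, xj)))))
    return err


class TestSteadyOracle:
    def test_matches_closed_form_nodewise(self):
        # the closed form is piecewise linear, which the scheme represents
        # exactly: agreement to solver tolerance at any resolution
        assert steady_error(5) < 1e-8
        assert steady_error(10) < 1e-8

    def test_error_does_not_grow_under_refinement(self):
        assert steady_error(10) <= steady_error(5) + 1e-10

    def test_uniform_field_is_invariant_without_exchange(self, tree):
        cfg = SolverConfig(nodes_per_branch=5, steps_per_cycle=20,
                           exchange=False, distal_bc="dirichlet",
                           distal_pressure=O2.P_air)
        solver = TransportSolver(tree, VentilationPattern(A=1.0, T=5.0),
                                 BloodParams(), gases=(O2,), config=cfg)
        state = solver.initialize_state()
        state.P["O2"][:] = O2.P_air
        out = solver.run_cycles(state.copy(), 1)
        assert np.allclose(out.P["O2"], O2.P_air, atol=1e-9)


class TestInitialState:
    def test_profile_monotone_root_to_leaf_for_oxygen(self, tree, blood):
        solver = TransportSolver(tree, VentilationPattern(A=1.0, T=5.0), blood,
                                 gases=(O2,), config=COARSE_CFG)
        state = solver.initialize_state()
        assert np.all(np.diff(state.P["O2"]) <= 1e-12)
        assert state.P["O2"][0] <= O2.P_air

    def test_half_homothety_gives_linear_decay_per_generation(self):
        # at h = 1/2 every generation drops the same amount: Σ(1/2h)ᵏ = N+1
        tree = build_tree(MorphometryParams(h=0.5, n_acinar=0))
        profile, junction = conductive_profile(tree, 150.0, 40.0)
        drops = np.diff(np.concatenate([[150.0], junction]))
        assert np.allclose(drops, drops[0])

    def test_continuity_at_junctions(self, tree, blood):
        solver = TransportSolver(tree, VentilationPattern(A=1.0, T=5.0), blood,
                                 config=COARSE_CFG)
        state = solver.initialize_state()
        profile, junction = conductive_profile(
            tree, O2.P_air, state.P["O2"][solver.distal_idx])
        for g in range(tree.n_conductive - 1):
            assert state.P["O2"][solver.junc_idx[g]] == pytest.approx(
                junction[g], rel=1e-12)


class TestConservation:
    def test_content_change_equals_boundary_influx_without_exchange(self, tree):
        """Discrete mass balance: d(content) = trachea influx when β = 0 and
        the distal end is sealed (zero-flux robin with exchange off)."""
        cfg = SolverConfig(nodes_per_branch=5, steps_per_cycle=40,
                           exchange=False, distal_bc="robin")
        solver = TransportSolver(tree, VentilationPattern(A=1.0, T=5.0),
                                 BloodParams(), gases=(O2,), config=cfg)
        state = solver.initialize_state()
        c0 = solver.total_content(state, "O2")
        record = {}
        state = solver.run_cycles(state, 1, record=record)
        c1 = solver.total_content(state, "O2")
        dt = 5.0 / cfg.steps_per_cycle
        influx = np.sum(record["influx"]["O2"]) * dt
        assert c1 - c0 == pytest.approx(influx, rel=1e-9, abs=1e-15)

    def test_periodic_cycle_uptake_equals_trachea_influx(self, rest_periodic):
        solver, result = rest_periodic
        f = result.flows
        assert f.VO2 == pytest.approx(f.trachea_influx["O2"], rel=2e-3)
        assert -f.VCO2 == pytest.approx(f.trachea_influx["CO2"], rel=2e-3)


class TestPeriodicRegime:
    def test_pressures_stay_within_physical_bounds(self, rest_periodic):
        solver, result = rest_periodic
        o2 = result.state.P["O2"]
        co2 = result.state.P["CO2"]
        assert np.all(o2 <= O2.P_air + 1e-6)
        assert np.all(o2 >= 0.0)
        assert np.all(co2 >= CO2.P_air - 1e-6)
        assert np.all(co2 <= 60.0)

    def test_extra_cycle_is_periodic(self, rest_periodic):
        solver, result = rest_periodic
        before = np.concatenate([result.state.P[g] for g in ("O2", "CO2")])
        after_state = solver.run_cycles(result.state.copy(), 1)
        after = np.concatenate([after_state.P[g] for g in ("O2", "CO2")])
        rel = np.linalg.norm(after - before) / np.linalg.norm(before)
        assert rel < 10 * solver.config.periodicity_tol

    def test_no_ventilation_approaches_diffusion_steady_state(self, tree, blood):
        # without ventilation the field relaxes diffusively toward the
        # stationary profile; the cycle-to-cycle residual decays and the
        # (small, diffusion-only) O2 flow balances the trachea influx
        cfg = SolverConfig(nodes_per_branch=5, steps_per_cycle=40,
                           periodicity_tol=1e-8, max_cycles=30)
        solver = TransportSolver(tree, VentilationPattern(A=0.0, T=5.0), blood,
                                 gases=(O2,), config=cfg)
        # the diffusive transient spans many breathing periods; pre-relax
        # with large implicit steps (stable at any dt), then verify the
        # cycle map is stationary and the flux balance closes
        state = solver.initialize_state()
        for _ in range(300):
            state = solver.advance(state, 1e4)
        result = solver.run_to_periodic(state)
        assert result.flows.converged
        assert result.flows.VO2 > 0
        assert result.flows.VO2 == pytest.approx(
            result.flows.trachea_influx["O2"], rel=0.01)

    def test_nonconvergence_warns(self, tree, blood):
        cfg = SolverConfig(nodes_per_branch=5, steps_per_cycle=30,
                           periodicity_tol=1e-14, max_cycles=2)
        solver = TransportSolver(tree, VentilationPattern(A=1.0, T=5.0), blood,
                                 gases=(O2,), config=cfg)
        with pytest.warns(RuntimeWarning, match="not periodic"):
            solver.run_to_periodic()


class TestFluxes:
    def test_no_exchange_pathway_gives_zero_flow(self, tree, blood):
        cfg = SolverConfig(nodes_per_branch=5, steps_per_cycle=40,
                           exchange=False, distal_bc="robin",
                           periodicity_tol=1e-4, max_cycles=30)
        solver = TransportSolver(tree, VentilationPattern(A=1.0, T=5.0), blood,
                                 gases=(O2,), config=cfg)
        result = solver.run_to_periodic()
        assert result.flows.VO2 == pytest.approx(0.0, abs=1e-12)

    def test_resting_flows_in_physiological_band(self, rest_periodic):
        _, result = rest_periodic
        assert 1e-4 < result.flows.VO2 < 2e-4
        assert 1e-4 < result.flows.VCO2 < 2e-4

    def test_flux_grid_convergence(self, tree, blood):
        """Richardson check: doubling time resolution moves VO2 only slightly."""
        flows = []
        for steps in (60, 120):
            cfg = SolverConfig(nodes_per_branch=6, steps_per_cycle=steps,
                               periodicity_tol=1e-5, max_cycles=40)
            solver = TransportSolver(tree, VentilationPattern(A=1.0, T=5.0),
                                     blood, gases=(O2,), config=cfg)
            flows.append(solver.run_to_periodic().flows.VO2)
        assert abs(flows[1] - flows[0]) / flows[1] < 0.02


class TestRER:
    def test_ratio_and_identity(self):
        f = FlowResult(VO2=1.32e-4, VCO2=1.06e-4, trachea_influx={},
                       converged=True, cycles=1, residual=0.0)
        assert respiratory_exchange_ratio(f) == pytest.approx(0.803, abs=5e-4)
        g = FlowResult(VO2=2.0, VCO2=2.0, trachea_influx={},
                       converged=True, cycles=1, residual=0.0)
        assert respiratory_exchange_ratio(g) == 1.0

    def test_nonpositive_vo2_rejected(self):
        f = FlowResult(VO2=0.0, VCO2=1.0, trachea_influx={},
                       converged=True, cycles=1, residual=0.0)
        with pytest.raises(ValueError):
            respiratory_exchange_ratio(f)

    def test_co2_requires_tracking(self):
        f = FlowResult(VO2=1.0, VCO2=None, trachea_influx={},
                       converged=True, cycles=1, residual=0.0)
        with pytest.raises(ValueError):
            respiratory_exchange_ratio(f)


class TestAdimensionals:
    def test_peclet_ratio_between_conductive_generations(self, tree, blood):
        ad = adimensional_profile(tree, VentilationPattern(A=1.0, T=5.0),
                                  O2, blood)
        h = tree.params.h
        nc = tree.n_conductive
        ratio = ad.Pe[1:nc] / ad.Pe[:nc - 1]
        assert np.allclose(ratio, 1.0 / (2.0 * h))

    def test_peclet_linear_in_amplitude(self, tree, blood):
        ad1 = adimensional_profile(tree, VentilationPattern(A=1.0, T=5.0), O2, blood)
        ad2 = adimensional_profile(tree, VentilationPattern(A=3.0, T=5.0), O2, blood)
        assert np.allclose(ad2.Pe, 3.0 * ad1.Pe)

    def test_gamma_defined_only_in_acinus_and_order_one(self, tree, blood):
        ad = adimensional_profile(tree, VentilationPattern(A=1.0, T=5.0), O2, blood)
        nc = tree.n_conductive
        assert np.all(np.isnan(ad.gamma[:nc]))
        assert np.all((ad.gamma[nc:] > 0.3) & (ad.gamma[nc:] < 10.0))


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"nodes_per_branch": 2},
        {"steps_per_cycle": 2},
        {"distal_bc": "neumann"},
        {"distal_bc": "dirichlet"},  # missing distal_pressure
    ])
    def test_invalid_solver_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SolverConfig(**kwargs)
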