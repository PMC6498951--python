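"""Breathing power closed forms and the constrained optimizer."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from ventopt.geometry import MorphometryParams, build_tree
from ventopt.power_optim import (InfeasibleFlowError, MechanicsParams,
                                 amplitude_for_flow,
                                 amplitude_for_tidal_volume, elastic_power,
                                 optimal_ventilation, tidal_volume,
                                 total_power, viscous_power)

S0 = math.pi * 1e-4  # trachea section for r0 = 1 cm


class TestClosedForms:
    def test_elastic_power_matches_quadrature(self):
        A, T, C = 1.0, 5.0, 5e-7
        # oracle: (1/T) ∫ V V̇ / C over inspiration, V(t) = S0 (AT/2π)(1−cos 2πt/T)
        V = lambda t: S0 * A * T / (2 * math.pi) * (1 - math.cos(2 * math.pi * t / T))
        Vdot = lambda t: S0 * A * math.sin(2 * math.pi * t / T)
        oracle, _ = quad(lambda t: V(t) * Vdot(t) / C, 0, T / 2)
        oracle /= T
        assert elastic_power(A, T, S0, C) == pytest.approx(oracle, rel=1e-9)
        assert elastic_power(A, T, S0, C) == pytest.approx(5.0e-2, rel=1e-2)

    def test_elastic_power_quadratic_in_amplitude(self):
        assert elastic_power(2.0, 5.0, S0, 5e-7) == pytest.approx(
            4 * elastic_power(1.0, 5.0, S0, 5e-7))

    def test_viscous_power_matches_quadrature_and_is_period_free(self):
        A, R = 1.0, 2e5
        for T in (2.0, 5.0, 9.0):
            oracle, _ = quad(
                lambda t: R * (A * math.sin(2 * math.pi * t / T) * S0) ** 2 / T,
                0, T)
            assert viscous_power(A, T, S0, R) == pytest.approx(oracle, rel=1e-9)
        assert viscous_power(A, 5.0, S0, R) == pytest.approx(9.87e-3, rel=1e-3)

    @settings(deadline=None, max_examples=25)
    @given(A=st.floats(0.1, 15.0), T=st.floats(0.5, 20.0))
    def test_total_equals_sum_and_factored_form(self, A, T):
        mech = MechanicsParams()
        total = total_power(A, T, mech, S0)
        assert total == pytest.approx(
            elastic_power(A, T, S0, mech.C) + viscous_power(A, T, S0, mech.R),
            rel=1e-12)
        factored = elastic_power(A, T, S0, mech.C) * (
            1 + math.pi**2 * mech.R * mech.C / T)
        assert total == pytest.approx(factored, rel=1e-12)

    def test_viscous_to_elastic_ratio(self):
        mech = MechanicsParams()
        for T in (2.0, 5.0, 8.0):
            ratio = viscous_power(1.0, T, S0, mech.R) / elastic_power(1.0, T, S0, mech.C)
            assert ratio == pytest.approx(math.pi**2 * mech.R * mech.C / T, rel=1e-12)

    def test_viscous_share_at_rest_period(self):
        mech = MechanicsParams()
        share = viscous_power(1.0, 5.0, S0, mech.R) / total_power(1.0, 5.0, mech, S0)
        assert share == pytest.approx(0.17, abs=0.01)

    def test_power_shape_depends_on_rc_product_only(self):
        m1 = MechanicsParams(R=2e5, C=5e-7)
        m2 = MechanicsParams(R=4e5, C=2.5e-7)
        for T in (2.0, 5.0, 11.0):
            r1 = total_power(1.0, T, m1, S0) / total_power(1.0, 5.0, m1, S0)
            r2 = total_power(1.0, T, m2, S0) / total_power(1.0, 5.0, m2, S0)
            assert r1 == pytest.approx(r2, rel=1e-12)


class TestTidalVolume:
    def test_rest_and_exercise_settings(self):
        assert tidal_volume(1.0, 5.0, S0) == pytest.approx(0.5e-3, rel=1e-12)
        assert tidal_volume(13.333, 1.5, S0) == pytest.approx(2e-3, rel=1e-3)

    def test_linear_in_amplitude_and_period(self):
        v = tidal_volume(1.0, 5.0, S0)
        assert tidal_volume(2.0, 5.0, S0) == pytest.approx(2 * v)
        assert tidal_volume(1.0, 10.0, S0) == pytest.approx(2 * v)

    def test_amplitude_roundtrip(self):
        for vt, T in ((0.5e-3, 5.0), (2e-3, 1.5)):
            A = amplitude_for_tidal_volume(vt, T, S0)
            assert tidal_volume(A, T, S0) == pytest.approx(vt, rel=1e-12)

    def test_nonpositive_arguments_rejected(self):
        with pytest.raises(ValueError):
            tidal_volume(-1.0, 5.0, S0)
        with pytest.raises(ValueError):
            elastic_power(1.0, 0.0, S0, 5e-7)


class AnalyticFlowModel:
    """Flow stub with a power-law constraint curve A(T) = (F/c)^(1/q) T^(-p/q).

    Oxygen flow c·A^q·T^p is increasing in A, so the optimizer's bracketing
    logic applies; the constrained power minimum has the closed form
    T* = 2p'·rc/(1−2p') with p' = p/q (from d/dT [A(T)² (T + rc)] = 0).
    """

    def __init__(self, c=1e-4, p=0.6, q=1.0, cap=None):
        self.c, self.p, self.q, self.cap = c, p, q, cap
        self.tree = build_tree(MorphometryParams())

    def oxygen_flow(self, A, T, warm_key=None):
        f = self.c * A**self.q * T**self.p
        return min(f, self.cap) if self.cap is not None else f

    def flows(self, A, T, warm_key=None):
        return None


class TestOptimizer:
    def test_amplitude_root_matches_closed_form(self):
        model = AnalyticFlowModel(p=0.5)
        F = 2e-4
        A = amplitude_for_flow(model, 4.0, F, rtol=1e-6)
        assert A == pytest.approx(F / (model.c * 4.0**0.5), rel=1e-5)

    def test_infeasible_flow_raises_with_supremum(self):
        model = AnalyticFlowModel(cap=1e-4)
        with pytest.raises(InfeasibleFlowError) as err:
            amplitude_for_flow(model, 5.0, 2e-4)
        assert err.value.sup_flow == pytest.approx(1e-4)

    def test_optimum_matches_analytic_minimum(self):
        # p' = 0.3: T* = 0.6 rc / 0.4 = 1.5 π² R C
        mech = MechanicsParams()
        rc = math.pi**2 * mech.R * mech.C
        model = AnalyticFlowModel(p=0.3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            opt = optimal_ventilation(model, 2e-4, mech, T_bracket=(0.5, 8.0),
                                      n_samples=13)
        assert opt.T_star == pytest.approx(1.5 * rc, rel=0.05)
        assert opt.curve.A[0] > opt.curve.A[-1]  # A(T) decreasing
        assert np.all(np.diff(opt.curve.A) < 0)

    def test_optimum_invariant_under_rc_tradeoff(self):
        # scaling R by c and C by 1/c preserves RC, hence T*; power scales
        model = AnalyticFlowModel(p=0.3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            o1 = optimal_ventilation(model, 2e-4, MechanicsParams(R=2e5, C=5e-7),
                                     T_bracket=(0.5, 8.0), n_samples=11)
            o2 = optimal_ventilation(model, 2e-4, MechanicsParams(R=6e5, C=5e-7 / 3),
                                     T_bracket=(0.5, 8.0), n_samples=11)
        assert o1.T_star == pytest.approx(o2.T_star, rel=1e-9)
        assert o1.A_star == pytest.approx(o2.A_star, rel=1e-9)

    def test_g_zero_brackets_grid_minimum(self):
        model = AnalyticFlowModel(p=0.3)
        mech = MechanicsParams()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            opt = optimal_ventilation(model, 2e-4, mech, T_bracket=(0.5, 8.0),
                                      n_samples=13)
        g_lo, g_hi = opt.G_bracket
        assert g_lo < 0 < g_hi

    def test_halving_demand_lowers_amplitude_everywhere(self):
        model = AnalyticFlowModel(p=0.4)
        for T in (2.0, 5.0, 9.0):
            a_full = amplitude_for_flow(model, T, 2e-4, rtol=1e-6)
            a_half = amplitude_for_flow(model, T, 1e-4, rtol=1e-6)
            assert a_half < a_full
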