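"""Blood-side gas equilibria and the alveolar-membrane exchange coefficient.

In the acinus the air-side partial pressure of a gas relaxes toward a local
blood-equilibrium pressure ``P_blood``.  For oxygen, ``P_blood`` balances the
membrane flux against the uptake capacity of flowing blood, dominated by
hemoglobin binding through the sigmoidal Hill saturation curve

    f(P) = P^2.6 / (P^2.6 + 26^2.6),

plus a small plasma-dissolved contribution.  For carbon dioxide, storage is
dominated by the bicarbonate buffer, giving a linear balance whose slope
depends on pH, the CO₂/HCO₃⁻ dissociation constant pK and the local
oxyhemoglobin saturation.

Incoming (pulmonary arterial) blood pressures anchor both balances.  Because
blood reaching a given acinar wall may already have exchanged gas upstream,
the oxygen balance uses an *effective* arterial pressure, calibrated once so
the model's resting respiratory exchange ratio matches physiology (~0.8);
carbon dioxide keeps the textbook arterial value.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .constants import RT_MMHG

__all__ = [
    "BloodParams",
    "MembraneCoefficients",
    "hill_fraction",
    "hill_fraction_derivative",
    "exchange_beta",
    "solve_blood_O2",
    "solve_blood_CO2",
    "co2_buffer_slope",
    "calibrate_efficace_arterial",
]

#: Hill exponent and half-saturation pressure (mmHg) of oxyhemoglobin.
HILL_EXPONENT = 2.6
HILL_P50 = 26.0


@dataclass(frozen=True)
class BloodParams:
    """Hemoglobin, plasma, membrane and arterial-pressure parameters.

    Attributes
    ----------
    Z0 : float
        Hemoglobin concentration in blood (mol m⁻³).
    v_s : float
        Blood velocity along the exchange surface (m s⁻¹).
    pH, pK : float
        Blood pH and the CO₂–bicarbonate dissociation coefficient.
    tau : float
        Alveolo-capillary membrane thickness (m).
    P_aO2, P_aCO2 : float
        Pulmonary arterial partial pressures (mmHg).
    P_art_eff : float
        Effective arterial O₂ pressure (mmHg) used in place of ``P_aO2`` in
        the oxygen balance; the calibrated default reproduces a resting
        respiratory exchange ratio of about 0.8.
    SO2_ref : float
        Fallback oxyhemoglobin saturation (fraction) for the CO₂ balance
        when no local O₂ solution is available.
    """

    Z0: float = 9.93
    v_s: float = 5e-4
    pH: float = 7.4
    pK: float = 6.09072
    tau: float = 1e-6
    P_aO2: float = 40.0
    P_aCO2: float = 47.0
    P_art_eff: float = 88.0
    SO2_ref: float = 0.97

    def __post_init__(self) -> None:
        for name in ("Z0", "v_s", "tau", "P_aO2", "P_aCO2", "P_art_eff"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not (6.8 < self.pH < 7.8):
            raise ValueError(f"pH out of physiological range (6.8, 7.8): {self.pH}")
        if not (0.0 <= self.SO2_ref <= 1.0):
            raise ValueError(f"SO2_ref must be a fraction in [0, 1], got {self.SO2_ref}")

    def with_(self, **kw) -> "BloodParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class MembraneCoefficients:
    """Derived exchange coefficients for one gas.

    ``alpha_mem`` is the membrane permeability D_w·σ_w/τ
    (mol m⁻² s⁻¹ mmHg⁻¹); ``k`` the pressure-to-concentration ratio in water
    (mmHg m³ mol⁻¹), computed from the dimensionless Henry solubility as
    ``RT/henry``; ``beta = 2 k α / r_A`` (s⁻¹) the volumetric exchange rate
    of a cylindrical acinar branch of radius ``r_A``.
    """

    alpha_mem: float
    k: float
    beta: float

    @property
    def surface_conductance(self) -> float:
        """``k·α`` (m s⁻¹): membrane conductance in pressure units."""
        return self.k * self.alpha_mem


def hill_fraction(P):
    """Oxyhemoglobin saturation fraction at O₂ partial pressure ``P`` (mmHg).

    Strictly increasing, 0 at P=0, exactly ½ at the half-saturation
    pressure of 26 mmHg, and bounded by 1.
    """
    P = np.asarray(P, dtype=float)
    if np.any(P < 0):
        raise ValueError("O2 partial pressure must be nonnegative")
    x = P**HILL_EXPONENT
    out = x / (x + HILL_P50**HILL_EXPONENT)
    return out if out.ndim else float(out)


def hill_fraction_derivative(P):
    """d(saturation)/dP (mmHg⁻¹) of the Hill curve."""
    P = np.asarray(P, dtype=float)
    c = HILL_P50**HILL_EXPONENT
    x = np.maximum(P, 1e-12) ** HILL_EXPONENT
    out = HILL_EXPONENT * c * x / (np.maximum(P, 1e-12) * (x + c) ** 2)
    return out if out.ndim else float(out)


def exchange_beta(gas, blood: BloodParams, r_A: float) -> MembraneCoefficients:
    """Membrane permeability, Henry ratio and exchange rate for one gas.

    Parameters
    ----------
    gas : GasSpecies
        Physical constants of the gas (water diffusivity, solubilities,
        Henry constant).
    blood : BloodParams
        Supplies the membrane thickness ``tau``.
    r_A : float
        Acinar branch radius (m).
    """
    if not (blood.tau > 0):
        raise ZeroDivisionError(f"membrane thickness must be positive, got {blood.tau}")
    if not (r_A > 0):
        raise ValueError(f"acinar radius must be positive, got {r_A}")
    alpha = gas.D_water * gas.sigma_blood / blood.tau
    k = RT_MMHG / gas.henry
    beta = 2.0 * k * alpha / r_A
    return MembraneCoefficients(alpha_mem=alpha, k=k, beta=beta)


def _o2_balance(P_b, P_alv, blood: BloodParams, membrane: MembraneCoefficients,
                sigma: float, P_ref: float):
    """Membrane flux minus blood uptake; decreasing in ``P_b``, root = equilibrium."""
    lhs = membrane.alpha_mem * (P_alv - P_b)
    rhs = (4.0 * blood.Z0 * (hill_fraction(P_b) - hill_fraction(P_ref))
           + sigma * (P_b - P_ref)) * blood.v_s
    return lhs - rhs


def solve_blood_O2(P_alv, blood: BloodParams, membrane: MembraneCoefficients,
                   sigma_blood: float, P_art: float | None = None):
    """Blood-equilibrium O₂ pressure (mmHg) facing alveolar pressure ``P_alv``.

    Solves the monotone scalar balance

        α (P_alv − P_b) = [4 Z₀ (f(P_b) − f(P_art)) + σ (P_b − P_art)] v_s

    for ``P_b``.  The left side (membrane supply) decreases and the right
    side (blood uptake) increases in ``P_b``, so the root is unique and lies
    between ``P_art`` and ``P_alv``.  ``P_art`` defaults to the effective
    arterial pressure of ``blood``.  Accepts scalars or arrays.
    """
    P_ref = blood.P_art_eff if P_art is None else P_art
    P_alv_arr = np.atleast_1d(np.asarray(P_alv, dtype=float))
    if np.any(P_alv_arr < 0):
        raise ValueError("alveolar O2 pressure must be nonnegative")
    out = solve_blood_O2_vec(P_alv_arr, blood, membrane, sigma_blood, P_ref)
    return out if np.ndim(P_alv) else float(out[0])


def solve_blood_O2_vec(P_alv: np.ndarray, blood: BloodParams,
                       membrane: MembraneCoefficients, sigma: float,
                       P_ref: float, x0: np.ndarray | None = None,
                       tol: float = 1e-10, max_newton: int = 30) -> np.ndarray:
    """Vectorized Newton solve of the O₂ balance with a bisection fallback.

    Warm-startable (``x0``), used per acinar node per time step by the
    transport solver.  Falls back to ``brentq`` on the (bracketed, monotone)
    balance for any component Newton fails to converge.
    """
    lo = np.minimum(P_alv, P_ref)
    hi = np.maximum(P_alv, P_ref)
    x = np.clip(x0 if x0 is not None else 0.5 * (lo + hi), lo, hi).astype(float)
    f_ref = hill_fraction(P_ref)
    a = membrane.alpha_mem
    for _ in range(max_newton):
        res = (a * (P_alv - x)
               - (4.0 * blood.Z0 * (hill_fraction(x) - f_ref) + sigma * (x - P_ref))
               * blood.v_s)
        if np.all(np.abs(res) < tol * max(1.0, a)):
            break
        dres = -a - (4.0 * blood.Z0 * hill_fraction_derivative(x) + sigma) * blood.v_s
        x = np.clip(x - res / dres, lo, hi)
    res = (a * (P_alv - x)
           - (4.0 * blood.Z0 * (hill_fraction(x) - f_ref) + sigma * (x - P_ref))
           * blood.v_s)
    bad = np.abs(res) >= 1e-8 * max(1.0, a)
    for idx in np.nonzero(bad)[0]:
        l, u = lo[idx], hi[idx]
        if u - l < 1e-14:
            x[idx] = l
            continue
        x[idx] = brentq(_o2_balance, l, u, xtol=1e-12,
                        args=(P_alv[idx], blood, membrane, sigma, P_ref))
    return x


def co2_buffer_slope(blood: BloodParams, sigma: float, SO2) -> float | np.ndarray:
    """Effective blood-side slope of the CO₂ balance (mol m⁻² s⁻¹ mmHg⁻¹).

    ``σ v_s (1 + 10^(pH−pK)) (1 − 0.0289 Z₀ (3.352 − 0.456 SO₂)(8.142 − pH))``
    with SO₂ the oxyhemoglobin saturation as a fraction in [0, 1].
    """
    SO2 = np.asarray(SO2, dtype=float)
    if np.any((SO2 < 0) | (SO2 > 1)):
        raise ValueError("SO2 must be a saturation fraction in [0, 1]")
    factor = 1.0 - 0.0289 * blood.Z0 * (3.352 - 0.456 * SO2) * (8.142 - blood.pH)
    slope = sigma * blood.v_s * (1.0 + 10.0 ** (blood.pH - blood.pK)) * factor
    if np.any(slope <= 0):
        raise ValueError(
            "CO2 buffer slope is non-positive; the hemoglobin correction factor "
            f"(1 - 0.0289 Z0 (3.352 - 0.456 SO2)(8.142 - pH)) = {factor} "
            "reversed sign (check that SO2 is a fraction, not a percentage)")
    return slope if slope.ndim else float(slope)


def solve_blood_CO2(P_alv, blood: BloodParams, membrane: MembraneCoefficients,
                    sigma_blood: float, SO2=None):
    """Blood-equilibrium CO₂ pressure (mmHg) facing alveolar pressure ``P_alv``.

    The bicarbonate-buffer balance

        α (P_alv − P_b) = (P_b − P_aCO2) · slope(pH, pK, SO₂)

    is linear in ``P_b`` and solved in closed form; the result lies between
    the arterial pressure and ``P_alv``.  ``SO2`` is the local oxyhemoglobin
    saturation fraction (defaults to ``blood.SO2_ref``).
    """
    P_alv_arr = np.asarray(P_alv, dtype=float)
    if np.any(P_alv_arr < 0):
        raise ValueError("alveolar CO2 pressure must be nonnegative")
    if SO2 is None:
        SO2 = blood.SO2_ref
    c = co2_buffer_slope(blood, sigma_blood, SO2)
    a = membrane.alpha_mem
    out = (a * P_alv_arr + np.asarray(c) * blood.P_aCO2) / (a + np.asarray(c))
    return out if np.ndim(out) else float(out)


def calibrate_efficace_arterial(tree, blood: BloodParams, target_RER: float = 0.8,
                                pattern=None, solver_config=None,
                                bracket=(40.0, 100.0), tol: float = 0.05):
    """Effective arterial O₂ pressure reproducing a target resting RER.

    Blood arriving at a given acinar wall may already have exchanged gas
    upstream, so the plain arterial O₂ pressure overestimates the uptake
    gradient.  This calibration replaces it by an effective value: the
    respiratory exchange ratio of the resting simulation increases
    monotonically with the effective pressure (a higher pressure throttles
    O₂ uptake while CO₂ output is essentially unchanged), so the target is
    bracketed and solved by ``brentq``.  Each evaluation runs the full
    transport model to its periodic regime.

    Returns ``(P_art_eff, evaluations)`` where ``evaluations`` is the list
    of sampled ``(pressure, RER)`` pairs.

    Parameters
    ----------
    tree : AirwayTree
    blood : BloodParams
        Template; its ``P_art_eff`` is replaced during the search.
    target_RER : float
        Desired VCO₂/VO₂ at rest, in (0.4, 1.0).
    pattern : VentilationPattern, optional
        Defaults to the resting pattern A = 1 m/s, T = 5 s.
    tol : float
        Absolute tolerance on the pressure (mmHg).
    """
    from .geometry import VentilationPattern
    from .transport import CO2, O2, SolverConfig, TransportSolver

    if not (0.4 < target_RER < 1.0):
        raise ValueError(f"target RER must be in (0.4, 1.0), got {target_RER}")
    if pattern is None:
        pattern = VentilationPattern(A=1.0, T=5.0)
    if solver_config is None:
        solver_config = SolverConfig()

    evaluations: list[tuple[float, float]] = []

    def rer_at(p: float) -> float:
        solver = TransportSolver(tree, pattern, blood.with_(P_art_eff=p),
                                 gases=(O2, CO2), config=solver_config)
        r = solver.run_to_periodic().flows.RER
        evaluations.append((p, r))
        return r

    lo, hi = bracket
    r_lo = rer_at(lo)
    if target_RER <= r_lo:
        return lo, evaluations
    r_hi = rer_at(hi)
    if target_RER > r_hi:
        raise ValueError(
            f"target RER {target_RER} not attainable on bracket {bracket}: "
            f"achieved range [{r_lo:.3f}, {r_hi:.3f}]")
    p_star = brentq(lambda p: rer_at(p) - target_RER, lo, hi, xtol=tol)
    return float(p_star), evaluations
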