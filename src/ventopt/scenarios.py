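"""End-to-end physiological experiments: exercise, altitude, geometry, oedema.

Each scenario perturbs one physiological knob of the calibrated resting
model and re-runs the constrained ventilation optimization (or, for the
oedema sweep, the fixed resting ventilation):

* exercise — raise the metabolic O₂ demand (activity table for a 70 kg
  subject) and find the power-optimal (A*, T*) per demand;
* altitude — scale the ambient O₂ partial pressure down while holding the
  resting demand, until the constraint becomes infeasible;
* geometry/resistance — tighten or widen the homothety ratio so the tree's
  Poiseuille resistance changes by a prescribed factor, updating geometry,
  transport and lumped resistance consistently;
* oedema — thicken the alveolo-capillary membrane at fixed resting
  ventilation and record the collapsing O₂ flow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .blood import BloodParams, calibrate_efficace_arterial
from .constants import ATM_PA, R_GAS, T_BODY
from .geometry import (AirwayTree, MorphometryParams, VentilationPattern,
                       build_tree, homothety_for_resistance_factor,
                       poiseuille_resistance)
from .power_optim import (FlowModel, InfeasibleFlowError, MechanicsParams,
                          OptimizationResult, optimal_ventilation)
from .transport import CO2, O2, GasSpecies, SolverConfig, TransportSolver

__all__ = [
    "Scenario",
    "ModelContext",
    "ACTIVITY_DEMANDS",
    "ALTITUDE_FRACTIONS",
    "REST_PATTERN",
    "metabolic_demand_mol_per_s",
    "run_exercise_series",
    "run_altitude_series",
    "run_resistance_sweep",
    "run_oedema_sweep",
]

#: Resting ventilation: 12 breaths/min, 0.5 L tidal volume at r0 = 1 cm.
REST_PATTERN = VentilationPattern(A=1.0, T=5.0)

#: Resting metabolic O₂ demand (mol s⁻¹): the physiological resting uptake
#: the calibrated model is anchored to.  Used as the flow constraint of the
#: rest optimization; ``ModelContext(rest_demand=None)`` switches to the
#: model's own computed resting uptake instead.
REST_OXYGEN_DEMAND = 1.32e-4

#: Oxygen cost of reference physical activities (mL O₂ kg⁻¹ min⁻¹).
ACTIVITY_DEMANDS = {
    "walking_5kmh": 11.2,
    "bicycling_15kmh": 20.65,
    "jogging_9kmh": 30.80,
    "basketball": 38.85,
    "ice_hockey": 45.15,
}

#: Ambient O₂ partial pressure vs altitude, as % of the sea-level value.
ALTITUDE_FRACTIONS = {0: 100.0, 1000: 89.0, 2000: 79.0, 3000: 69.0, 4000: 60.0}


def metabolic_demand_mol_per_s(ml_per_kg_min: float, mass_kg: float = 70.0,
                               temperature_K: float = T_BODY) -> float:
    """Convert a volumetric O₂ cost to a molar flow (mol s⁻¹).

    The volumetric rate is read as an ideal-gas volume at 1 atm and
    ``temperature_K`` (body temperature by default).
    """
    if not (ml_per_kg_min > 0 and mass_kg > 0):
        raise ValueError("demand and body mass must be positive")
    m3_per_s = ml_per_kg_min * mass_kg * 1e-6 / 60.0
    return m3_per_s * ATM_PA / (R_GAS * temperature_K)


@dataclass(frozen=True)
class Scenario:
    """One experiment definition.

    ``demand`` is the metabolic O₂ flow; either directly in mol/s
    (``demand_mol_s``) or volumetric (``demand_ml_kg_min`` with
    ``mass_kg``).  ``ambient_o2_percent`` scales the tracheal O₂ pressure
    relative to sea level.  ``R_factor``/``C_factor`` scale the lumped
    mechanics; ``h_override`` replaces the homothety ratio (geometry-linked
    resistance change); ``tau_factor`` thickens the exchange membrane.
    """

    name: str
    demand_mol_s: float | None = None
    demand_ml_kg_min: float | None = None
    mass_kg: float = 70.0
    ambient_o2_percent: float = 100.0
    R_factor: float = 1.0
    C_factor: float = 1.0
    h_override: float | None = None
    tau_factor: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.ambient_o2_percent <= 100.0):
            raise ValueError("ambient O2 fraction must be in (0, 100] percent")
        for f_ in ("R_factor", "C_factor", "tau_factor", "mass_kg"):
            if not (getattr(self, f_) > 0):
                raise ValueError(f"{f_} must be positive")

    def demand(self, rest_anchor: float | None = None) -> float:
        """Resolve the O₂ demand in mol/s (``rest_anchor`` if unspecified)."""
        if self.demand_mol_s is not None:
            return self.demand_mol_s
        if self.demand_ml_kg_min is not None:
            return metabolic_demand_mol_per_s(self.demand_ml_kg_min, self.mass_kg)
        if rest_anchor is None:
            raise ValueError(f"scenario {self.name!r} has no demand specified")
        return rest_anchor


@dataclass
class ModelContext:
    """Shared model configuration for a batch of scenario runs.

    Bundles geometry, blood, gases, mechanics and solver settings, and
    caches the two quantities every scenario needs: the calibrated
    effective arterial O₂ pressure and the resting O₂ flow (the rest
    demand anchor).
    """

    morphometry: MorphometryParams = field(default_factory=MorphometryParams)
    blood: BloodParams = field(default_factory=BloodParams)
    mechanics: MechanicsParams = field(default_factory=MechanicsParams)
    o2: GasSpecies = O2
    co2: GasSpecies = CO2
    solver_config: SolverConfig = field(default_factory=SolverConfig)
    rest_pattern: VentilationPattern = REST_PATTERN
    target_rest_RER: float = 0.8
    calibrate: bool = True
    rest_demand: float | None = REST_OXYGEN_DEMAND
    T_bracket: tuple = (1.0, 15.0)
    n_samples: int = 9

    _tree: AirwayTree | None = None
    _rest_flow: float | None = None
    _calibrated: bool = False

    @property
    def tree(self) -> AirwayTree:
        if self._tree is None:
            self._tree = build_tree(self.morphometry)
        return self._tree

    def calibrated_blood(self) -> BloodParams:
        """Blood parameters with the effective arterial pressure fitted so
        the resting RER matches ``target_rest_RER`` (cached)."""
        if self.calibrate and not self._calibrated:
            p_star, _ = calibrate_efficace_arterial(
                self.tree, self.blood, target_RER=self.target_rest_RER,
                pattern=self.rest_pattern, solver_config=self.solver_config)
            self.blood = self.blood.with_(P_art_eff=p_star)
            self._calibrated = True
        return self.blood

    def rest_oxygen_flow(self) -> float:
        """Resting O₂ demand anchor (mol/s).

        The configured ``rest_demand`` (physiological resting uptake) by
        default; with ``rest_demand=None``, the model's own computed resting
        uptake at the rest pattern.
        """
        if self.rest_demand is not None:
            return self.rest_demand
        if self._rest_flow is None:
            blood = self.calibrated_blood()
            solver = TransportSolver(self.tree, self.rest_pattern, blood,
                                     gases=(self.o2, self.co2),
                                     config=self.solver_config)
            self._rest_flow = solver.run_to_periodic().flows.VO2
        return self._rest_flow

    def flow_model(self, tree: AirwayTree | None = None,
                   blood: BloodParams | None = None,
                   o2: GasSpecies | None = None) -> FlowModel:
        return FlowModel(tree if tree is not None else self.tree,
                         blood if blood is not None else self.calibrated_blood(),
                         gases=(o2 if o2 is not None else self.o2,),
                         config=self.solver_config)

    def flows_at(self, A: float, T: float, tree=None, blood=None, o2=None):
        """Both-gas flow evaluation (for RER at an optimum)."""
        solver = TransportSolver(
            tree if tree is not None else self.tree,
            VentilationPattern(A=A, T=T),
            blood if blood is not None else self.calibrated_blood(),
            gases=(o2 if o2 is not None else self.o2, self.co2),
            config=self.solver_config)
        return solver.run_to_periodic().flows

    def optimize(self, F: float, tree=None, blood=None, o2=None,
                 mech: MechanicsParams | None = None) -> OptimizationResult:
        model = self.flow_model(tree=tree, blood=blood, o2=o2)
        return optimal_ventilation(model, F,
                                   mech if mech is not None else self.mechanics,
                                   T_bracket=self.T_bracket,
                                   n_samples=self.n_samples)


def _optimum_row(ctx: ModelContext, opt: OptimizationResult,
                 tree=None, blood=None, o2=None) -> dict:
    f = ctx.flows_at(opt.A_star, opt.T_star, tree=tree, blood=blood, o2=o2)
    return {
        "T_star_s": opt.T_star,
        "A_star_m_per_s": opt.A_star,
        "P_total_W": opt.power_total,
        "P_elastic_W": opt.power_elastic,
        "P_viscous_W": opt.power_viscous,
        "tidal_volume_m3": opt.tidal_volume,
        "VO2_mol_per_s": f.VO2,
        "VCO2_mol_per_s": f.VCO2,
        "RER": f.RER,
        "band_lo_s": opt.band[0],
        "band_hi_s": opt.band[1],
    }


def run_exercise_series(ctx: ModelContext,
                        activities: dict | None = None) -> pd.DataFrame:
    """Optimal ventilation across increasing metabolic demands.

    Runs one constrained optimization per activity (rest first, anchored to
    the calibrated resting O₂ flow; then the activity table converted for
    the configured body mass) and reports the optimum, power decomposition
    and the RER at each optimum.
    """
    if activities is None:
        activities = ACTIVITY_DEMANDS
    rows = []
    rest_F = ctx.rest_oxygen_flow()
    demands = [("rest", rest_F)] + [
        (name, metabolic_demand_mol_per_s(v)) for name, v in
        sorted(activities.items(), key=lambda kv: kv[1])]
    for name, F in demands:
        try:
            opt = ctx.optimize(F)
        except InfeasibleFlowError:
            rows.append({"activity": name, "VO2_demand_mol_per_s": F,
                         "feasible": False})
            continue
        row = {"activity": name, "VO2_demand_mol_per_s": F, "feasible": True}
        row.update(_optimum_row(ctx, opt))
        rows.append(row)
    return pd.DataFrame(rows)


def run_altitude_series(ctx: ModelContext,
                        fractions: dict | None = None,
                        demand: float | None = None) -> pd.DataFrame:
    """Optimal ventilation under altitude hypoxia at fixed O₂ demand.

    The ambient (tracheal) O₂ partial pressure is scaled to the given
    percentage of sea level per altitude; everything blood-side stays
    fixed.  Altitudes where the demand cannot be met at any amplitude are
    flagged infeasible.
    """
    if fractions is None:
        fractions = ALTITUDE_FRACTIONS
    if demand is None:
        demand = ctx.rest_oxygen_flow()
    rows = []
    for altitude, pct in sorted(fractions.items()):
        o2 = ctx.o2.with_(P_air=ctx.o2.P_air * pct / 100.0)
        base = {"altitude_m": altitude, "ambient_o2_percent": pct,
                "P_air_O2_mmHg": o2.P_air, "VO2_demand_mol_per_s": demand}
        try:
            opt = ctx.optimize(demand, o2=o2)
        except InfeasibleFlowError as err:
            rows.append({**base, "feasible": False})
            continue
        rows.append({**base, "feasible": True, **_optimum_row(ctx, opt, o2=o2)})
    return pd.DataFrame(rows)


def run_resistance_sweep(ctx: ModelContext,
                         factors=(0.7, 1.0, 1.3),
                         geometry_linked: bool = True,
                         demand: float | None = None) -> pd.DataFrame:
    """Optimal ventilation for airway trees of different resistance.

    With ``geometry_linked`` (the physiological reading: a resistance change
    is a geometry change), the homothety ratio is adjusted so the conductive
    tree's Poiseuille resistance scales by each factor; geometry, transport
    and the lumped resistance R are all updated consistently.  Otherwise
    only the lumped R of the power model is scaled (a proximal constriction
    that does not alter gas transport).
    """
    if demand is None:
        demand = ctx.rest_oxygen_flow()
    rows = []
    for factor in factors:
        mech = replace(ctx.mechanics, R=ctx.mechanics.R * factor)
        if geometry_linked:
            params = homothety_for_resistance_factor(factor, ctx.morphometry)
            tree = build_tree(params)
        else:
            params, tree = ctx.morphometry, ctx.tree
        base = {"R_factor": factor, "R_Pa_s_per_m3": mech.R, "h": params.h,
                "R_poiseuille_Pa_s_per_m3": poiseuille_resistance(tree),
                "VO2_demand_mol_per_s": demand}
        try:
            opt = ctx.optimize(demand, tree=tree, mech=mech)
        except InfeasibleFlowError:
            rows.append({**base, "feasible": False})
            continue
        rows.append({**base, "feasible": True, **_optimum_row(ctx, opt, tree=tree)})
    return pd.DataFrame(rows)


def run_oedema_sweep(ctx: ModelContext,
                     tau_factors=tuple(2.0**k for k in range(13)),
                     pattern: VentilationPattern | None = None) -> pd.DataFrame:
    """Resting O₂ flow as the alveolo-capillary membrane thickens.

    Ventilation stays at the resting pattern; each row rescales the
    membrane thickness τ (which divides the exchange coefficient β).  The
    flow is expected to plateau while screening still hides exchange
    surface in reserve, then collapse once the whole surface is recruited.
    """
    if pattern is None:
        pattern = ctx.rest_pattern
    blood0 = ctx.calibrated_blood()
    rows = []
    for factor in tau_factors:
        if factor < 1.0:
            raise ValueError("tau multipliers must be >= 1 (thickening)")
        blood = blood0.with_(tau=blood0.tau * factor)
        solver = TransportSolver(ctx.tree, pattern, blood,
                                 gases=(ctx.o2,), config=ctx.solver_config)
        flows = solver.run_to_periodic().flows
        rows.append({"tau_factor": factor, "tau_m": blood.tau,
                     "VO2_mol_per_s": flows.VO2})
    return pd.DataFrame(rows)
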