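"""Gas transport through the airway tree: convection, diffusion, exchange.

Each gas species obeys a 1-D convection–diffusion equation for its partial
pressure along every branch,

    ∂P/∂t − D ∂²P/∂x² + u(t) ∂P/∂x = 0,

augmented in the acinus by a first-order exchange with blood,
β (P − P_blood), and closed distally by a membrane-flux boundary condition
−D ∂P/∂x = α k (P − P_blood).  Branches of one generation are identical by
symmetry, so a single representative branch per generation (with its
multiplicity) carries the whole tree.  Generations are coupled through
junction pressures governed by a mass balance over the small bifurcation
volume.

The partial-pressure field is continuous through each junction
(``P_i(l_i) = P_bif,i = P_{i+1}(0)``), so the junction mass balance reduces
to a storage term over the bifurcation volume plus the jump in diffusive
flux — the advective contributions cancel by incompressibility.  The
discretization is vertex-centered finite-volume (first-order upwind
convection, central diffusion, backward Euler in time) with the junction
pressures as shared grid nodes whose dual volume is augmented by the
bifurcation volume; the discrete gas content is conserved exactly up to
boundary and exchange fluxes.  The trachea inlet holds the ambient partial
pressure at all times.
The blood-equilibrium pressure entering the exchange terms is recomputed at
every acinar cell from the previous time level (lagged), which keeps each
step linear; the CO₂ balance consumes the oxyhemoglobin saturation of the
local O₂ solution.

Ventilation is sinusoidal; fields are marched whole cycles until the
pressure pattern is periodic, and molar gas flows are averaged over the
final cycle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import solve_banded

from . import blood as blood_mod
from .blood import BloodParams, MembraneCoefficients
from .constants import RT_MMHG
from .geometry import AirwayTree, VentilationPattern

__all__ = [
    "GasSpecies",
    "O2",
    "CO2",
    "SolverConfig",
    "TransportState",
    "FlowResult",
    "PeriodicResult",
    "Adimensionals",
    "TransportSolver",
    "conductive_profile",
    "respiratory_exchange_ratio",
    "adimensional_profile",
]


@dataclass(frozen=True)
class GasSpecies:
    """Physical constants of one gas species.

    ``D_air``/``D_water`` are diffusion coefficients (m² s⁻¹), ``sigma_blood``
    the solubility in blood (mol m⁻³ mmHg⁻¹), ``henry`` the dimensionless
    Henry solubility (aqueous over gas-phase concentration), and ``P_air``
    the ambient partial pressure at the trachea inlet (mmHg).
    """

    name: str
    D_air: float
    D_water: float
    sigma_blood: float
    henry: float
    P_air: float

    def __post_init__(self) -> None:
        for f_ in ("D_air", "D_water", "sigma_blood", "henry"):
            if not (getattr(self, f_) > 0):
                raise ValueError(f"{f_} must be positive, got {getattr(self, f_)}")
        if self.P_air < 0:
            raise ValueError(f"P_air must be nonnegative, got {self.P_air}")

    def with_(self, **kw) -> "GasSpecies":
        return replace(self, **kw)


#: Oxygen defaults.  The tracheal partial pressure corresponds to humidified
#: inspired air at sea level.
O2 = GasSpecies(name="O2", D_air=0.2e-4, D_water=3.3e-9,
                sigma_blood=1.34e-3, henry=2.592e-2, P_air=150.0)

#: Carbon dioxide defaults; ambient CO₂ is essentially zero.
CO2 = GasSpecies(name="CO2", D_air=0.14e-4, D_water=2.505e-9,
                 sigma_blood=3.07e-2, henry=0.594, P_air=0.3)


@dataclass(frozen=True)
class SolverConfig:
    """Numerical settings of the transport solver.

    ``nodes_per_branch`` is the number of grid intervals per branch (each
    branch carries that many intervals between shared endpoint nodes),
    ``steps_per_cycle`` the number of backward-Euler steps per ventilation
    period.  Cycles are repeated until the relative L² change of the full
    pressure state between consecutive cycle starts drops below
    ``periodicity_tol`` (or ``max_cycles`` is hit).  ``distal_bc`` selects
    the distal closure: the physical membrane-flux condition (``"robin"``)
    or a fixed pressure (``"dirichlet"``, for verification against the
    closed-form steady profile).

    ``bifurcation_volumes`` toggles the storage term of the junction mass
    balance.  With it on, each junction node carries its bifurcation volume
    as extra capacitance, which retards the inspired-air front by the
    cumulative junction volume and lowers the gas flows by roughly 20%
    (an extra ~0.05 L of conductive dead space acting on a ~0.15 L alveolar
    tidal delivery).  The default leaves it off — junctions are then pure
    flux-continuity nodes — which is the configuration that reproduces the
    reference physiological flux values this model is calibrated against
    (see the methods note).
    """

    nodes_per_branch: int = 10
    steps_per_cycle: int = 200
    max_cycles: int = 50
    periodicity_tol: float = 1e-6
    exchange: bool = True
    distal_bc: str = "robin"
    distal_pressure: float | None = None
    bifurcation_volumes: bool = False

    def __post_init__(self) -> None:
        if self.nodes_per_branch < 3:
            raise ValueError("need at least 3 cells per branch")
        if self.steps_per_cycle < 4:
            raise ValueError("need at least 4 time steps per cycle")
        if self.distal_bc not in ("robin", "dirichlet"):
            raise ValueError(f"unknown distal_bc {self.distal_bc!r}")
        if self.distal_bc == "dirichlet" and self.distal_pressure is None:
            raise ValueError("distal_bc='dirichlet' requires distal_pressure")


@dataclass
class TransportState:
    """Discretized partial-pressure fields of all tracked gases.

    ``P[name]`` is the flat unknown vector (branch cells interleaved with
    junction scalars); ``P_blood[name]`` caches the lagged blood-equilibrium
    pressures on acinar cells (plus the distal face) for warm starts.
    """

    t: float
    P: dict
    P_blood: dict

    def copy(self) -> "TransportState":
        return TransportState(
            t=self.t,
            P={k: v.copy() for k, v in self.P.items()},
            P_blood={k: v.copy() for k, v in self.P_blood.items()},
        )


@dataclass(frozen=True)
class FlowResult:
    """Cycle-averaged molar gas flows (mol s⁻¹).

    ``VO2`` is oxygen transferred from air to blood, ``VCO2`` carbon dioxide
    transferred from blood to air; both are positive under normal operation.
    ``trachea_influx`` is the net molar influx through the trachea section,
    per gas with the air→lung sign convention.
    """

    VO2: float
    VCO2: float | None
    trachea_influx: dict
    converged: bool
    cycles: int
    residual: float

    @property
    def RER(self) -> float:
        return respiratory_exchange_ratio(self)


@dataclass(frozen=True)
class PeriodicResult:
    """Final periodic cycle of a transport run."""

    state: TransportState
    flows: FlowResult
    times: np.ndarray
    uptake_series: dict
    influx_series: dict
    residual_history: np.ndarray


@dataclass(frozen=True)
class Adimensionals:
    """Per-generation dimensionless numbers of the transport problem.

    ``alpha = l²/(D T)`` compares transient and diffusive time scales,
    ``Pe = l u / D`` convection and diffusion (peak velocity), and
    ``gamma = β l²/D`` blood capture and diffusion (acinar generations only,
    NaN elsewhere).
    """

    generation: np.ndarray
    alpha: np.ndarray
    Pe: np.ndarray
    gamma: np.ndarray


def respiratory_exchange_ratio(flows: FlowResult) -> float:
    """RER = VCO₂/VO₂ of a flow result (requires positive O₂ uptake)."""
    if flows.VCO2 is None:
        raise ValueError("flow result carries no CO2 flow; run with both gases")
    if not (flows.VO2 > 0):
        raise ValueError(f"RER undefined for non-positive VO2={flows.VO2}")
    return flows.VCO2 / flows.VO2


def conductive_profile(tree: AirwayTree, P_air: float, P_sink: float):
    """Closed-form steady conductive profile between inlet and distal sink.

    With no convection, steady diffusion through the conductive tree carries
    a constant total flux, so the per-generation pressure drop scales as
    ``(1/2h)ⁱ`` (total cross-section grows as ``2ⁱ h²ⁱ`` while length shrinks
    as ``hⁱ``).  Returns ``(profile, junction)`` where ``profile(i, x)``
    evaluates the in-branch pressure and ``junction[i]`` is the value at the
    distal end of generation ``i``.
    """
    G = tree.params.G
    q = 1.0 / (2.0 * tree.params.h)
    powers = q ** np.arange(G + 1)
    denom = powers.sum()
    cumulative = np.concatenate([[0.0], np.cumsum(powers)])  # Σ_{k<i}

    def profile(i: int, x):
        l_i = tree.length[i]
        return P_air + (P_sink - P_air) / denom * (cumulative[i] + powers[i] * np.asarray(x) / l_i)

    junction = P_air + (P_sink - P_air) / denom * cumulative[1:]
    return profile, junction


class TransportSolver:
    """Coupled implicit solver for gas transport over the whole tree.

    Parameters
    ----------
    tree, pattern, blood :
        Geometry, sinusoidal ventilation, blood-side parameters.
    gases :
        Sequence of :class:`GasSpecies`; O₂ must come first when CO₂ is
        present, since the CO₂ blood balance consumes the local
        oxyhemoglobin saturation.
    config :
        Numerical settings.
    """

    def __init__(self, tree: AirwayTree, pattern: VentilationPattern,
                 blood: BloodParams, gases=(O2, CO2),
                 config: SolverConfig = SolverConfig()):
        self.tree = tree
        self.pattern = pattern
        self.blood = blood
        self.gases = {g.name: g for g in gases}
        if "CO2" in self.gases and "O2" not in self.gases:
            raise ValueError("CO2 transport requires O2 (for the saturation coupling)")
        self.config = config

        m = config.nodes_per_branch
        ng = tree.n_generations
        self.m = m
        self.ng = ng
        # block g: indices [g*m, (g+1)*m) = interior nodes at x = dx..(m-1)dx
        # followed by the branch's right endpoint (junction g, or the distal
        # node for the last generation); the left endpoint is the previous
        # junction (or the Dirichlet trachea inlet for g = 0)
        self.N = ng * m

        # geometry arrays
        self.dx = tree.length / m                       # (ng,)
        self.S = tree.area                              # (ng,)
        self.vf = tree.velocity_factors()               # (ng,)
        self.vbif = tree.v_bif                          # (ng-1,)

        self.block_idx = (np.arange(ng)[:, None] * m + np.arange(m)[None, :])
        self.junc_idx = (np.arange(1, ng)) * m - 1      # right node of blocks 0..ng-2
        self.distal_idx = ng * m - 1

        self.acinar = np.arange(ng) > tree.params.G     # (ng,) bool
        # nodes carrying blood exchange: contiguous run from the
        # conductive->acinar junction through the distal node
        self.exch_start = (tree.params.G + 1) * m - 1
        self.n_exch = self.N - self.exch_start

        # per-gas membrane/exchange coefficients
        self.membrane = {name: blood_mod.exchange_beta(g, blood, tree.r_acinus)
                         for name, g in self.gases.items()}

        # junction dual volumes (per parent branch): the two adjacent
        # half-cells (dx/2 from the parent, dx/2 from each daughter), plus
        # the bifurcation volume when its storage is enabled
        self.junc_vol = (self.S[:-1] * self.dx[:-1] / 2.0
                         + self.S[1:] * self.dx[1:])
        if config.bifurcation_volumes:
            self.junc_vol = self.junc_vol + self.vbif
        # junction exchange volume (acinar half-cells only)
        self.junc_exch_vol = (self.acinar[:-1] * self.S[:-1] * self.dx[:-1] / 2.0
                              + self.acinar[1:] * self.S[1:] * self.dx[1:])

    # ------------------------------------------------------------------ setup

    def initialize_state(self) -> TransportState:
        """Initial fields: closed-form conductive profile, constant acinus.

        The conductive tree carries the steady zero-velocity profile between
        the ambient pressure and the blood-equilibrium sink; acinar branches
        start uniform at that sink value, which also sets the junction
        pressures by continuity.
        """
        P = {}
        P_blood = {}
        sinks = {}
        for name, gas in self.gases.items():
            mem = self.membrane[name]
            if name == "O2":
                sink = blood_mod.solve_blood_O2(gas.P_air, self.blood, mem, gas.sigma_blood)
            else:
                so2 = blood_mod.hill_fraction(sinks.get("O2", self.blood.P_art_eff))
                sink = blood_mod.solve_blood_CO2(gas.P_air, self.blood, mem,
                                                 gas.sigma_blood, SO2=so2)
            sinks[name] = sink
            vec = np.empty(self.N)
            profile, _ = conductive_profile(self.tree, gas.P_air, sink)
            m = self.m
            for g in range(self.ng):
                xj = np.arange(1, m + 1) * self.dx[g]   # nodes incl. right endpoint
                vec[self.block_idx[g]] = sink if self.acinar[g] else profile(g, xj)
            P[name] = vec
            P_blood[name] = np.full(self.n_exch, sink)
        return TransportState(t=0.0, P=P, P_blood=P_blood)

    # ------------------------------------------------------------- blood side

    def _blood_pressures(self, state: TransportState) -> dict:
        """Blood equilibria at all exchanging nodes, with sensitivities.

        Returns, per gas, ``(P_b, dP_b/dP_alv)`` evaluated at the previous
        time level.  The derivative is used to linearize the exchange term
        semi-implicitly (the blood pressure tracks the local alveolar
        pressure, so a fully lagged source is only conditionally stable at
        large time steps).
        """
        out = {}
        for name, gas in self.gases.items():
            mem = self.membrane[name]
            a = mem.alpha_mem
            P_alv = np.clip(state.P[name][self.exch_start:], 0.0, None)
            if name == "O2":
                pb = blood_mod.solve_blood_O2_vec(
                    P_alv, self.blood, mem, gas.sigma_blood,
                    self.blood.P_art_eff,
                    x0=state.P_blood.get(name))
                uptake_slope = (4.0 * self.blood.Z0
                                * blood_mod.hill_fraction_derivative(pb)
                                + gas.sigma_blood) * self.blood.v_s
                dpb = a / (a + uptake_slope)
            else:
                so2 = blood_mod.hill_fraction(out["O2"][0]) if "O2" in out \
                    else self.blood.SO2_ref
                pb = blood_mod.solve_blood_CO2(P_alv, self.blood, mem,
                                               gas.sigma_blood, SO2=so2)
                c = blood_mod.co2_buffer_slope(self.blood, gas.sigma_blood, so2)
                dpb = a / (a + np.asarray(c)) * np.ones_like(pb)
            out[name] = (pb, dpb)
        return out

    # ------------------------------------------------------------------ step

    def advance(self, state: TransportState, dt: float,
                record: dict | None = None) -> TransportState:
        """One backward-Euler step of all gases; advances ``state.t`` by dt.

        With ``record`` a dict, appends the instantaneous molar uptake and
        trachea influx (evaluated on the implicit level, matching the
        discrete budget exactly) under keys ``uptake``/``influx`` per gas.
        """
        if not (dt > 0):
            raise ValueError(f"dt must be positive, got {dt}")
        t_new = state.t + dt
        u0 = float(self.pattern.u0(t_new))
        blood_eq = self._blood_pressures(state)

        new_P = {}
        for name, gas in self.gases.items():
            new_P[name] = self._step_gas(state.P[name], gas, blood_eq[name],
                                         u0, dt, record)
        return TransportState(t=t_new, P=new_P,
                              P_blood={k: v[0] for k, v in blood_eq.items()})

    def _step_gas(self, P_old: np.ndarray, gas: GasSpecies,
                  blood_eq: tuple, u0: float, dt: float,
                  record: dict | None) -> np.ndarray:
        m, ng, N = self.m, self.ng, self.N
        cfg = self.config
        D = gas.D_air
        dx = self.dx
        u = self.vf * u0                    # (ng,) branch velocity
        up = np.maximum(u, 0.0)
        um = np.minimum(u, 0.0)
        c = D / dx                          # diffusive face conductance

        beta = np.zeros(ng)
        if cfg.exchange:
            beta[self.acinar] = self.membrane[gas.name].beta

        bi = self.block_idx                 # (ng, m)
        ji = self.junc_idx                  # (ng-1,)
        es = self.exch_start

        # semi-implicit exchange: flux = β (P − P_b) with P_b linearized
        # around the previous level, P_b ≈ pb + dpb (P^{n+1} − P^n), giving
        # an implicit coefficient β(1−dpb) and a source β(pb − dpb P^n)
        pb, dpb = blood_eq
        one_m = np.zeros(N)                 # (1 − dpb) at exchanging nodes
        src = np.zeros(N)                   # pb − dpb P^n
        one_m[es:] = 1.0 - dpb
        src[es:] = pb - dpb * P_old[es:]

        # every face of block g has flux F = (u⁺+c) P_left + (u⁻−c) P_right
        a_l = up + c                        # coefficient of the upstream node
        a_r = um - c                        # coefficient of the downstream node

        # --- interior-node rows (per branch, length units) ------------------
        # rows 0..m-2 of each block: dx/dt (P−Pold) + F_right − F_left + β dx (P−Pb) = 0
        diag_blk = np.empty((ng, m))
        lower_blk = np.empty((ng, m))
        upper_blk = np.empty((ng, m))
        rhs_blk = (dx / dt)[:, None] * P_old[bi]
        diag_blk[:] = (dx / dt + a_l - a_r)[:, None] \
            + (beta * dx)[:, None] * one_m[bi]
        lower_blk[:] = -a_l[:, None]
        upper_blk[:] = a_r[:, None]
        # exchange source at acinar interior nodes
        rhs_blk += (beta * dx)[:, None] * src[bi]
        # trachea inlet: the left neighbor of block 0's first node is P_air
        rhs_blk[0, 0] += a_l[0] * gas.P_air
        lower_blk[0, 0] = 0.0

        diag = np.empty(N)
        lower = np.empty(N)
        upper = np.empty(N)
        rhs = np.empty(N)
        diag[bi] = diag_blk
        lower[bi] = lower_blk
        upper[bi] = upper_blk
        rhs[bi] = rhs_blk

        # --- junction rows (extensive, per parent branch) -------------------
        # W (P−Pold)/dt + 2 S_{g+1} F_{g+1,first} − S_g F_{g,last} + E (P−Pb) = 0
        Sg, Sg1 = self.S[:-1], self.S[1:]
        E = beta[1:] * self.junc_exch_vol if cfg.exchange else np.zeros(ng - 1)
        W = self.junc_vol
        diag[ji] = (W / dt + E * one_m[ji]
                    + 2.0 * Sg1 * (up[1:] + c[1:])
                    - Sg * (um[:-1] - c[:-1]))
        lower[ji] = -Sg * (up[:-1] + c[:-1])
        upper[ji] = 2.0 * Sg1 * (um[1:] - c[1:])
        rhs[ji] = W / dt * P_old[ji] + E * src[ji]

        # --- distal node row (extensive per branch) -------------------------
        di = self.distal_idx
        Sd, dxd = self.S[-1], dx[-1]
        ak = Ed = 0.0
        if cfg.distal_bc == "robin":
            ak = self.membrane[gas.name].surface_conductance if cfg.exchange else 0.0
            Ed = beta[-1] * Sd * dxd / 2.0
            Wd = Sd * dxd / 2.0
            diag[di] = Wd / dt + (Sd * ak + Ed) * one_m[di] - Sd * a_r[-1]
            lower[di] = -Sd * a_l[-1]
            upper[di] = 0.0
            rhs[di] = Wd / dt * P_old[di] + (Sd * ak + Ed) * src[di]
        else:
            diag[di] = 1.0
            lower[di] = 0.0
            upper[di] = 0.0
            rhs[di] = cfg.distal_pressure

        # --- banded solve ---------------------------------------------------
        ab = np.zeros((3, N))
        ab[0, 1:] = upper[:-1]
        ab[1] = diag
        ab[2, :-1] = lower[1:]
        P_new = solve_banded((1, 1), ab, rhs)

        if record is not None:
            uptake = 0.0
            if cfg.exchange:
                # extensive exchange weights: interior acinar nodes, junction
                # half-cells, distal node (membrane + half-cell)
                acin = self.acinar
                node_w = np.zeros(N)
                node_w[bi[acin]] = (beta[acin] * dx[acin] * self.S[acin]
                                    * self.tree.count[acin])[:, None]
                node_w[ji] = self.tree.count[:-1] * E
                node_w[di] = self.tree.count[-1] * (Ed + Sd * ak)
                uptake = float(node_w[es:] @ (one_m[es:] * P_new[es:] - src[es:]))
            influx = self.S[0] * (a_l[0] * gas.P_air + a_r[0] * P_new[0])
            record.setdefault("uptake", {}).setdefault(gas.name, []).append(uptake / RT_MMHG)
            record.setdefault("influx", {}).setdefault(gas.name, []).append(influx / RT_MMHG)
        return P_new

    # ------------------------------------------------------------------ runs

    def run_cycles(self, state: TransportState, n_cycles: int = 1,
                   record: dict | None = None) -> TransportState:
        """March ``n_cycles`` whole ventilation periods."""
        dt = self.pattern.T / self.config.steps_per_cycle
        for _ in range(n_cycles * self.config.steps_per_cycle):
            state = self.advance(state, dt, record=record)
        return state

    def run_to_periodic(self, state: TransportState | None = None) -> PeriodicResult:
        """March whole cycles until the pressure pattern is periodic.

        Convergence is the relative L² change of the concatenated pressure
        state between consecutive cycle starts.  After convergence one more
        cycle is run to record the flux time series from which the
        cycle-averaged molar flows are formed.
        """
        cfg = self.config
        if state is None:
            state = self.initialize_state()
        snapshot = self._flat(state)
        residuals = []
        converged = False
        cycles = 0
        for cycles in range(1, cfg.max_cycles + 1):
            state = self.run_cycles(state, 1)
            current = self._flat(state)
            res = np.linalg.norm(current - snapshot) / max(np.linalg.norm(snapshot), 1e-30)
            residuals.append(res)
            snapshot = current
            if res < cfg.periodicity_tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"pressure pattern not periodic after {cfg.max_cycles} cycles "
                f"(residual {residuals[-1]:.3e} > tol {cfg.periodicity_tol:.1e})",
                RuntimeWarning, stacklevel=2)

        record: dict = {}
        t0 = state.t
        state = self.run_cycles(state, 1, record=record)
        dtv = self.pattern.T / cfg.steps_per_cycle
        times = t0 + dtv * (np.arange(cfg.steps_per_cycle) + 1)
        uptake = {k: np.asarray(v) for k, v in record["uptake"].items()}
        influx = {k: np.asarray(v) for k, v in record["influx"].items()}

        vo2 = float(uptake["O2"].mean()) if "O2" in uptake else float("nan")
        vco2 = -float(uptake["CO2"].mean()) if "CO2" in uptake else None
        flows = FlowResult(
            VO2=vo2, VCO2=vco2,
            trachea_influx={k: float(v.mean()) for k, v in influx.items()},
            converged=converged, cycles=cycles,
            residual=float(residuals[-1]) if residuals else 0.0,
        )
        return PeriodicResult(state=state, flows=flows, times=times,
                              uptake_series=uptake, influx_series=influx,
                              residual_history=np.asarray(residuals))

    def _flat(self, state: TransportState) -> np.ndarray:
        return np.concatenate([state.P[name] for name in self.gases])

    # ------------------------------------------------------------- diagnostics

    def branch_profiles(self, state: TransportState, gas_name: str):
        """Per-generation ``(x_nodes, P)`` arrays for plotting/export.

        Nodes run from the branch inlet (previous junction, or the trachea
        inlet value) to the branch's distal endpoint.
        """
        out = []
        P = state.P[gas_name]
        for g in range(self.ng):
            xj = np.arange(self.m + 1) * self.dx[g]
            left = self.gases[gas_name].P_air if g == 0 else P[g * self.m - 1]
            vals = np.concatenate([[left], P[self.block_idx[g]]])
            out.append((xj, vals))
        return out

    def total_content(self, state: TransportState, gas_name: str) -> float:
        """Tracked molar gas content downstream of the inlet face.

        Sums the dual-cell volumes of all unknowns: interior nodes carry
        ``S dx`` per branch, junction nodes their bifurcation volume plus the
        adjacent half-cells, the distal node its half-cell.
        """
        P = state.P[gas_name]
        w = np.empty(self.N)
        w[self.block_idx] = (self.S * self.dx * self.tree.count)[:, None]
        w[self.junc_idx] = self.tree.count[:-1] * self.junc_vol
        w[self.distal_idx] = self.tree.count[-1] * self.S[-1] * self.dx[-1] / 2.0
        return float((w @ P) / RT_MMHG)


def adimensional_profile(tree: AirwayTree, pattern: VentilationPattern,
                         gas: GasSpecies, blood: BloodParams) -> Adimensionals:
    """Dimensionless transport numbers per generation (peak velocities)."""
    mem = blood_mod.exchange_beta(gas, blood, tree.r_acinus)
    l = tree.length
    u_peak = tree.velocity_factors() * pattern.A
    alpha = l**2 / (gas.D_air * pattern.T)
    Pe = l * u_peak / gas.D_air
    gamma = np.full(tree.n_generations, np.nan)
    acin = np.arange(tree.n_generations) > tree.params.G
    gamma[acin] = mem.beta * l[acin] ** 2 / gas.D_air
    return Adimensionals(generation=np.arange(tree.n_generations),
                         alpha=alpha, Pe=Pe, gamma=gamma)
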