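"""Idealized airway-tree geometry and ventilation kinematics.

The lung is modeled as a symmetric dichotomous bifurcating tree.  The first
17 generations (indices 0..16) form the conductive tree: branch radius and
length shrink by a constant homothety ratio ``h`` at every bifurcation.  The
last 6 generations form the acinus, where all branches keep the size of the
last conductive generation and gas exchange with blood takes place.

Air is treated as incompressible, so the mean axial velocity in a branch
follows from mass conservation at each bifurcation: each branch feeds two
daughters whose combined cross-section is ``2 h²`` times its own, hence the
velocity is amplified by ``1/(2h²)`` per conductive generation.  In the
acinus the cross-section is constant and the velocity simply halves at each
bifurcation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MorphometryParams",
    "AirwayTree",
    "VentilationPattern",
    "build_tree",
    "branch_velocity",
    "poiseuille_resistance",
    "AIR_VISCOSITY",
]

#: Dynamic viscosity of air at body temperature (Pa s), used only by the
#: optional Poiseuille link between homothety ratio and tree resistance.
AIR_VISCOSITY = 1.8e-5


@dataclass(frozen=True)
class MorphometryParams:
    """Parameters defining the symmetric airway tree.

    Attributes
    ----------
    r0 : float
        Trachea radius (m).
    h : float
        Homothety ratio between successive conductive generations, in (0, 1]
        (``h = 1`` is the degenerate non-shrinking tree, useful for tests).
    G : int
        Index of the last conductive generation (default 16, i.e. 17
        conductive generations).
    n_acinar : int
        Number of acinar generations (default 6).

    The trachea length is tied to the radius by the standard
    length-to-diameter ratio 3, i.e. ``l0 = 6 r0``.
    """

    r0: float = 1e-2
    h: float = 0.7937
    G: int = 16
    n_acinar: int = 6

    def __post_init__(self) -> None:
        if not (self.r0 > 0):
            raise ValueError(f"trachea radius must be positive, got r0={self.r0}")
        if not (0 < self.h <= 1):
            raise ValueError(f"homothety ratio must satisfy 0 < h <= 1, got h={self.h}")
        if self.G < 0 or self.n_acinar < 0:
            raise ValueError("generation counts must be nonnegative")

    @property
    def l0(self) -> float:
        """Trachea length (m), ``6 r0``."""
        return 6.0 * self.r0


@dataclass(frozen=True)
class VentilationPattern:
    """Sinusoidal trachea ventilation ``u0(t) = A sin(2π t / T)``.

    ``A`` is the peak air velocity in the trachea (m/s) and ``T`` the
    breathing period (s).  Positive velocity is inspiration.
    """

    A: float
    T: float

    def __post_init__(self) -> None:
        if self.A < 0:
            raise ValueError(f"amplitude must be nonnegative, got A={self.A}")
        if not (self.T > 0):
            raise ValueError(f"period must be positive, got T={self.T}")

    def u0(self, t):
        """Trachea mean velocity (m/s) at time ``t`` (s, scalar or array)."""
        return self.A * np.sin(2.0 * np.pi * np.asarray(t) / self.T)


@dataclass(frozen=True)
class AirwayTree:
    """Fully resolved per-generation geometry of the symmetric tree.

    All arrays cover the conductive generations followed by the acinar
    generations (``n_gen = G + 1 + n_acinar`` entries).  Junction arrays
    (``v_bif``, ``n_bif``) have one entry per inter-generation junction,
    ``n_gen - 1`` in total; junction ``i`` sits between generations ``i``
    and ``i + 1``.
    """

    params: MorphometryParams
    radius: np.ndarray = field(repr=False)
    length: np.ndarray = field(repr=False)
    area: np.ndarray = field(repr=False)
    count: np.ndarray = field(repr=False)
    v_bif: np.ndarray = field(repr=False)
    n_bif: np.ndarray = field(repr=False)

    @property
    def n_conductive(self) -> int:
        return self.params.G + 1

    @property
    def n_acinar(self) -> int:
        return self.params.n_acinar

    @property
    def n_generations(self) -> int:
        return self.radius.size

    @property
    def r_acinus(self) -> float:
        """Radius of an acinar branch (m), equal to the last conductive one."""
        return float(self.radius[self.params.G])

    @property
    def l_acinus(self) -> float:
        return float(self.length[self.params.G])

    @property
    def area_acinus(self) -> float:
        return float(self.area[self.params.G])

    def is_acinar(self, g: int) -> bool:
        return g > self.params.G

    def velocity_factor(self, g: int) -> float:
        """Ratio of the mean branch velocity in generation ``g`` to ``u0``."""
        p = self.params
        if not (0 <= g < self.n_generations):
            raise IndexError(f"generation index {g} out of range [0, {self.n_generations})")
        amp = (1.0 / (2.0 * p.h**2)) ** p.G
        if g <= p.G:
            return (1.0 / (2.0 * p.h**2)) ** g
        # first acinar halving applies at the conductive->acinar transition
        j = g - p.G - 1
        return amp / 2.0 ** (j + 1)

    def velocity_factors(self) -> np.ndarray:
        return np.array([self.velocity_factor(g) for g in range(self.n_generations)])

    def to_frame(self):
        """Geometry as a :class:`pandas.DataFrame`, one row per generation."""
        import pandas as pd

        n = self.n_generations
        vbif = np.concatenate([self.v_bif, [np.nan]])
        return pd.DataFrame(
            {
                "generation": np.arange(n),
                "kind": ["conductive"] * self.n_conductive + ["acinar"] * self.n_acinar,
                "radius_m": self.radius,
                "length_m": self.length,
                "area_m2": self.area,
                "count": self.count,
                "bifurcation_volume_m3": vbif,
            }
        )


def build_tree(params: MorphometryParams) -> AirwayTree:
    """Construct the per-generation geometry from the morphometry parameters.

    Conductive generation ``i`` has radius ``r0 hⁱ``, length ``6 r0 hⁱ`` and
    ``2ⁱ`` branches.  Acinar generations all share the size of the last
    conductive generation and keep doubling in count.  The junction between
    generations ``g`` and ``g+1`` is assigned the volume of three tubular
    stubs, ``π (r_g³/2 + r_{g+1}³)``.
    """
    p = params
    i = np.arange(p.G + 1)
    r_cond = p.r0 * p.h**i
    l_cond = p.l0 * p.h**i
    n_cond = 2.0**i

    r_a = p.r0 * p.h**p.G
    l_a = p.l0 * p.h**p.G
    j = np.arange(p.n_acinar)
    r_acin = np.full(p.n_acinar, r_a)
    l_acin = np.full(p.n_acinar, l_a)
    n_acin = 2.0 ** (p.G + 1 + j)

    radius = np.concatenate([r_cond, r_acin])
    length = np.concatenate([l_cond, l_acin])
    count = np.concatenate([n_cond, n_acin])
    area = np.pi * radius**2

    v_bif = np.pi * (radius[:-1] ** 3 / 2.0 + radius[1:] ** 3)
    n_bif = count[:-1]  # one junction per parent branch

    return AirwayTree(
        params=p,
        radius=radius,
        length=length,
        area=area,
        count=count,
        v_bif=v_bif,
        n_bif=n_bif,
    )


def branch_velocity(tree: AirwayTree, pattern: VentilationPattern, g: int, t):
    """Mean air velocity (m/s) in a generation-``g`` branch at time ``t``.

    Conductive branches amplify the trachea velocity by ``(1/(2h²))``ᵍ;
    acinar branches continue from the last conductive generation with a
    halving per bifurcation (the first halving applied at the transition).
    """
    return tree.velocity_factor(g) * pattern.u0(t)


def poiseuille_resistance(tree: AirwayTree, air_viscosity: float = AIR_VISCOSITY) -> float:
    """Poiseuille resistance (Pa s m⁻³) of the conductive tree.

    Sum over conductive generations of ``8 μ l_i / (π r_i⁴ n_i)`` — branches
    of one generation in parallel, generations in series.  The absolute value
    underestimates the physiological lumped resistance (no upper airway), so
    it is used only to translate homothety-ratio changes into relative
    resistance changes.
    """
    if not (air_viscosity > 0):
        raise ValueError(f"viscosity must be positive, got {air_viscosity}")
    nc = tree.n_conductive
    r = tree.radius[:nc]
    l = tree.length[:nc]
    n = tree.count[:nc]
    return float(np.sum(8.0 * air_viscosity * l / (np.pi * r**4 * n)))


def homothety_for_resistance_factor(
    factor: float, reference: MorphometryParams
) -> MorphometryParams:
    """Homothety ratio whose Poiseuille resistance is ``factor`` × reference.

    Solves for ``h`` such that the conductive-tree Poiseuille resistance
    equals ``factor`` times the resistance at the reference ``h``, keeping
    every other morphometric parameter fixed.  Used by the geometry-linked
    resistance sweeps: a tighter tree (smaller ``h``) raises the resistance.
    """
    from scipy.optimize import brentq

    if not (factor > 0):
        raise ValueError(f"resistance factor must be positive, got {factor}")
    r_ref = poiseuille_resistance(build_tree(reference))

    def _mismatch(h: float) -> float:
        p = MorphometryParams(
            r0=reference.r0, h=h, G=reference.G, n_acinar=reference.n_acinar
        )
        return poiseuille_resistance(build_tree(p)) / r_ref - factor

    h_star = brentq(_mismatch, 0.4, 0.9999, xtol=1e-10)
    return MorphometryParams(
        r0=reference.r0, h=float(h_star), G=reference.G, n_acinar=reference.n_acinar
    )
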