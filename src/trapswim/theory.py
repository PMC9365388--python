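"""Closed-form results for a magnetic microswimmer in a circular trap.

U-turn radius, regime boundaries in the (v, mB/kBT) plane, the magnetic/thermal
energy ratio and the volumetric magnetosome estimate of the magnetic moment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .params import A_UM2_TO_A_M2, KB

POLAR_TRAPPING = "polar_trapping"
U_TURNS = "u_turns"
CIRCLING = "circling"
REGIMES = (POLAR_TRAPPING, U_TURNS, CIRCLING)


def energy_ratio(m: float, B: float, T: float = 305.0) -> float:
    """Ratio of magnetic to thermal energy, m*B/(kB*T).

    Parameters
    ----------
    m : float
        Magnetic moment, A·µm².
    B : float
        Field magnitude, T.
    T : float
        Temperature, K.
    """
    if T <= 0:
        raise ValueError("T must be > 0")
    return m * A_UM2_TO_A_M2 * B / (KB * T)


def uturn_radius(
    m: float, B: float, v: float, Dr: float = 0.1, T: float = 305.0
) -> float:
    """U-turn radius RU = (pi/2) * (kBT/mB) * (v/Dr), µm.

    The radius of the arc traced while the magnetic torque realigns a swimmer
    moving against the field, from the balance of magnetic torque and
    rotational friction. Returns ``inf`` for mB = 0 (no realignment).
    """
    if Dr <= 0:
        raise ValueError("Dr must be > 0")
    alpha = energy_ratio(m, B, T)
    if alpha == 0:
        return math.inf
    if alpha < 0:
        raise ValueError("m*B must be >= 0")
    return (math.pi / 2) * (v / Dr) / alpha


def uturn_radius_alpha(alpha: float, v: float, Dr: float = 0.1) -> float:
    """U-turn radius from the dimensionless energy ratio alpha = mB/kBT, µm."""
    if Dr <= 0:
        raise ValueError("Dr must be > 0")
    if alpha == 0:
        return math.inf
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    return (math.pi / 2) * (v / Dr) / alpha


def regime_boundary_alpha(v: float, Dr: float, Rtrap: float) -> float:
    """Energy ratio at the circling <-> U-turn boundary: (pi/2)(v/Dr)/Rtrap.

    Obtained by solving RU = Rtrap for mB/kBT; above this value U-turns fit
    inside the trap, below it the swimmer circles along the wall.
    """
    if v < 0 or Dr <= 0 or Rtrap <= 0:
        raise ValueError("v >= 0, Dr > 0 and Rtrap > 0 required")
    return (math.pi / 2) * (v / Dr) / Rtrap


def classify_regime(
    v: float, alpha: float, Dr: float, Rtrap: float, Aw: float
) -> str:
    """Classify the trajectory regime from the U-turn radius.

    ``circling`` if RU >= Rtrap (the U-turn does not fit in the trap),
    ``polar_trapping`` if RU <= Aw (the swimmer turns within the wall
    interaction range and stays pinned at the field-side pole), else
    ``u_turns``. Boundary ties are assigned to the outer regimes.
    """
    if Aw >= Rtrap:
        raise ValueError("Aw must be smaller than Rtrap")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    ru = uturn_radius_alpha(alpha, v, Dr) if alpha > 0 else math.inf
    if ru >= Rtrap:
        return CIRCLING
    if ru <= Aw:
        return POLAR_TRAPPING
    return U_TURNS


@dataclass(frozen=True)
class PhasePoint:
    """One point of the (v, mB/kBT) phase diagram with its regime label."""

    v: float
    alpha: float
    regime: str

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")


def phase_diagram(v_values, alpha_values, Dr: float, Rtrap: float, Aw: float):
    """Regime label for every (v, alpha) grid combination.

    Returns a list of :class:`PhasePoint`, row-major over ``v_values`` then
    ``alpha_values``.
    """
    return [
        PhasePoint(v=v, alpha=al, regime=classify_regime(v, al, Dr, Rtrap, Aw))
        for v in v_values
        for al in alpha_values
    ]


@dataclass(frozen=True)
class MagnetosomeStats:
    """Summary statistics of a magnetosome census from TEM imaging.

    ``N`` +/- ``dN`` magnetosomes per cell, crystal radius ``Rm`` +/- ``dRm``
    in nm, and the magnetite moment density ``rhoM`` in A·m²/nm³.
    """

    N: float = 23.8
    dN: float = 8.3
    Rm: float = 19.4
    dRm: float = 4.3
    rhoM: float = 4.8e-22

    def __post_init__(self) -> None:
        for name in ("N", "dN", "Rm", "dRm", "rhoM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.N > 0 and self.dN > self.N:
            warnings.warn(
                "count std exceeds the mean count; check the summary table",
                stacklevel=2,
            )


def magnetic_moment(stats: MagnetosomeStats) -> float:
    """Mean cell moment M = N * (4/3) pi Rm^3 * rhoM, A·m².

    Volumetric estimate: the chain moment is the total magnetite volume times
    the magnetite moment density.
    """
    return stats.N * (4.0 / 3.0) * math.pi * stats.Rm**3 * stats.rhoM


def moment_uncertainty(M: float, stats: MagnetosomeStats) -> float:
    """Propagated uncertainty dM = M * sqrt((dN/N)^2 + (3 dRm/Rm)^2), A·m²."""
    if stats.N == 0 or stats.Rm == 0:
        if stats.dN == 0 and stats.dRm == 0:
            return 0.0
        raise ValueError("N and Rm must be > 0 to propagate uncertainties")
    rel = math.sqrt((stats.dN / stats.N) ** 2 + (3 * stats.dRm / stats.Rm) ** 2)
    return M * rel
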