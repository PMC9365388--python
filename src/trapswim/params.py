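"""Physical parameters and domain types for the trapped-microswimmer model.

Unit system
-----------
Lengths are in micrometres, time in seconds and energy in units of the thermal
energy kB*T. In these units the rotational friction coefficient gamma_r =
kB*T/Dr has the numerical value 1/Dr, the translational friction gamma_t =
kB*T/Dt the value 1/Dt, forces are in kBT/µm and torques in kBT. The wall
torque strength Tw (µm in this system) multiplies the wall force directly, so
fitted values can be used as printed. Magnetic moments are in A·µm² and fields
in tesla; the magnetic torque enters through the dimensionless energy ratio
m*B/(kB*T).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

#: Boltzmann constant, J/K.
KB = 1.380649e-23

#: Conversion factor A·µm² -> A·m².
A_UM2_TO_A_M2 = 1e-12

#: Conversion factor µT -> T.
UT_TO_T = 1e-6

NORTH_SEEKER = "north_seeker"
SOUTH_SEEKER = "south_seeker"


@dataclass(frozen=True)
class SwimmerParams:
    """Physical parameters of one bacterium.

    Parameters
    ----------
    v : float
        Self-propulsion speed, µm/s.
    m : float
        Magnetic moment magnitude, A·µm².
    a : float
        Effective steric body radius for the wall interaction, µm. The cell
        body is a thin spirillum (~3 µm long, ~0.5 µm across); the default
        0.25 µm is its transverse radius, which together with the default
        wall stiffness reproduces the observed near-wall occupancy peaks
        across all trap sizes.
    Dr : float
        Rotational diffusion coefficient, 1/s.
    Dt : float
        Translational diffusion coefficient, µm²/s (Stokes sphere in water
        at ~305 K for the default radius).
    polarity : str
        ``"north_seeker"`` (moment along the propulsion axis, the typical
        case) or ``"south_seeker"`` (moment anti-parallel).
    reversal_rate : float
        Optional Poisson rate of propulsion-sign flips, 1/s. The base model
        has none; the option exists so reversal analytics can be exercised
        against a known ground truth.
    """

    v: float = 40.0
    m: float = 0.36e-3
    a: float = 0.25
    Dr: float = 0.1
    Dt: float = 0.2
    polarity: str = NORTH_SEEKER
    reversal_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.v < 0:
            raise ValueError("v must be >= 0")
        if self.m < 0:
            raise ValueError("m must be >= 0")
        if self.a <= 0:
            raise ValueError("a must be > 0")
        if self.Dr <= 0:
            raise ValueError("Dr must be > 0")
        if self.Dt < 0:
            raise ValueError("Dt must be >= 0")
        if self.polarity not in (NORTH_SEEKER, SOUTH_SEEKER):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.reversal_rate < 0:
            raise ValueError("reversal_rate must be >= 0")

    @property
    def polarity_sign(self) -> int:
        """+1 for a north-seeker, -1 for a south-seeker."""
        return 1 if self.polarity == NORTH_SEEKER else -1


@dataclass(frozen=True)
class Environment:
    """Temperature and magnetic field.

    ``B`` is the magnetic field vector in tesla, in the trap frame (x-y is
    the trap plane; the experimental field points along the trap diameter).
    """

    T: float = 305.0
    B: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("T must be > 0")
        object.__setattr__(self, "B", tuple(float(b) for b in self.B))
        if len(self.B) != 3:
            raise ValueError("B must be a 3-vector")

    @property
    def kBT(self) -> float:
        """Thermal energy kB*T, J."""
        return KB * self.T

    @property
    def B_vec(self) -> np.ndarray:
        return np.asarray(self.B, dtype=float)

    def alpha_vec(self, params: SwimmerParams) -> np.ndarray:
        """Dimensionless magnetic torque vector s*m*B/(kB*T) (3-vector).

        Its magnitude is the energy ratio mB/kBT; its direction is the field
        direction, signed by the swimmer's polarity.
        """
        return (
            params.polarity_sign
            * params.m
            * A_UM2_TO_A_M2
            * self.B_vec
            / self.kBT
        )


def field_for_alpha(
    alpha: float, params: SwimmerParams, T: float = 305.0, direction=(-1.0, 0.0, 0.0)
) -> Environment:
    """Environment whose field magnitude realizes a given energy ratio mB/kBT.

    The default direction (-x) matches the experimental convention of the
    field's north pointing to the left side of the trap.
    """
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    Bmag = alpha * KB * T / (params.m * A_UM2_TO_A_M2)
    return Environment(T=T, B=tuple(Bmag * d))


@dataclass(frozen=True)
class TrapGeometry:
    """Closed cylindrical trap: radius ``Rtrap`` and height ``H``, µm.

    The trap centre is the origin; the axis is z with the floor at -H/2 and
    the ceiling at +H/2.
    """

    Rtrap: float
    H: float = 10.0

    def __post_init__(self) -> None:
        if self.Rtrap <= 0:
            raise ValueError("Rtrap must be > 0")
        if self.H <= 0:
            raise ValueError("H must be > 0")

    def contains(self, r: np.ndarray) -> bool:
        r = np.asarray(r, dtype=float)
        rho = float(np.hypot(r[0], r[1]))
        return rho <= self.Rtrap and abs(r[2]) <= self.H / 2


@dataclass(frozen=True)
class WallModel:
    """Wall interaction law: WCA repulsion plus reorientation torque.

    An imaginary sphere of radius ``Aw`` sits with its centre on the nearest
    point of each wall surface; the bacterium (radius ``a``) is repelled by a
    WCA force that switches on when its centre is closer than ``a + Aw`` to
    the wall, i.e. sigma = (a + Aw) / 2^(1/6) so the force cutoff equals the
    surface interaction range. ``Tw`` multiplies ``e x F`` to give the
    reorientation torque (in kBT for forces in kBT/µm). ``eps`` is the WCA
    energy scale in kBT: a soft scale of order kBT lets the swimmer
    dynamically penetrate the interaction zone while turning, which is what
    places the occupancy peak slightly inside the interaction range. The
    default 0.5 kBT, with the default body radius, reproduces the measured
    peak distances from the wall in every trap size.
    """

    Aw: float
    Tw: float
    eps: float = 0.5

    def __post_init__(self) -> None:
        if self.Aw <= 0:
            raise ValueError("Aw must be > 0")
        if self.Tw < 0:
            raise ValueError("Tw must be >= 0")
        if self.eps <= 0:
            raise ValueError("eps must be > 0")

    def sigma(self, a: float) -> float:
        """WCA length scale for body radius ``a``: (a + Aw)/2^(1/6), µm."""
        return (a + self.Aw) / 2 ** (1 / 6)

    def cutoff(self, a: float) -> float:
        """Force cutoff distance from the wall surface: a + Aw, µm."""
        return a + self.Aw


@dataclass
class SimState:
    """Instantaneous simulation state."""

    r: np.ndarray
    e: np.ndarray
    t: float = 0.0
    propulsion_sign: int = 1

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float).copy()
        self.e = np.asarray(self.e, dtype=float).copy()
        n = np.linalg.norm(self.e)
        if abs(n - 1.0) > 1e-9:
            raise ValueError("orientation must be a unit vector")
        if self.propulsion_sign not in (-1, 1):
            raise ValueError("propulsion_sign must be +/-1")


@dataclass
class Trajectory:
    """Simulated trajectory on a uniform output grid.

    Attributes
    ----------
    t : ndarray (n,)
        Sample times, s, strictly increasing.
    r : ndarray (n, 3)
        Positions, µm.
    e : ndarray (n, 3)
        Unit orientations.
    sign : ndarray (n,)
        Propulsion sign (+/-1) at each sample.
    dt_out : float
        Output sampling interval, s.
    provenance : dict
        Full parameter set and seed that produced the trajectory.
    """

    t: np.ndarray
    r: np.ndarray
    e: np.ndarray
    sign: np.ndarray
    dt_out: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("times must be strictly increasing")
        norms = np.linalg.norm(self.e, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-8):
            raise ValueError("orientations must be unit vectors")

    def __len__(self) -> int:
        return len(self.t)
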