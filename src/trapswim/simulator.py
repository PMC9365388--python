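"""Active Brownian particle simulation in a closed cylindrical micro-trap.

The swimmer is a sphere self-propelled along its orientation vector ``e``,
subject to translational and rotational diffusion, a magnetic torque aligning
its moment with the field, and a wall interaction composed of a WCA repulsion
plus a reorientation torque ``Tw e x F`` (a phenomenological stand-in for the
steric and hydrodynamic wall coupling of an elongated swimmer). In the
package unit system (µm, s, kBT; see :mod:`trapswim.params`) the overdamped
equations of motion read

    dr/dt = v s e + Dt F + sqrt(2 Dt) xi_t
    de/dt = Dr (Gamma x e) + sqrt(2 Dr) (xi_r x e),   Gamma = e x (alpha + Tw F)

with ``alpha = m B / kBT`` the dimensionless magnetic torque vector and
``s = +/-1`` the propulsion sign. Integration is Euler-Maruyama with explicit
renormalization of ``e`` after every step, which keeps the orientation on the
unit sphere.
"""

from __future__ import annotations

import math

import numpy as np

from . import _kernels
from .params import Environment, SimState, SwimmerParams, Trajectory, TrapGeometry, WallModel

__all__ = [
    "wall_force",
    "wall_torque",
    "magnetic_torque",
    "step",
    "simulate",
    "default_fmax",
]

DEFAULT_DT = 1e-4
DEFAULT_DT_OUT = 0.02  # 50 fps, the experimental frame interval


def default_fmax(a: float, Dt: float, dt: float) -> float:
    """Force clamp keeping the per-step force displacement below 0.1*a.

    Dt*F*dt <= 0.1*a  =>  F_max = 0.1*a/(Dt*dt). Infinite when Dt = 0 (the
    force then produces no displacement at all).
    """
    if Dt == 0:
        return math.inf
    return 0.1 * a / (Dt * dt)


def _check_inside(r: np.ndarray, geom: TrapGeometry) -> None:
    rho = math.hypot(r[0], r[1])
    if rho > geom.Rtrap or abs(r[2]) > geom.H / 2:
        raise ValueError(
            f"position {r} lies outside the cylinder "
            f"(Rtrap={geom.Rtrap}, H={geom.H})"
        )


def wall_force(
    r,
    geom: TrapGeometry,
    wall: WallModel,
    a: float,
    fmax: float = math.inf,
) -> np.ndarray:
    """Total WCA wall force on a bacterium centre at ``r``, kBT/µm.

    Sum of independent side-wall, floor and ceiling contributions; each is
    directed away from its surface and vanishes beyond the cutoff a + Aw.
    Raises for positions outside the cylinder.
    """
    r = np.asarray(r, dtype=float)
    _check_inside(r, geom)
    fx, fy, fz = _kernels.wall_force_components(
        r[0], r[1], r[2], geom.Rtrap, geom.H, wall.sigma(a), wall.eps, fmax
    )
    return np.array([fx, fy, fz])


def wall_torque(e, F, Tw: float) -> np.ndarray:
    """Wall reorientation torque Tw * (e x F), kBT; perpendicular to ``e``."""
    e = np.asarray(e, dtype=float)
    F = np.asarray(F, dtype=float)
    return Tw * np.cross(e, F)


def magnetic_torque(
    e, m: float, polarity: str, B, T: float = 305.0
) -> np.ndarray:
    """Magnetic torque (s m e) x B in kBT units.

    ``s`` is +1 for a north-seeker and -1 for a south-seeker; the result is
    ``e x alpha`` with alpha the polarity-signed dimensionless field vector.
    """
    params = SwimmerParams(m=m, polarity=polarity)
    env = Environment(T=T, B=tuple(np.asarray(B, dtype=float)))
    e = np.asarray(e, dtype=float)
    return np.cross(e, env.alpha_vec(params))


def _advance_once(
    r, e, s, dt, params, alpha, geom, wall, fmax, rng
):
    """One Euler-Maruyama substep; returns (r', e', s', inside)."""
    if geom is not None and wall is not None:
        fx, fy, fz = _kernels.wall_force_components(
            r[0], r[1], r[2], geom.Rtrap, geom.H,
            wall.sigma(params.a), wall.eps, fmax,
        )
        F = np.array([fx, fy, fz])
    else:
        F = np.zeros(3)
    Tw = wall.Tw if wall is not None else 0.0

    xi_t = rng.standard_normal(3)
    r_new = (
        r
        + dt * (params.v * s * e + params.Dt * F)
        + math.sqrt(2 * params.Dt * dt) * xi_t
    )
    if geom is not None:
        rho = math.hypot(r_new[0], r_new[1])
        if rho > geom.Rtrap or abs(r_new[2]) > geom.H / 2:
            return r, e, s, False

    G = alpha + Tw * F
    xi_r = rng.standard_normal(3)
    e_new = (
        e
        + dt * params.Dr * (G - np.dot(G, e) * e)
        + math.sqrt(2 * params.Dr * dt) * np.cross(xi_r, e)
    )
    e_new = e_new / np.linalg.norm(e_new)
    if params.reversal_rate > 0 and rng.random() < params.reversal_rate * dt:
        s = -s
    return r_new, e_new, s, True


def step(
    state: SimState,
    params: SwimmerParams,
    env: Environment,
    geom: TrapGeometry | None,
    wall: WallModel | None,
    dt: float,
    rng: np.random.Generator,
    fmax: float | None = None,
) -> SimState:
    """Advance the state by one time step ``dt``.

    Reference (pure-Python) implementation of the same scheme as the compiled
    trajectory kernel. A step that would leave the cylinder is retried as
    2^k substeps of dt/2^k (k <= 10) before raising.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if geom is not None:
        _check_inside(state.r, geom)
    if fmax is None:
        fmax = default_fmax(params.a, params.Dt, dt)
    alpha = env.alpha_vec(params)

    for level in range(11):
        nsub = 1 << level
        dt_s = dt / nsub
        r, e, s = state.r.copy(), state.e.copy(), state.propulsion_sign
        ok = True
        for _ in range(nsub):
            r, e, s, inside = _advance_once(
                r, e, s, dt_s, params, alpha, geom, wall, fmax, rng
            )
            if not inside:
                ok = False
                break
        if ok:
            return SimState(r=r, e=e, t=state.t + dt, propulsion_sign=s)
    raise RuntimeError(
        f"step at t={state.t} would leave the cylinder after 10 halvings"
    )


def _initial_state(
    params: SwimmerParams, geom: TrapGeometry | None, rng: np.random.Generator
):
    """Uniform position in the interior (>= a from all walls) and uniform
    orientation on the sphere."""
    if geom is None:
        r0 = np.zeros(3)
    else:
        rmax = geom.Rtrap - params.a
        zmax = geom.H / 2 - params.a
        if rmax <= 0 or zmax <= 0:
            raise ValueError("trap too small for the body radius")
        rho = rmax * math.sqrt(rng.random())
        phi = 2 * math.pi * rng.random()
        z = rng.uniform(-zmax, zmax)
        r0 = np.array([rho * math.cos(phi), rho * math.sin(phi), z])
    e0 = rng.standard_normal(3)
    e0 /= np.linalg.norm(e0)
    return r0, e0


def simulate(
    params: SwimmerParams,
    env: Environment,
    geom: TrapGeometry | None,
    wall: WallModel | None,
    duration: float,
    dt: float = DEFAULT_DT,
    dt_out: float = DEFAULT_DT_OUT,
    seed: int | None = None,
    initial_state: SimState | None = None,
) -> Trajectory:
    """Simulate one trajectory of duration ``duration`` seconds.

    ``geom=None`` (or ``wall=None``) disables confinement: free-space motion
    with only the magnetic torque and noise. The output grid has spacing
    ``dt_out``; ``dt`` is snapped to an integer divisor of ``dt_out``.
    Reproducible bit-for-bit given ``seed``.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if dt <= 0 or dt > dt_out:
        raise ValueError("need 0 < dt <= dt_out")
    stride = max(1, round(dt_out / dt))
    dt = dt_out / stride
    n_out = int(round(duration / dt_out)) + 1
    n_steps = (n_out - 1) * stride
    if n_steps == 0:
        raise ValueError("duration shorter than one output interval")

    rng = np.random.default_rng(seed)
    if initial_state is None:
        r0, e0 = _initial_state(params, geom if wall is not None else None, rng)
        sign0 = 1
    else:
        r0, e0 = initial_state.r, initial_state.e
        sign0 = initial_state.propulsion_sign
        if geom is not None:
            _check_inside(r0, geom)
    noise_seed = int(rng.integers(2**31 - 1))

    has_walls = geom is not None and wall is not None
    sigma = wall.sigma(params.a) if has_walls else 1.0
    eps = wall.eps if has_walls else 0.0
    Tw = wall.Tw if has_walls else 0.0
    R = geom.Rtrap if has_walls else 0.0
    H = geom.H if has_walls else 0.0
    fmax = default_fmax(params.a, params.Dt, dt)

    t_out = np.empty(n_out)
    r_out = np.empty((n_out, 3))
    e_out = np.empty((n_out, 3))
    s_out = np.empty(n_out, dtype=np.int8)
    status, where = _kernels.simulate_kernel(
        np.asarray(r0, dtype=float),
        np.asarray(e0, dtype=float),
        sign0,
        n_steps,
        dt,
        stride,
        params.v,
        params.Dr,
        params.Dt,
        env.alpha_vec(params),
        Tw,
        sigma,
        eps,
        fmax,
        R,
        H,
        has_walls,
        params.reversal_rate,
        noise_seed,
        t_out,
        r_out,
        e_out,
        s_out,
    )
    if status != _kernels.OK:
        raise RuntimeError(
            f"integration stuck at step {where} (t={where * dt:.4f} s): "
            "step leaves the cylinder after 10 halvings"
        )
    provenance = {
        "params": {
            "v": params.v,
            "m": params.m,
            "a": params.a,
            "Dr": params.Dr,
            "Dt": params.Dt,
            "polarity": params.polarity,
            "reversal_rate": params.reversal_rate,
        },
        "environment": {"T": env.T, "B": list(env.B)},
        "geometry": None if geom is None else {"Rtrap": geom.Rtrap, "H": geom.H},
        "wall": None
        if wall is None
        else {"Aw": wall.Aw, "Tw": wall.Tw, "eps": wall.eps},
        "dt": dt,
        "dt_out": dt_out,
        "duration": duration,
        "seed": seed,
        "noise_seed": noise_seed,
    }
    return Trajectory(
        t=t_out, r=r_out, e=e_out, sign=s_out.astype(int), dt_out=dt_out,
        provenance=provenance,
    )
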