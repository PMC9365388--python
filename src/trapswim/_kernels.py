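"""Numba-compiled hot loops for the ABP integrator.

All functions use the package unit system (µm, s, kBT). They are plain
numerical kernels: validation and bookkeeping live in :mod:`trapswim.simulator`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

TWO_POW_SIXTH = 2.0 ** (1.0 / 6.0)

#: Kernel status codes.
OK = 0
STUCK = 1  # a step left the cylinder even after 10 halvings


@njit(cache=True)
def wca_magnitude(d: float, sigma: float, eps: float) -> float:
    """Repulsive WCA force magnitude at surface distance ``d`` (kBT/µm).

    Zero at and beyond the cutoff 2^(1/6) sigma; diverges as d -> 0.
    """
    if d >= sigma * TWO_POW_SIXTH:
        return 0.0
    if d < 1e-12:
        d = 1e-12
    x6 = (sigma / d) ** 6
    return 24.0 * eps / d * (2.0 * x6 * x6 - x6)


@njit(cache=True)
def wall_force_components(
    x: float,
    y: float,
    z: float,
    R: float,
    H: float,
    sigma: float,
    eps: float,
    fmax: float,
):
    """Total wall force at a point inside the cylinder (kBT/µm).

    Sum of three independent contributions (side wall, floor, ceiling), each
    from an imaginary WCA sphere centred on the nearest point of that
    surface, directed away from the wall, with the per-surface magnitude
    clamped to ``fmax`` (stiff-potential safeguard).
    """
    fx = 0.0
    fy = 0.0
    fz = 0.0
    # side wall
    rho = np.sqrt(x * x + y * y)
    if rho > 1e-12:
        m = wca_magnitude(R - rho, sigma, eps)
        if m > fmax:
            m = fmax
        fx -= m * x / rho
        fy -= m * y / rho
    # floor (z = -H/2), pushes up
    m = wca_magnitude(z + 0.5 * H, sigma, eps)
    if m > fmax:
        m = fmax
    fz += m
    # ceiling (z = +H/2), pushes down
    m = wca_magnitude(0.5 * H - z, sigma, eps)
    if m > fmax:
        m = fmax
    fz -= m
    return fx, fy, fz


@njit(cache=True)
def simulate_kernel(
    r0,
    e0,
    sign0,
    n_steps,
    dt,
    stride,
    v,
    Dr,
    Dt,
    av,          # polarity-signed dimensionless magnetic torque vector m*B/kBT
    Tw,
    sigma,
    eps,
    fmax,
    R,
    H,
    has_walls,
    rev_rate,
    seed,
    t_out,
    r_out,
    e_out,
    s_out,
):
    """Euler-Maruyama integration of the confined ABP equations of motion.

    Position: r' = r + dt (v s e + Dt F) + sqrt(2 Dt dt) xi_t.
    Orientation: e' = normalize(e + dt Dr (G - (G.e)e) + sqrt(2 Dr dt) xi_r x e)
    with G = av + Tw F the total torque generator (magnetic + wall), which is
    the unit-system form of de/dt = (Gamma_total x e)/gamma_r.

    A step that would leave the cylinder is retried as 2^k substeps of dt/2^k
    (fresh noise, k <= 10); if it still fails the kernel stops and returns
    (STUCK, step_index).
    """
    np.random.seed(seed)
    x, y, z = r0[0], r0[1], r0[2]
    ex, ey, ez = e0[0], e0[1], e0[2]
    s = sign0
    avx, avy, avz = av[0], av[1], av[2]

    t_out[0] = 0.0
    r_out[0, 0] = x
    r_out[0, 1] = y
    r_out[0, 2] = z
    e_out[0, 0] = ex
    e_out[0, 1] = ey
    e_out[0, 2] = ez
    s_out[0] = s
    idx = 1

    for k in range(1, n_steps + 1):
        done = False
        for level in range(11):
            nsub = 1 << level
            dt_s = dt / nsub
            sq_t = np.sqrt(2.0 * Dt * dt_s)
            sq_r = np.sqrt(2.0 * Dr * dt_s)
            # trial state
            tx, ty, tz = x, y, z
            tex, tey, tez = ex, ey, ez
            ts = s
            ok = True
            for _ in range(nsub):
                if has_walls:
                    fx, fy, fz = wall_force_components(
                        tx, ty, tz, R, H, sigma, eps, fmax
                    )
                else:
                    fx = 0.0
                    fy = 0.0
                    fz = 0.0
                nx = tx + dt_s * (v * ts * tex + Dt * fx) + sq_t * np.random.standard_normal()
                ny = ty + dt_s * (v * ts * tey + Dt * fy) + sq_t * np.random.standard_normal()
                nz = tz + dt_s * (v * ts * tez + Dt * fz) + sq_t * np.random.standard_normal()
                if has_walls:
                    if nx * nx + ny * ny > R * R or np.abs(nz) > 0.5 * H:
                        ok = False
                        break
                # torque generator G = alpha vector + Tw * F
                gx = avx + Tw * fx
                gy = avy + Tw * fy
                gz = avz + Tw * fz
                gd = gx * tex + gy * tey + gz * tez
                xr0 = np.random.standard_normal()
                xr1 = np.random.standard_normal()
                xr2 = np.random.standard_normal()
                nex = tex + dt_s * Dr * (gx - gd * tex) + sq_r * (xr1 * tez - xr2 * tey)
                ney = tey + dt_s * Dr * (gy - gd * tey) + sq_r * (xr2 * tex - xr0 * tez)
                nez = tez + dt_s * Dr * (gz - gd * tez) + sq_r * (xr0 * tey - xr1 * tex)
                norm = np.sqrt(nex * nex + ney * ney + nez * nez)
                tex, tey, tez = nex / norm, ney / norm, nez / norm
                tx, ty, tz = nx, ny, nz
                if rev_rate > 0.0 and np.random.random() < rev_rate * dt_s:
                    ts = -ts
            if ok:
                x, y, z = tx, ty, tz
                ex, ey, ez = tex, tey, tez
                s = ts
                done = True
                break
        if not done:
            return STUCK, k
        if k % stride == 0:
            t_out[idx] = k * dt
            r_out[idx, 0] = x
            r_out[idx, 1] = y
            r_out[idx, 2] = z
            e_out[idx, 0] = ex
            e_out[idx, 1] = ey
            e_out[idx, 2] = ez
            s_out[idx] = s
            idx += 1
    return OK, n_steps
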