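"""Simulator: forces, torques, stepping, determinism, confinement."""

import math

import numpy as np
import pytest

import trapswim as ts
from trapswim.simulator import default_fmax, magnetic_torque, step, wall_force, wall_torque


GEOM = ts.TrapGeometry(Rtrap=12.8, H=10.0)
WALL = ts.WallModel(Aw=3.0, Tw=11.0)
A = 0.25


def test_wall_force_zero_in_the_interior():
    # centre of the trap: farther than a + Aw from every surface
    F = wall_force([0.0, 0.0, 0.0], GEOM, WALL, a=A)
    assert np.allclose(F, 0.0)


def test_wall_force_points_inward_near_side_wall():
    d = 0.5 * WALL.cutoff(A)
    F = wall_force([GEOM.Rtrap - d, 0.0, 0.0], GEOM, WALL, a=A)
    assert F[0] < 0 and F[1] == pytest.approx(0.0) and F[2] == pytest.approx(0.0)


def test_wall_force_floor_and_ceiling_are_symmetric():
    d = 0.6 * WALL.cutoff(A)
    Ff = wall_force([0.0, 0.0, -GEOM.H / 2 + d], GEOM, WALL, a=A)
    Fc = wall_force([0.0, 0.0, GEOM.H / 2 - d], GEOM, WALL, a=A)
    assert Ff[2] > 0 and Fc[2] < 0
    assert Ff[2] == pytest.approx(-Fc[2])


def test_wall_force_vanishes_exactly_at_cutoff():
    d = WALL.cutoff(A)
    F = wall_force([GEOM.Rtrap - d, 0.0, 0.0], GEOM, WALL, a=A)
    assert np.allclose(F, 0.0, atol=1e-12)
    F_in = wall_force([GEOM.Rtrap - 0.999 * d, 0.0, 0.0], GEOM, WALL, a=A)
    assert F_in[0] < 0


def test_wall_force_monotone_increase_toward_wall():
    ds = np.linspace(0.999, 0.2, 20) * WALL.cutoff(A)
    mags = [
        abs(wall_force([GEOM.Rtrap - d, 0.0, 0.0], GEOM, WALL, a=A)[0]) for d in ds
    ]
    assert all(m2 >= m1 for m1, m2 in zip(mags, mags[1:]))


def test_wall_force_clamp():
    d = 0.05 * WALL.cutoff(A)
    F = wall_force([GEOM.Rtrap - d, 0.0, 0.0], GEOM, WALL, a=A, fmax=5.0)
    assert abs(F[0]) <= 5.0 + 1e-12


def test_wall_force_rejects_outside_positions():
    with pytest.raises(ValueError):
        wall_force([GEOM.Rtrap + 0.1, 0.0, 0.0], GEOM, WALL, a=A)


def test_wall_torque_is_perpendicular_to_e():
    e = np.array([1.0, 0.0, 0.0])
    F = np.array([-3.0, 1.0, 0.5])
    T = wall_torque(e, F, Tw=11.0)
    assert np.allclose(T, 11.0 * np.cross(e, F))
    assert np.dot(T, e) == pytest.approx(0.0)
    assert np.allclose(wall_torque(e, F, 0.0), 0.0)


def test_magnetic_torque_aligns_and_vanishes_when_aligned():
    B = (-500e-6, 0.0, 0.0)
    e_aligned = np.array([-1.0, 0.0, 0.0])
    assert np.allclose(magnetic_torque(e_aligned, 0.36e-3, "north_seeker", B), 0.0)
    e_perp = np.array([0.0, 1.0, 0.0])
    T = magnetic_torque(e_perp, 0.36e-3, "north_seeker", B)
    assert np.linalg.norm(T) == pytest.approx(42.745, abs=0.01)
    # south-seeker torque is opposite
    Ts = magnetic_torque(e_perp, 0.36e-3, "south_seeker", B)
    assert np.allclose(Ts, -T)


def test_default_fmax():
    assert default_fmax(0.25, 0.2, 1e-4) == pytest.approx(0.1 * 0.25 / (0.2 * 1e-4))
    assert default_fmax(0.25, 0.0, 1e-4) == math.inf


def test_step_deterministic_motion_without_noise():
    # Dt = 0, free space, no field: pure self-propulsion along e
    p = ts.SwimmerParams(v=10.0, Dt=0.0, Dr=1e-12)
    st = ts.SimState(r=[0.0, 0.0, 0.0], e=[1.0, 0.0, 0.0])
    rng = np.random.default_rng(0)
    out = step(st, p, ts.Environment(), None, None, dt=0.01, rng=rng)
    assert out.r[0] == pytest.approx(0.1, rel=1e-6)
    assert abs(out.r[1]) < 1e-4 and abs(out.r[2]) < 1e-4


def test_step_preserves_unit_orientation():
    p = ts.SwimmerParams()
    st = ts.SimState(r=[0.0, 0.0, 0.0], e=[0.0, 0.0, 1.0])
    rng = np.random.default_rng(3)
    for _ in range(200):
        st = step(st, p, ts.Environment(), GEOM, WALL, dt=1e-3, rng=rng)
        assert np.linalg.norm(st.e) == pytest.approx(1.0, abs=1e-9)


def test_simulate_is_deterministic_given_seed():
    p = ts.SwimmerParams()
    t1 = ts.simulate(p, ts.Environment(), GEOM, WALL, duration=1.0, seed=42)
    t2 = ts.simulate(p, ts.Environment(), GEOM, WALL, duration=1.0, seed=42)
    assert np.array_equal(t1.r, t2.r) and np.array_equal(t1.e, t2.e)
    t3 = ts.simulate(p, ts.Environment(), GEOM, WALL, duration=1.0, seed=43)
    assert not np.array_equal(t1.r, t3.r)


def test_simulate_output_grid():
    p = ts.SwimmerParams()
    traj = ts.simulate(p, ts.Environment(), GEOM, WALL, duration=2.0, seed=0)
    assert len(traj) == 101
    assert np.allclose(np.diff(traj.t), 0.02)
    assert traj.provenance["seed"] == 0
    assert traj.provenance["geometry"]["Rtrap"] == GEOM.Rtrap


def test_simulate_never_leaves_the_cylinder(size2_trajectory):
    rho = np.hypot(size2_trajectory.r[:, 0], size2_trajectory.r[:, 1])
    assert rho.max() <= GEOM.Rtrap + 1e-9
    assert np.abs(size2_trajectory.r[:, 2]).max() <= GEOM.H / 2 + 1e-9


def test_simulate_free_space_has_no_confinement():
    p = ts.SwimmerParams(v=40.0)
    traj = ts.simulate(p, ts.Environment(), None, None, duration=20.0, seed=5)
    assert np.linalg.norm(traj.r[-1]) > 12.8  # typically far outside any trap


def test_simulate_strong_field_aligns_swimmer():
    p = ts.SwimmerParams()
    env = ts.field_for_alpha(43.0, p)  # field along -x
    traj = ts.simulate(p, env, None, None, duration=30.0, seed=7)
    # after alignment the mean projection approaches the Langevin value
    proj = -traj.e[len(traj) // 2 :, 0]
    L = 1.0 / math.tanh(43.0) - 1.0 / 43.0
    assert np.mean(proj) == pytest.approx(L, abs=0.05)


def test_simulate_respects_initial_state():
    p = ts.SwimmerParams(v=0.0, Dt=0.0, Dr=1e-9)
    st = ts.SimState(r=[1.0, 2.0, 0.5], e=[0.0, 1.0, 0.0])
    traj = ts.simulate(
        p, ts.Environment(), GEOM, WALL, duration=0.1, seed=0, initial_state=st
    )
    assert np.allclose(traj.r[0], [1.0, 2.0, 0.5])
    assert np.allclose(traj.r[-1], [1.0, 2.0, 0.5], atol=1e-6)


def test_simulate_rejects_bad_arguments():
    p = ts.SwimmerParams()
    with pytest.raises(ValueError):
        ts.simulate(p, ts.Environment(), GEOM, WALL, duration=0.0)
    with pytest.raises(ValueError):
        ts.simulate(p, ts.Environment(), GEOM, WALL, duration=1.0, dt=0.1, dt_out=0.02)
    bad = ts.SimState(r=[GEOM.Rtrap + 1, 0.0, 0.0], e=[1.0, 0.0, 0.0])
    with pytest.raises(ValueError):
        ts.simulate(p, ts.Environment(), GEOM, WALL, duration=1.0, initial_state=bad)


def test_radial_peak_insensitive_to_wall_stiffness():
    # the near-wall occupancy peak is set by the torque-alignment dynamics,
    # not by the WCA energy scale: 4+ orders of magnitude in eps move the
    # fitted peak by well under a micrometre
    from trapswim.tracks import Track2D, fit_peak, radial_pdf

    Rtrap = 45.4
    geom = ts.TrapGeometry(Rtrap=Rtrap, H=10.0)
    p = ts.SwimmerParams(v=40.0)
    centers = []
    for eps in (0.5, 1e4):
        wall = ts.WallModel(Aw=6.0, Tw=2.8, eps=eps)
        tracks = []
        for s in range(3):
            traj = ts.simulate(p, ts.Environment(), geom, wall, duration=40.0, seed=300 + s)
            tracks.append(
                Track2D(
                    fragments=[np.column_stack([traj.t, traj.r[:, :2]])],
                    fps=50.0,
                    trap_radius=Rtrap,
                )
            )
        centers.append(fit_peak(radial_pdf(tracks, Rtrap=Rtrap), Rtrap).center)
    assert abs(centers[1] - centers[0]) < 1.0


def test_reversal_rate_flips_propulsion_sign():
    p = ts.SwimmerParams(v=20.0, reversal_rate=0.5)
    traj = ts.simulate(p, ts.Environment(), None, None, duration=40.0, seed=9)
    flips = np.count_nonzero(np.diff(traj.sign))
    # 40 s at 0.5/s -> ~20 flips; allow generous Poisson scatter
    assert 5 <= flips <= 45
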