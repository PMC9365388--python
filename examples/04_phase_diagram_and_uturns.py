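"""Trajectory regimes in the (speed, field-energy) plane, and U-turn radii.

A magnetic swimmer in a trap shows three regimes depending on its U-turn
radius RU = (pi/2)(kBT/mB)(v/Dr):

  circling        RU >= Rtrap  (the turn does not fit in the trap)
  U-turns         Aw < RU < Rtrap
  polar trapping  RU <= Aw     (pinned at the pole the field points to)

The script prints a coarse phase map and then verifies the U-turn radius
formula against detected, circle-fitted U-turns in a simulation.
"""

import numpy as np

import trapswim as ts
from trapswim import theory

Dr, Rtrap, Aw = 0.1, 45.4, 6.0

print("phase map (rows: v in um/s, cols: mB/kBT):")
v_values = [10.0, 20.0, 40.0, 80.0, 150.0]
alphas = [5.0, 15.0, 43.0, 100.0, 300.0]
short = {"polar_trapping": "polar", "u_turns": "uturn", "circling": "circ "}
print("        " + "  ".join(f"{a:6.0f}" for a in alphas))
for v in v_values:
    row = [short[theory.classify_regime(v, a, Dr, Rtrap, Aw)] for a in alphas]
    print(f"v={v:5.0f}  " + "  ".join(f"{r:>6s}" for r in row))

alpha, v = 43.0, 40.0
ru = theory.uturn_radius_alpha(alpha, v, Dr)
print(f"\ntheory: RU = {ru:.2f} um at mB/kBT = {alpha:g}, v = {v:g} um/s")

params = ts.SwimmerParams(v=v)
env = ts.field_for_alpha(alpha, params)
geom = ts.TrapGeometry(Rtrap=Rtrap)
wall = ts.WallModel(Aw=Aw, Tw=2.8)
radii = []
for seed in range(4):
    traj = ts.simulate(params, env, geom, wall, duration=40.0, seed=seed)
    track = ts.wall_cutoff(ts.smooth_track(ts.degrade(traj, seed=seed + 100)))
    for ev in ts.detect_uturns(track, B_direction=env.B_vec[:2], Rtrap=Rtrap):
        f = track.fragments[ev.fragment]
        pts = f[ev.start : ev.stop + 1, 1:3]
        if Rtrap - np.hypot(pts[:, 0], pts[:, 1]).max() > Aw + params.a:
            radii.append(ev.radius)  # wall-free turns obey the theory
print(
    f"simulation: {len(radii)} wall-free U-turns, "
    f"mean circle-fit radius {np.mean(radii):.2f} um"
)
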