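"""Emulate experimental tracking artifacts on a simulated trajectory.

Video tracking at 50 fps loses the bacterium intermittently (a 40 s recording
breaks into ~43 +/- 16 fragments), adds sub-pixel localization noise and
rejects wall-shadow mis-tracks beyond 1.1 trap radii. `degrade` applies the
same artifacts to a clean simulated trajectory, so every analysis routine can
be exercised against a known ground truth.
"""

import numpy as np

import trapswim as ts

params = ts.SwimmerParams(v=40.0)
geom = ts.TrapGeometry(Rtrap=12.8)
wall = ts.WallModel(Aw=3.0, Tw=11.0)

traj = ts.simulate(params, ts.Environment(), geom, wall, duration=40.0, seed=7)
print(f"clean trajectory: {len(traj)} samples at {1 / traj.dt_out:.0f} Hz")

track = ts.degrade(traj, ts.DegradeSpec(noise_sigma=0.05), seed=8)
print(
    f"degraded track:  {len(track.fragments)} fragments, "
    f"{track.n_points} frames, {track.tracked_time:.1f} s tracked"
)

# the analysis chain smooths, applies the wall cutoff and measures speeds
smooth = ts.wall_cutoff(ts.smooth_track(track))
speeds = np.concatenate(ts.instantaneous_speed(smooth))
print(
    f"instantaneous speed: median {np.median(speeds):.1f} um/s "
    f"(simulated propulsion speed: {params.v:.0f} um/s)"
)
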