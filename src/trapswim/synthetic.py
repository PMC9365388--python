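"""Emulation of experimental tracking artifacts on simulated trajectories.

The experimental pipeline records 2D centroid tracks at 50 fps for 40 s,
loses the bacterium intermittently (a 40 s recording breaks into 43±16
continuous fragments), carries sub-pixel localization noise, and rejects
wall-shadow mis-tracks with a cutoff circle at 1.1 trap radii. ``degrade``
applies the same artifacts to a simulated trajectory so every analysis stage
can be exercised against a known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import Environment, SwimmerParams, Trajectory, TrapGeometry, WallModel, field_for_alpha
from .simulator import simulate
from .tracks import Track2D

__all__ = ["DegradeSpec", "degrade", "make_reference_suite", "TRAP_STUDY_ROWS"]

#: Per-trap-size study conditions: trap radius (µm), swimming speed (µm/s),
#: wall torque strength Tw and wall interaction range Aw (µm), as fitted for
#: the five trap sizes.
TRAP_STUDY_ROWS = (
    {"size": 1, "Rtrap": 7.3, "v": 30.0, "Tw": 14.0, "Aw": 2.0},
    {"size": 2, "Rtrap": 12.8, "v": 40.0, "Tw": 11.0, "Aw": 3.0},
    {"size": 3, "Rtrap": 17.9, "v": 45.0, "Tw": 9.5, "Aw": 3.5},
    {"size": 4, "Rtrap": 26.1, "v": 30.0, "Tw": 4.5, "Aw": 3.7},
    {"size": 5, "Rtrap": 45.4, "v": 40.0, "Tw": 2.8, "Aw": 6.0},
)

#: Reference energy ratio mB/kBT at the strong experimental field (500 µT).
ALPHA_AT_500UT = 42.745


@dataclass(frozen=True)
class DegradeSpec:
    """Parameters of the tracking-artifact emulation.

    ``fragments_mean``/``fragments_sd`` describe the number of continuous
    fragments a 40 s recording breaks into; for other durations the mean and
    sd scale linearly with duration. ``noise_sigma`` is i.i.d. Gaussian
    localization noise per coordinate (default 0.05 µm, sub-pixel at the
    experimental 111 nm/px). ``cutoff_factor`` is the wall-shadow rejection
    circle in units of the trap radius.
    """

    fps: float = 50.0
    noise_sigma: float = 0.05
    fragments_mean: float = 43.0
    fragments_sd: float = 16.0
    reference_duration: float = 40.0
    cutoff_factor: float = 1.1
    max_gap: int = 4

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.fragments_mean < 0 or self.fragments_sd < 0:
            raise ValueError("fragment statistics must be >= 0")

    def draw_fragment_count(self, duration: float, rng: np.random.Generator) -> int:
        """Fragment count for a recording of ``duration`` seconds: a normal
        draw with duration-scaled mean and sd, rounded and clipped to >= 1."""
        scale = duration / self.reference_duration
        k = rng.normal(self.fragments_mean * scale, self.fragments_sd * scale)
        return max(1, int(round(k)))


def degrade(
    traj: Trajectory,
    spec: DegradeSpec | None = None,
    seed: int | None = None,
) -> Track2D:
    """Turn a simulated trajectory into an experiment-like 2D track.

    Projects to the trap plane, resamples to ``spec.fps``, adds localization
    noise, and deletes short frame gaps so the track breaks into the target
    number of fragments (break positions uniform at random, gap lengths
    uniform in [1, max_gap] frames). Reproducible given ``seed``. The
    surviving frames are always a time-ordered subsequence of the input.
    """
    if spec is None:
        spec = DegradeSpec()
    frame_dt = 1.0 / spec.fps
    stride = frame_dt / traj.dt_out
    if abs(stride - round(stride)) > 1e-9 or round(stride) < 1:
        raise ValueError(
            f"trajectory sampling ({1 / traj.dt_out:g}/s) is not an integer "
            f"multiple of the target frame rate ({spec.fps:g} fps)"
        )
    stride = int(round(stride))
    t = traj.t[::stride]
    xy = traj.r[::stride, :2]
    n = len(t)
    if n < 2:
        raise ValueError("trajectory shorter than one frame interval")
    duration = t[-1] - t[0]

    rng = np.random.default_rng(seed)
    xy = xy + rng.normal(0.0, spec.noise_sigma, size=xy.shape)

    k = spec.draw_fragment_count(duration, rng)
    keep = np.ones(n, dtype=bool)
    if k > 1:
        # k-1 distinct interior break frames, each deleting a short gap
        n_breaks = min(k - 1, max(0, n - 2))
        cuts = rng.choice(np.arange(1, n - 1), size=n_breaks, replace=False)
        for c in np.sort(cuts):
            gap = rng.integers(1, spec.max_gap + 1)
            keep[c : min(c + gap, n - 1)] = False

    geom = (traj.provenance or {}).get("geometry")
    trap_radius = geom["Rtrap"] if geom else None
    rows = np.column_stack([t, xy])[keep]
    idx = np.flatnonzero(keep)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    fragments = [seg for seg in np.split(rows, breaks + 1) if len(seg)]
    return Track2D(
        fragments=fragments,
        fps=spec.fps,
        trap_radius=trap_radius,
        trap_center=(0.0, 0.0),
    )


def make_reference_suite(
    seed: int,
    n_tracks: int = 6,
    duration: float = 40.0,
    fields_uT=(0.0, 50.0, 500.0),
    rows=TRAP_STUDY_ROWS,
    spec: DegradeSpec | None = None,
    dt: float = 1e-4,
):
    """Synthetic reference tracks for every trap size and field strength.

    For each study row, simulates ``n_tracks`` trajectories at each field
    strength (energy ratio scaled linearly from ~42.7 at 500 µT), degrades
    them into experiment-like tracks, and returns a dict keyed by
    ``(size, field_uT)`` with lists of :class:`Track2D`.
    """
    if spec is None:
        spec = DegradeSpec()
    ss = np.random.SeedSequence(seed)
    suite = {}
    for row in rows:
        geom = TrapGeometry(Rtrap=row["Rtrap"], H=10.0)
        wall = WallModel(Aw=row["Aw"], Tw=row["Tw"])
        for B_uT in fields_uT:
            params = SwimmerParams(v=row["v"])
            alpha = ALPHA_AT_500UT * B_uT / 500.0
            env = (
                field_for_alpha(alpha, params)
                if alpha > 0
                else Environment()
            )
            tracks = []
            for _ in range(n_tracks):
                s_sim, s_deg = ss.spawn(1)[0].generate_state(2) % (2**31 - 1)
                traj = simulate(
                    params, env, geom, wall, duration=duration, dt=dt, seed=int(s_sim)
                )
                tracks.append(degrade(traj, spec, seed=int(s_deg)))
            suite[(row["size"], B_uT)] = tracks
    return suite
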