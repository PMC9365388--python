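"""File formats, run configuration and the end-to-end pipeline.

CSV formats (comma separated, '.' decimal, UTF-8, '#' comment lines):

* track CSV: header ``fragment,t,x,y`` — time in s, positions in µm;
* trajectory CSV: header ``t,x,y,z,ex,ey,ez,sign`` with a JSON sidecar
  carrying the full parameter set and seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .params import Environment, SwimmerParams, Trajectory, TrapGeometry, WallModel
from .simulator import simulate
from .synthetic import DegradeSpec, degrade
from .tracks import (
    Track2D,
    detect_reversals,
    detect_uturns,
    fit_peak,
    heatmap,
    radial_pdf,
    smooth_track,
    wall_cutoff,
)
from .wallfit import fit_wall_params

__all__ = [
    "read_track_csv",
    "write_track_csv",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "RunConfig",
    "load_config",
    "run_pipeline",
]

_TRACK_COLUMNS = ["fragment", "t", "x", "y"]


def write_track_csv(track: Track2D, path) -> None:
    """Write a fragmented track; lossless round trip for finite values."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("# trapswim track: t in s, x/y in um, fragment is a 0-based index\n")
        if track.trap_radius is not None:
            fh.write(
                f"# trap_radius_um={float(track.trap_radius)!r} "
                f"trap_center_um={float(track.trap_center[0])!r},{float(track.trap_center[1])!r} "
                f"fps={float(track.fps)!r}\n"
            )
        else:
            fh.write(f"# fps={float(track.fps)!r}\n")
        fh.write(",".join(_TRACK_COLUMNS) + "\n")
        for fi, frag in enumerate(track.fragments):
            for t, x, y in frag:
                fh.write(f"{fi},{float(t)!r},{float(x)!r},{float(y)!r}\n")


def read_track_csv(path, fps: float | None = None) -> Track2D:
    """Read a track CSV written by :func:`write_track_csv`.

    Metadata comment lines are parsed when present; ``fps`` overrides them.
    Raises with the offending line number for malformed rows, a missing
    header or non-monotone times within a fragment.
    """
    path = Path(path)
    meta = {}
    header_line = None
    data_start = 0
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            for tok in s[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
            continue
        header_line = i
        break
    if header_line is None:
        raise ValueError(f"{path}: no header; expected columns {_TRACK_COLUMNS}")
    header = [c.strip() for c in lines[header_line].strip().split(",")]
    if header != _TRACK_COLUMNS:
        raise ValueError(
            f"{path}:{header_line + 1}: bad header {header}; expected {_TRACK_COLUMNS}"
        )
    data_start = header_line + 1
    rows = []
    for i, line in enumerate(lines[data_start:], start=data_start + 1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        parts = s.split(",")
        if len(parts) != 4:
            raise ValueError(f"{path}:{i}: expected 4 fields, got {len(parts)}")
        try:
            rows.append((int(parts[0]), float(parts[1]), float(parts[2]), float(parts[3])))
        except ValueError as exc:
            raise ValueError(f"{path}:{i}: malformed row ({exc})") from None
    if not rows:
        raise ValueError(f"{path}: no data rows")
    df = pd.DataFrame(rows, columns=_TRACK_COLUMNS)
    fragments = []
    for fi, grp in df.groupby("fragment", sort=True):
        arr = grp[["t", "x", "y"]].to_numpy()
        if len(arr) > 1 and np.any(np.diff(arr[:, 0]) <= 0):
            raise ValueError(f"{path}: non-monotone time in fragment {fi}")
        fragments.append(arr)
    if fps is None:
        fps = float(meta.get("fps", 50.0))
    radius = float(meta["trap_radius_um"]) if "trap_radius_um" in meta else None
    center = (0.0, 0.0)
    if "trap_center_um" in meta:
        cx, cy = meta["trap_center_um"].split(",")
        center = (float(cx), float(cy))
    return Track2D(fragments=fragments, fps=fps, trap_radius=radius, trap_center=center)


def write_trajectory_csv(traj: Trajectory, path) -> None:
    """Write a simulated trajectory plus a ``.json`` provenance sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "t": traj.t,
            "x": traj.r[:, 0],
            "y": traj.r[:, 1],
            "z": traj.r[:, 2],
            "ex": traj.e[:, 0],
            "ey": traj.e[:, 1],
            "ez": traj.e[:, 2],
            "sign": traj.sign,
        }
    )
    with path.open("w", encoding="utf-8") as fh:
        fh.write("# trapswim trajectory: t in s, positions in um, e unit orientation\n")
        df.to_csv(fh, index=False, float_format="%.10g")
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(traj.provenance, indent=1), encoding="utf-8"
    )


def read_trajectory_csv(path) -> Trajectory:
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    sidecar = path.with_suffix(path.suffix + ".json")
    prov = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    t = df["t"].to_numpy()
    dt_out = float(prov.get("dt_out", np.median(np.diff(t)) if len(t) > 1 else 0.02))
    return Trajectory(
        t=t,
        r=df[["x", "y", "z"]].to_numpy(),
        e=df[["ex", "ey", "ez"]].to_numpy(),
        sign=df["sign"].to_numpy(),
        dt_out=dt_out,
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# configuration


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SwimmerConfig(_Strict):
    v: float = 40.0
    m: float = 0.36e-3
    a: float = 0.25
    Dr: float = 0.1
    Dt: float = 0.2
    polarity: str = "north_seeker"
    reversal_rate: float = 0.0


class EnvironmentConfig(_Strict):
    T: float = 305.0
    B: tuple[float, float, float] = (0.0, 0.0, 0.0)


class TrapConfig(_Strict):
    Rtrap: float
    H: float = 10.0


class WallConfig(_Strict):
    Aw: float
    Tw: float
    eps: float = 0.5


class DegradeConfig(_Strict):
    fps: float = 50.0
    noise_sigma: float = 0.05
    fragments_mean: float = 43.0
    fragments_sd: float = 16.0
    cutoff_factor: float = 1.1


class SimulateConfig(_Strict):
    duration: float = 40.0
    dt: float = 1e-4
    dt_out: float = 0.02
    n_trajectories: int = 6


class FitConfig(_Strict):
    aw_grid: list[float]
    tw_grid: list[float]
    replicates: int = 6
    duration: float = 40.0


class RunConfig(_Strict):
    """Full pipeline configuration; unknown keys are rejected."""

    swimmer: SwimmerConfig = Field(default_factory=SwimmerConfig)
    environment: EnvironmentConfig = Field(default_factory=EnvironmentConfig)
    trap: TrapConfig
    wall: WallConfig
    degrade: DegradeConfig = Field(default_factory=DegradeConfig)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    fit: FitConfig | None = None
    seed: int = 0
    outdir: str = "trapswim-out"
    log_level: str = "INFO"

    def swimmer_params(self) -> SwimmerParams:
        return SwimmerParams(**self.swimmer.model_dump())

    def environment_params(self) -> Environment:
        return Environment(**self.environment.model_dump())

    def trap_geometry(self) -> TrapGeometry:
        return TrapGeometry(**self.trap.model_dump())

    def wall_model(self) -> WallModel:
        return WallModel(**self.wall.model_dump())

    def degrade_spec(self) -> DegradeSpec:
        return DegradeSpec(**self.degrade.model_dump())


def load_config(path) -> RunConfig:
    """Load a :class:`RunConfig` from a JSON or TOML file."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        import tomllib

        data = tomllib.loads(path.read_text(encoding="utf-8"))
    else:
        data = json.loads(path.read_text(encoding="utf-8"))
    return RunConfig.model_validate(data)


# ---------------------------------------------------------------------------
# pipeline


def analyze_tracks(tracks, Rtrap: float, B_direction=None, dr: float = 0.1) -> dict:
    """Standard analysis of a set of tracks: smoothing + cutoff, radial PDF
    with Gaussian peak fit, heat-map, reversal rates and U-turns."""
    processed = [wall_cutoff(smooth_track(tr), 1.1) if tr.trap_radius else smooth_track(tr) for tr in tracks]
    pdf = radial_pdf(processed, Rtrap=Rtrap, dr=dr)
    try:
        peak = fit_peak(pdf, Rtrap)
    except ValueError:
        peak = None
    hm, xe, ye = heatmap(processed)
    reversals = []
    uturns = []
    total_time = 0.0
    for tr in processed:
        ev, _ = detect_reversals(tr)
        reversals.extend(ev)
        uturns.extend(detect_uturns(tr, B_direction=B_direction, Rtrap=Rtrap))
        total_time += tr.tracked_time
    return {
        "pdf": pdf,
        "peak": peak,
        "heatmap": (hm, xe, ye),
        "reversals": reversals,
        "reversal_rate": len(reversals) / total_time if total_time else float("nan"),
        "uturns": uturns,
        "tracked_time": total_time,
    }


def run_pipeline(config: RunConfig, outdir=None) -> dict:
    """Simulate -> degrade -> analyze (-> optionally fit walls), end to end.

    Writes trajectory and track CSVs, the radial PDF, event tables, a JSON
    summary and a manifest tying every artifact to the config and seed.
    Bit-identical on rerun with the same config for the simulation stages.
    """
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.swimmer_params()
    env = config.environment_params()
    geom = config.trap_geometry()
    wall = config.wall_model()
    spec = config.degrade_spec()
    ss = np.random.SeedSequence(config.seed)

    tracks = []
    artifacts = []
    for i in range(config.simulate.n_trajectories):
        s_sim, s_deg = (ss.spawn(1)[0].generate_state(2) % (2**31 - 1)).tolist()
        traj = simulate(
            params, env, geom, wall,
            duration=config.simulate.duration,
            dt=config.simulate.dt, dt_out=config.simulate.dt_out,
            seed=s_sim,
        )
        tpath = out / f"trajectory_{i:03d}.csv"
        write_trajectory_csv(traj, tpath)
        track = degrade(traj, spec, seed=s_deg)
        kpath = out / f"track_{i:03d}.csv"
        write_track_csv(track, kpath)
        tracks.append(track)
        artifacts.extend([tpath.name, kpath.name])

    Bvec = env.B_vec
    Bdir = Bvec[:2] if np.linalg.norm(Bvec[:2]) > 0 else None
    report = analyze_tracks(tracks, Rtrap=geom.Rtrap, B_direction=Bdir)

    pdf = report["pdf"]
    pd.DataFrame({"r": pdf.r, "density": pdf.density, "std": pdf.std}).to_csv(
        out / "radial_pdf.csv", index=False
    )
    artifacts.append("radial_pdf.csv")
    if report["uturns"]:
        pd.DataFrame(
            [
                {
                    "fragment": u.fragment, "start": u.start, "stop": u.stop,
                    "cx": u.center[0], "cy": u.center[1],
                    "radius": u.radius, "mean_speed": u.mean_speed,
                }
                for u in report["uturns"]
            ]
        ).to_csv(out / "uturns.csv", index=False)
        artifacts.append("uturns.csv")

    summary = {
        "n_tracks": len(tracks),
        "tracked_time_s": report["tracked_time"],
        "reversal_rate_per_s": report["reversal_rate"],
        "n_uturns": len(report["uturns"]),
        "mean_uturn_radius_um": (
            float(np.mean([u.radius for u in report["uturns"]]))
            if report["uturns"]
            else None
        ),
        "peak": None
        if report["peak"] is None
        else {
            "center_um": report["peak"].center,
            "width_um": report["peak"].width,
            "distance_from_wall_um": report["peak"].distance_from_wall,
        },
    }

    if config.fit is not None:
        fit = fit_wall_params(
            pdf, config.fit.aw_grid, config.fit.tw_grid, params, geom,
            duration=config.fit.duration, replicates=config.fit.replicates,
            seed=int(ss.spawn(1)[0].generate_state(1)[0] % (2**31 - 1)),
        )
        summary["wall_fit"] = {
            "Aw": fit.Aw, "Tw": fit.Tw, "r2_adj": fit.r2_adj,
            "dAw": [fit.dAw_minus, fit.dAw_plus],
            "dTw": [fit.dTw_minus, fit.dTw_plus],
        }

    (out / "summary.json").write_text(json.dumps(summary, indent=1), encoding="utf-8")
    manifest = {
        "config": config.model_dump(),
        "seed": config.seed,
        "artifacts": sorted(set(artifacts + ["summary.json"])),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    report["summary"] = summary
    report["outdir"] = str(out)
    return report
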