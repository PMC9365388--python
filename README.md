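# trapswim

Simulation and trajectory analytics for magnetotactic bacteria swimming in
circular microfluidic traps.

Magnetotactic bacteria (e.g. *Magnetospirillum gryphiswaldense*) carry a chain
of magnetite nanocrystals that acts as a permanent compass needle. Confined in
a shallow circular trap they behave as magnetic active Brownian particles:
they accumulate at the trap wall, and under an in-plane magnetic field they
show three distinct regimes — circling along the wall, U-turns inside the
trap, or pinning at the pole the field points to — controlled by a single
length, the U-turn radius

```
RU = (pi/2) * (kBT / mB) * (v / Dr)
```

`trapswim` implements the full model-and-measurement chain for this system:

- **Simulation** (`trapswim.simulator`): overdamped active Brownian particle
  in a closed cylindrical trap; WCA wall repulsion, wall reorientation torque
  `Tw e x F`, magnetic torque, translational/rotational noise, optional
  Poisson swimming reversals. Euler–Maruyama integration in a numba kernel,
  bit-reproducible given a seed.
- **Theory** (`trapswim.theory`): U-turn radius, regime classification and
  phase diagram in the (speed, mB/kBT) plane, magnetosome-census estimate of
  the magnetic moment with propagated uncertainty.
- **Trajectory analytics** (`trapswim.tracks`): five-point smoothing,
  wall-shadow cutoff, fourth-order instantaneous velocities, radial occupancy
  PDFs with Gaussian peak fits, occupancy heat-maps, reversal detection
  (>150° heading flips over six frames) and U-turn detection with algebraic
  (Kåsa) circle fits.
- **Tracking-artifact emulation** (`trapswim.synthetic`): turns clean
  simulated trajectories into experiment-like 2D tracks — 50 fps sampling,
  localization noise, fragmentation into ~43 ± 16 pieces per 40 s recording —
  so every analysis stage can be validated against a known ground truth.
- **Wall-parameter fitting** (`trapswim.wallfit`): grid-search fit of the two
  unobservable wall parameters (interaction range `Aw`, torque strength `Tw`)
  by adjusted R² against a reference radial distribution, with 10%-of-maximum
  error bounds.
- **I/O and pipeline** (`trapswim.io`): CSV track/trajectory formats with
  lossless round trips, validated JSON/TOML run configs, and an end-to-end
  simulate → degrade → analyze pipeline with a manifest. A thin `trapswim`
  CLI wraps these.

## Worked example

```python
import numpy as np
import trapswim as ts

# a 40 um/s swimmer in the largest study trap (radius 45.4 um), zero field
params = ts.SwimmerParams(v=40.0)
geom = ts.TrapGeometry(Rtrap=45.4, H=10.0)
wall = ts.WallModel(Aw=6.0, Tw=2.8)

tracks = []
for seed in range(6):
    traj = ts.simulate(params, ts.Environment(), geom, wall, duration=40.0, seed=seed)
    tracks.append(ts.Track2D(
        fragments=[np.column_stack([traj.t, traj.r[:, :2]])],
        fps=50.0, trap_radius=geom.Rtrap,
    ))

pdf = ts.radial_pdf(tracks, Rtrap=geom.Rtrap)
peak = ts.fit_peak(pdf, Rtrap=geom.Rtrap)
print(f"occupancy peak at r = {peak.center:.1f} um")   # ~40 um, i.e. ~5.4 um
                                                       # inside the wall
```

With the default parameters this prints a peak centre near 40 µm — the
swimmer spends most of its time in a ~1 µm-wide band about 5.4 µm inside the
45.4 µm wall. At 500 µT (mB/kBT ≈ 43) the same swimmer makes U-turns of
radius `RU ≈ 14.6` µm, and `ts.detect_uturns` recovers that radius from
circle fits to the degraded tracks.

More narrative walk-throughs are in `examples/`:

| script | shows |
| --- | --- |
| `01_confined_swimming.py` | wall accumulation and the radial occupancy peak |
| `02_tracking_artifacts.py` | degrading clean trajectories into realistic tracks |
| `03_wall_parameter_fit.py` | recovering (Aw, Tw) by adjusted-R² grid search |
| `04_phase_diagram_and_uturns.py` | regime map and U-turn radii vs theory |
| `05_magnetic_moment.py` | magnetosome census → magnetic moment ± uncertainty |
| `06_full_pipeline.py` | config-driven end-to-end run with artifacts |

## Command line

```
trapswim simulate --rtrap 45.4 --aw 6 --tw 2.8 --out traj.csv
trapswim degrade --traj traj.csv --out track.csv
trapswim analyze --track track.csv --rtrap 45.4
trapswim fit-walls --reference pdf.csv --rtrap 12.8 --v 40 \
    --aw-grid 2,3,4 --tw-grid 7,11,15
trapswim phase-diagram --rtrap 45.4 --aw 6 --out phases.csv
trapswim moment
trapswim run --config run.toml
```

## Units

Lengths in µm, time in s, energy in kBT. Forces are kBT/µm and the wall
torque strength `Tw` multiplies the wall force directly, so fitted values are
used as-is. Magnetic moments are in A·µm², fields in tesla; the field enters
only through the dimensionless energy ratio mB/kBT.

## Reproduction

- `python -m pytest tests/` runs the full suite, including the end-to-end
  acceptance tests in `tests/test_acceptance.py` (a few minutes on one CPU).
  One documented reference-value discrepancy is deliberately left failing;
  see the docstring of `test_criterion_2_magnetic_moment`.
- `python scripts/acceptance.py --seed 1 --out results/acceptance.json`
  writes the two closed-form headline numbers (magnetic moment and its
  relative uncertainty).
- All simulations are deterministic given their seed; the pipeline writes a
  manifest tying every artifact to its config and seed.

See `docs/methods.md` for the model equations, numerical scheme and the
calibration rationale behind the default parameters.
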