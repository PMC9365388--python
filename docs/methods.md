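# Methods

## Model

The bacterium is modelled as an overdamped active Brownian particle (ABP) at
position `r` with unit orientation `e`, self-propelled at speed `v` along
`s·e` (`s = ±1`, allowing optional Poisson swimming reversals at rate
`reversal_rate`). In the package unit system — lengths in µm, time in s,
energy in kBT — the equations of motion are

```
dr/dt = v s e + Dt F + sqrt(2 Dt) xi_t
de/dt = Dr (Gamma x e) + sqrt(2 Dr) (xi_r x e),   Gamma = e x (alpha + Tw F)
```

where `F` is the wall force (kBT/µm), `alpha = s_p · m B / kBT` the
dimensionless magnetic torque vector (`s_p = +1` for a north-seeker), `Tw`
the wall torque strength and `xi` unit white noise. Since friction
coefficients are `gamma = kBT / D`, all torques are expressed per `kBT`:
rotation rates are `Dr · torque`. The magnetic torque aligns `e` with the
field; the wall torque `Tw e x F` is a phenomenological stand-in for the
steric and hydrodynamic alignment of an elongated swimmer with a nearby wall.

### Trap and wall interaction

The trap is a closed cylinder of radius `Rtrap` and height `H` (default
10 µm), centre at the origin. Each of the three surfaces (side wall, floor,
ceiling) repels the swimmer independently with a WCA (purely repulsive,
truncated Lennard-Jones) force. An imaginary sphere of radius `Aw` sits with
its centre on the nearest point of the surface, so the interaction switches
on when the bacterium centre is within `a + Aw` of the wall:

```
sigma = (a + Aw) / 2^(1/6),   cutoff = a + Aw
|F|(d) = 24 eps/d [ 2 (sigma/d)^12 - (sigma/d)^6 ],  d < cutoff
```

with `d` the centre–surface distance, `a` the effective body radius and
`eps` the WCA energy in kBT.

### Choice of `eps` and `a`

Published parameter tables for this system quote `Aw` and `Tw` per trap
size, plus the position of the near-wall occupancy peak. Two observations
constrain the remaining constants:

1. A very stiff (`eps >> kBT`) wall is inconsistent with the geometry: with
   `Aw ≈ 6` µm on both floor and ceiling of a 10 µm-high trap the two hard
   interaction zones would overlap, and the radial peak would be pushed out
   to the full cutoff distance, farther from the wall than is observed.
2. The observed peak sits slightly *inside* the interaction range: the
   swimmer dynamically penetrates the soft repulsion while the wall torque
   turns it.

A soft energy scale of order kBT reproduces this. The defaults `a = 0.25` µm
(the transverse radius of the spirillum body — the cell is ~3 µm long but
thin) and `eps = 0.5` kBT were calibrated once against the occupancy peak of
the largest trap and then cross-validated against the peak positions of the
other four trap sizes, matching all five within 0.4 µm. They are
configuration options, not hard-coded: `SwimmerParams(a=...)`,
`WallModel(eps=...)`. The fitted peak position is in fact insensitive to
`eps` over at least four orders of magnitude (tested 0.5 → 1e4 kBT, peak
moves < 0.4 µm): the peak is set by the torque-alignment dynamics, not by
the repulsion stiffness.

## Numerical scheme

Euler–Maruyama with time step `dt` (default 1e-4 s), orientation explicitly
renormalized each step, compiled with numba. Output is sampled on a uniform
grid `dt_out` (default 0.02 s = 50 fps, the experimental frame interval);
`dt` is snapped to an integer divisor of `dt_out`.

Robustness details:

- The wall force of each surface is clamped to `F_max = 0.1 a / (Dt dt)` so
  that one step's force displacement never exceeds a tenth of the body
  radius.
- A step that would leave the cylinder is retried as `2^k` substeps of
  `dt/2^k` (k ≤ 10) before the integrator reports failure, so trajectories
  can never escape the trap.
- Noise is generated inside the kernel from a seed drawn once per
  trajectory; `simulate(..., seed=n)` is reproducible bit-for-bit.

The pure-Python `step()` implements the same scheme for reference and
testing.

## Theory

- **U-turn radius** (`uturn_radius`): balancing magnetic torque against
  rotational friction while swimming at `v` gives a turn of lateral half-width
  `RU = (pi/2)(kBT/mB)(v/Dr)`.
- **Regimes** (`classify_regime`): `circling` if `RU >= Rtrap` (the turn
  cannot fit), `polar_trapping` if `RU <= Aw` (the swimmer turns inside the
  wall interaction zone and stays at the field-side pole), else `u_turns`.
  The circling boundary in the (v, alpha) plane is
  `alpha = (pi/2)(v/Dr)/Rtrap`.
- **Magnetic moment from a magnetosome census** (`magnetic_moment`):
  `M = N (4/3) pi Rm^3 rhoM` with propagated relative uncertainty
  `sqrt((dN/N)^2 + (3 dRm/Rm)^2)`.

## Trajectory analytics

All analysis operates on `Track2D` objects — fragmented (t, x, y) tracks at
fixed frame rate — and is applied identically to degraded-simulation and
external data.

- **Smoothing**: five-point moving average per coordinate; endpoints use
  shrinking symmetric windows so straight lines are preserved exactly.
- **Wall cutoff**: points beyond 1.1 trap radii are removed (wall-shadow
  mis-tracks), splitting fragments.
- **Velocities**: five-point fourth-order central stencil in the fragment
  interior, second-order one-sided at the ends.
- **Radial PDF**: per-track histogram normalized to `n / (N 2 pi r dr)` (each
  integrates to exactly 1 over the disc), averaged across tracks with the
  across-track standard deviation. The near-wall peak is fitted with a
  Gaussian `a exp(-(r-b)^2/c^2)` over the contiguous region above 30% of the
  maximum.
- **Reversals**: a reversal is an angle > 150° between the displacement
  direction at frame `i` and at frame `i+6`; consecutive qualifying frames
  merge into one event at the angle maximum. Rates are reported per
  wall-distance bin (2 µm bins near the wall, pooled interior).
- **U-turns**: headings from the fourth-order velocities are scanned for
  monotone rotation runs (20° counter-rotation tolerance) accumulating
  150°–270°; more rotation is wall circling. The fitted span is trimmed to
  the sub-span carrying the central 96% of the rotation (removing straight
  tangent lead-in/out), then circle-fitted with the algebraic Kåsa method.
  Segments overlapping a reversal, with radius within 7 µm of `Rtrap`
  (wall circling), or ending against the field direction are rejected.
  Note that the ideal realignment path is not a circle — its curvature peaks
  mid-turn — so the circle fit approximates `RU` only when it covers the
  whole turn; fits restricted to the fast core of the turn would
  systematically read ~ (2/pi) RU. Quantitative comparisons against the
  `RU` formula should use *wall-free* turns (arcs that stay outside the wall
  interaction range), since wall-assisted or truncated turns do not follow
  free realignment.

## Synthetic tracking data

`degrade` emulates the experimental tracking pipeline on a simulated
trajectory: projection to the trap plane, resampling to 50 fps, i.i.d.
Gaussian localization noise (default sigma 0.05 µm, sub-pixel), and deletion
of short random gaps so a 40 s recording fragments into ~43 ± 16 pieces
(mean and sd scale with duration). Scope: it reproduces the *statistical*
artifacts relevant to the analysis chain (sampling, noise, fragmentation,
wall-shadow cutoff), not the imaging physics; there is no model of the
optical wall shadow itself, of tracking identity swaps, or of
cell-to-cell parameter variability within one recording.

## Wall-parameter fitting

`fit_wall_params` grid-searches (Aw, Tw): for each candidate pair it
simulates several zero-field trajectories (replicates play the role of the
~6 traps pooled per experimental condition), builds the mean radial PDF on
the reference grid and scores it with the adjusted R²

```
R2_adj = 1 - [(n-1)/(n-nu-1)] (SS_res / SS_tot),   nu = 2
```

(`n` radial bins). Grid search is used because the objective is stochastic;
everything is deterministic given the top-level seed (replicate seeds are
spawned from a `SeedSequence`). One-at-a-time error bounds are the outermost
grid values whose score stays within 10% of the maximum; intervals reaching
the grid edge are flagged as open.

## Limitations

- The ABP is a sphere with an effective body radius; elongation enters only
  through the phenomenological wall torque.
- Hydrodynamic interactions with the walls are not modelled explicitly.
- The magnetic moment is fixed and body-aligned; no magnetization dynamics.
- The wall-parameter fit assumes the swimming speed is known (measured from
  the tracks) and fits only (Aw, Tw).
- Fragmentation is modelled as random short gaps; real tracking loss is
  correlated with the wall shadow and crossings.
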