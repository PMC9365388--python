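"""Trajectory analytics for 2D bacterial tracks in circular traps.

Implements the analysis chain applied identically to experimental-style and
simulated tracks: five-point smoothing, wall-shadow cutoff, fourth-order
instantaneous velocities, radial occupancy PDFs with Gaussian peak fits,
occupancy heat-maps, reversal detection (abrupt >150° heading flips over a
six-frame lag) and U-turn detection with algebraic circle fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "Track2D",
    "RadialPDF",
    "PeakFit",
    "ReversalEvent",
    "UTurnEvent",
    "smooth_track",
    "wall_cutoff",
    "instantaneous_speed",
    "radial_pdf",
    "fit_peak",
    "heatmap",
    "detect_reversals",
    "fit_circle",
    "detect_uturns",
]


@dataclass
class Track2D:
    """A fragmented 2D track at a fixed frame rate.

    ``fragments`` is a list of (n_i, 3) arrays with columns (t, x, y); times
    are strictly increasing within each fragment and fragments do not overlap
    in time. ``trap_radius``/``trap_center`` may be ``None`` for unconfined
    tracks.
    """

    fragments: list
    fps: float = 50.0
    trap_radius: float | None = None
    trap_center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        frags = []
        t_prev_end = -math.inf
        for f in self.fragments:
            f = np.asarray(f, dtype=float)
            if f.ndim != 2 or f.shape[1] != 3:
                raise ValueError("each fragment must be an (n, 3) array of (t, x, y)")
            if len(f) > 1 and np.any(np.diff(f[:, 0]) <= 0):
                raise ValueError("times must be strictly increasing within a fragment")
            if len(f) and f[0, 0] <= t_prev_end:
                raise ValueError("fragments must not overlap in time")
            if len(f):
                t_prev_end = f[-1, 0]
            frags.append(f)
        self.fragments = frags
        if self.fps <= 0:
            raise ValueError("fps must be > 0")

    @property
    def n_points(self) -> int:
        return sum(len(f) for f in self.fragments)

    @property
    def tracked_time(self) -> float:
        """Total tracked time, s (frames times the frame interval)."""
        return self.n_points / self.fps

    def points(self) -> np.ndarray:
        """All (t, x, y) rows concatenated."""
        if not self.fragments:
            return np.empty((0, 3))
        return np.concatenate(self.fragments, axis=0)

    def radii(self) -> np.ndarray:
        """Distance of every point from the trap centre."""
        p = self.points()
        cx, cy = self.trap_center
        return np.hypot(p[:, 1] - cx, p[:, 2] - cy)


@dataclass
class RadialPDF:
    """Radial occupancy probability density, averaged over traps.

    ``density`` is the mean of the per-trap densities n/(N_pts * 2 pi r dr);
    each per-trap density integrates to 1 over the disc. ``std`` is the
    standard deviation across traps (zero when only one trap is pooled).
    """

    r: np.ndarray
    dr: float
    density: np.ndarray
    std: np.ndarray
    n_traps: int
    counts: np.ndarray = field(default=None, repr=False)

    def integral(self) -> float:
        return float(np.sum(self.density * 2 * np.pi * self.r * self.dr))


@dataclass(frozen=True)
class PeakFit:
    """Gaussian a*exp(-(r-b)^2/c^2) fitted to the near-wall occupancy peak."""

    amplitude: float
    center: float
    scale: float
    width: float
    distance_from_wall: float


@dataclass(frozen=True)
class ReversalEvent:
    """An abrupt heading flip: frame index (global within the track), the
    position where it happened and its distance from the wall (None for
    unconfined tracks)."""

    fragment: int
    frame: int
    position: tuple[float, float]
    distance_from_wall: float | None


@dataclass(frozen=True)
class UTurnEvent:
    """A detected U-turn: the fragment-local frame span, the fitted circle
    and the mean speed over the span."""

    fragment: int
    start: int
    stop: int
    center: tuple[float, float]
    radius: float
    mean_speed: float


# ---------------------------------------------------------------------------
# smoothing / filtering / kinematics


def _moving_average_shrinking(x: np.ndarray, half: int = 2) -> np.ndarray:
    """Centred moving average with shrinking symmetric windows at the ends.

    Interior points use the full 2*half+1 window; point i uses half-width
    min(i, n-1-i, half), so endpoints pass through unchanged and straight
    lines are preserved exactly everywhere.
    """
    n = len(x)
    out = np.empty_like(x)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    for i in range(n):
        h = min(i, n - 1 - i, half)
        out[i] = (csum[i + h + 1] - csum[i - h]) / (2 * h + 1)
    return out


def smooth_track(track: Track2D, window: int = 5) -> Track2D:
    """Five-point moving average of each coordinate, per fragment.

    Fragments shorter than the window pass through unchanged; endpoints use
    shrinking symmetric windows.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    half = window // 2
    frags = []
    for f in track.fragments:
        if len(f) < window:
            frags.append(f.copy())
            continue
        g = f.copy()
        g[:, 1] = _moving_average_shrinking(f[:, 1], half)
        g[:, 2] = _moving_average_shrinking(f[:, 2], half)
        frags.append(g)
    return replace(track, fragments=frags)


def wall_cutoff(track: Track2D, factor: float = 1.1) -> Track2D:
    """Drop points farther than ``factor * trap_radius`` from the centre.

    Mimics the experimental rejection of wall-shadow mis-tracks; fragments
    are split wherever points are removed.
    """
    if track.trap_radius is None:
        raise ValueError("wall_cutoff needs a trap radius")
    rmax = factor * track.trap_radius
    cx, cy = track.trap_center
    frags = []
    for f in track.fragments:
        keep = np.hypot(f[:, 1] - cx, f[:, 2] - cy) <= rmax
        if keep.all():
            frags.append(f)
            continue
        idx = np.flatnonzero(keep)
        if len(idx) == 0:
            continue
        # split at gaps in the kept index sequence
        breaks = np.flatnonzero(np.diff(idx) > 1)
        for part in np.split(idx, breaks + 1):
            if len(part):
                frags.append(f[part])
    return replace(track, fragments=frags)


def _fragment_velocity(f: np.ndarray, fps: float) -> np.ndarray:
    """Fourth-order finite-difference velocity (n, 2) of one fragment.

    Interior: five-point central stencil (-p2 + 8 p1 - 8 p-1 + p-2)/(12 dt);
    the two points at each end use one-sided lower-order stencils.
    """
    n = len(f)
    dt = 1.0 / fps
    p = f[:, 1:3]
    v = np.empty((n, 2))
    if n < 2:
        v[:] = 0.0
        return v
    # interior, fourth order
    if n >= 5:
        v[2:-2] = (-p[4:] + 8 * p[3:-1] - 8 * p[1:-3] + p[:-4]) / (12 * dt)
    # ends: second-order one-sided / central where possible
    v[0] = (p[1] - p[0]) / dt if n < 3 else (-3 * p[0] + 4 * p[1] - p[2]) / (2 * dt)
    v[-1] = (p[-1] - p[-2]) / dt if n < 3 else (3 * p[-1] - 4 * p[-2] + p[-3]) / (2 * dt)
    if n >= 3:
        v[1] = (p[2] - p[0]) / (2 * dt)
        v[-2] = (p[-1] - p[-3]) / (2 * dt)
    if n == 4:
        v[1] = (p[2] - p[0]) / (2 * dt)
        v[2] = (p[3] - p[1]) / (2 * dt)
    return v


def instantaneous_speed(track: Track2D) -> list:
    """Per-frame speed (µm/s) of each fragment, fourth order in the interior."""
    return [np.linalg.norm(_fragment_velocity(f, track.fps), axis=1) for f in track.fragments]


# ---------------------------------------------------------------------------
# occupancy statistics


def radial_pdf(
    tracks,
    Rtrap: float,
    dr: float = 0.1,
    center: tuple[float, float] = (0.0, 0.0),
    r_max: float | None = None,
) -> RadialPDF:
    """Radial occupancy PDF, one histogram per track, averaged over tracks.

    Each track plays the role of one trap recording: its counts n(r) are
    normalised to a density n/(N_pts * 2 pi r dr) that integrates to 1, and
    the returned density is the unweighted mean over tracks with the
    across-track standard deviation. Bins extend to ``r_max`` (default
    1.1 * Rtrap so cutoff-filtered experimental tracks fit the same grid).
    """
    if isinstance(tracks, Track2D):
        tracks = [tracks]
    if not tracks:
        raise ValueError("need at least one track")
    if r_max is None:
        r_max = 1.1 * Rtrap
    edges = np.arange(0.0, r_max + dr / 2, dr)
    centers = 0.5 * (edges[:-1] + edges[1:])
    dens = []
    counts = np.zeros(len(centers))
    for tr in tracks:
        cx, cy = center
        p = tr.points()
        if len(p) == 0:
            raise ValueError("empty track")
        r = np.hypot(p[:, 1] - cx, p[:, 2] - cy)
        h, _ = np.histogram(r, bins=edges)
        counts += h
        dens.append(h / (len(r) * 2 * np.pi * centers * dr))
    dens = np.asarray(dens)
    return RadialPDF(
        r=centers,
        dr=dr,
        density=dens.mean(axis=0),
        std=dens.std(axis=0, ddof=0),
        n_traps=len(tracks),
        counts=counts,
    )


def fit_peak(pdf: RadialPDF, Rtrap: float, rel_threshold: float = 0.3) -> PeakFit:
    """Gaussian fit a*exp(-(r-b)^2/c^2) to the near-wall occupancy peak.

    The fit is restricted to the contiguous run of bins around the maximum
    with density >= rel_threshold * max, which excludes the long interior
    tail. Raises if the density has no strict interior maximum.
    """
    d = pdf.density
    if len(d) < 3:
        raise ValueError("too few bins to fit a peak")
    imax = int(np.argmax(d))
    if imax == 0 or imax == len(d) - 1 or d[imax] <= 0:
        raise ValueError("no strict interior maximum in the radial density")
    mask = d >= rel_threshold * d[imax]
    lo = imax
    while lo > 0 and mask[lo - 1]:
        lo -= 1
    hi = imax
    while hi < len(d) - 1 and mask[hi + 1]:
        hi += 1
    if hi - lo + 1 < 3:
        raise ValueError("peak region too narrow to fit")
    r_w, d_w = pdf.r[lo : hi + 1], d[lo : hi + 1]

    def gauss(r, a, b, c):
        return a * np.exp(-((r - b) ** 2) / c**2)

    try:
        popt, _ = curve_fit(
            gauss, r_w, d_w, p0=[d[imax], pdf.r[imax], max(2 * pdf.dr, 1.0)], maxfev=10000
        )
    except RuntimeError as exc:
        raise ValueError(f"peak fit did not converge: {exc}") from None
    a_g, b, c = popt
    c = abs(c)
    if not (0 < b < Rtrap * 1.1):
        raise ValueError(f"fitted peak centre {b:.2f} outside the trap")
    return PeakFit(
        amplitude=a_g,
        center=b,
        scale=c,
        width=c / math.sqrt(2),
        distance_from_wall=Rtrap - b,
    )


def heatmap(tracks, bin_size: float = 1.0, extent: float | None = None):
    """2D occupancy density on square bins.

    Counts per bin divided by (bin area * total points), so that
    sum(matrix) * bin_size^2 == 1. Returns (matrix, x_edges, y_edges).
    """
    if isinstance(tracks, Track2D):
        tracks = [tracks]
    pts = np.concatenate([tr.points() for tr in tracks], axis=0)
    if len(pts) == 0:
        raise ValueError("no points")
    if extent is None:
        radius = tracks[0].trap_radius
        if radius is not None:
            extent = 1.1 * radius
        else:
            extent = max(np.abs(pts[:, 1]).max(), np.abs(pts[:, 2]).max()) + bin_size
    nbin = max(1, int(math.ceil(2 * extent / bin_size)))
    edges = -extent + bin_size * np.arange(nbin + 1)
    h, xe, ye = np.histogram2d(pts[:, 1], pts[:, 2], bins=[edges, edges])
    matrix = h / (bin_size**2 * len(pts))
    return matrix, xe, ye


# ---------------------------------------------------------------------------
# event detection


def _heading_angles(v: np.ndarray) -> np.ndarray:
    return np.unwrap(np.arctan2(v[:, 1], v[:, 0]))


def detect_reversals(
    track: Track2D,
    angle_thresh: float = 150.0,
    lag: int = 6,
    bin_edges=None,
):
    """Detect abrupt swimming reversals and their rate vs wall distance.

    A reversal is flagged where the angle between the displacement direction
    at frame i and at frame i+lag exceeds ``angle_thresh`` degrees;
    consecutive qualifying frames are merged into one event located at the
    angle maximum. Rates are events per tracked time in wall-distance bins;
    the default binning uses 2 µm bins near the wall and pools the interior
    (distances in [R/2, R]). Returns ``(events, (edges, rates))``; the rate
    part is ``None`` for unconfined tracks.
    """
    cos_thresh = math.cos(math.radians(angle_thresh))
    events = []
    for fi, f in enumerate(track.fragments):
        n = len(f)
        if n <= lag + 1:
            continue
        d = np.diff(f[:, 1:3], axis=0)  # displacement directions
        nd = np.linalg.norm(d, axis=1)
        nd[nd == 0] = np.inf
        u = d / nd[:, None]
        m = len(u) - lag
        cosang = np.einsum("ij,ij->i", u[:m], u[lag:])
        qual = cosang < cos_thresh
        idx = np.flatnonzero(qual)
        if len(idx) == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        for grp in np.split(idx, breaks + 1):
            i_best = grp[np.argmin(cosang[grp])]
            frame = i_best + lag // 2  # centre of the comparison window
            pos = (f[frame, 1], f[frame, 2])
            if track.trap_radius is not None:
                cx, cy = track.trap_center
                dist = track.trap_radius - math.hypot(pos[0] - cx, pos[1] - cy)
            else:
                dist = None
            events.append(
                ReversalEvent(fragment=fi, frame=frame, position=pos, distance_from_wall=dist)
            )

    if track.trap_radius is None:
        return events, None
    R = track.trap_radius
    if bin_edges is None:
        near = np.arange(0.0, R / 2, 2.0)
        bin_edges = np.concatenate([near, [R / 2, R]])
    bin_edges = np.asarray(bin_edges, dtype=float)
    dists = R - track.radii()
    np.clip(dists, bin_edges[0], bin_edges[-1], out=dists)
    time_per_bin = np.histogram(dists, bins=bin_edges)[0] / track.fps
    ev_d = np.array([e.distance_from_wall for e in events]) if events else np.empty(0)
    ev_per_bin = np.histogram(np.clip(ev_d, bin_edges[0], bin_edges[-1]), bins=bin_edges)[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where(time_per_bin > 0, ev_per_bin / time_per_bin, np.nan)
    return events, (bin_edges, rates)


def fit_circle(points: np.ndarray):
    """Algebraic least-squares (Kåsa) circle fit.

    Solves the linear system for x^2 + y^2 + D x + E y + F = 0. Raises for
    fewer than three points or (near-)collinear input.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need >= 3 points of shape (n, 2)")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([x, y, np.ones_like(x)])
    b = -(x**2 + y**2)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise ValueError("collinear points: no unique circle")
    D, E, F = sol
    cx, cy = -D / 2, -E / 2
    r2 = cx**2 + cy**2 - F
    if r2 <= 0 or not np.isfinite(r2):
        raise ValueError("degenerate circle fit")
    return (cx, cy), math.sqrt(r2)


def detect_uturns(
    track: Track2D,
    B_direction=None,
    Rtrap: float | None = None,
    min_rotation: float = 150.0,
    max_rotation: float = 270.0,
    tolerance: float = 20.0,
    wall_margin: float | None = None,
    min_frames: int = 8,
    reversal_lag: int = 6,
) -> list:
    """Detect U-turns and measure their radii by circle fits.

    A U-turn is a segment over which the heading (from the fourth-order
    instantaneous velocity of the smoothed track) rotates monotonically
    (counter-rotation tolerance ``tolerance`` degrees) by at least
    ``min_rotation`` cumulative degrees but no more than ``max_rotation``
    (continued turning is wall circling, not a U-turn). Candidate segments
    overlapping a detected reversal are discarded, as are segments whose
    fitted radius hugs the trap radius (within ``wall_margin`` of ``Rtrap``,
    i.e. wall circling) or — when the field direction is given — that do not
    leave the swimmer heading down-field.
    """
    Rtrap = Rtrap if Rtrap is not None else track.trap_radius
    if wall_margin is None:
        wall_margin = 7.0  # typical wall-interaction range, µm
    if B_direction is not None:
        Bd = np.asarray(B_direction, dtype=float)[:2]
        nB = np.linalg.norm(Bd)
        Bd = Bd / nB if nB > 0 else None
    else:
        Bd = None
    reversal_events, _ = detect_reversals(track, lag=reversal_lag)
    rev_frames = {}
    for e in reversal_events:
        rev_frames.setdefault(e.fragment, []).append(e.frame)

    min_rot = math.radians(min_rotation)
    max_rot = math.radians(max_rotation)
    tol = math.radians(tolerance)
    events = []
    for fi, f in enumerate(track.fragments):
        if len(f) < max(min_frames, 5):
            continue
        vel = _fragment_velocity(f, track.fps)
        speed = np.linalg.norm(vel, axis=1)
        theta = _heading_angles(vel)
        # scan for monotone rotation runs
        start = 0
        ext = 0.0  # extreme cumulative rotation since start
        ext_i = 0
        i = 1
        cum = 0.0
        direction = 0.0

        def flush(start, stop, ext):
            if abs(ext) < min_rot or abs(ext) > max_rot:
                return
            # trim straight tangent lead-in/out: keep the sub-span carrying
            # the central 96% of the cumulative rotation. The realignment
            # path is only approximately circular (curvature peaks mid-turn),
            # so the fit must cover the whole turn including its shallow
            # entry and exit; the trim only removes frames that add no
            # rotation at all.
            rel = (theta[start : stop + 1] - theta[start]) / (theta[stop] - theta[start])
            inner = np.flatnonzero((rel >= 0.02) & (rel <= 0.98))
            if len(inner):
                start, stop = start + inner[0], start + inner[-1]
            if stop - start + 1 < min_frames:
                return
            for rf in rev_frames.get(fi, []):
                if start <= rf <= stop:
                    return
            pts = f[start : stop + 1, 1:3]
            try:
                (cx, cy), radius = fit_circle(pts)
            except ValueError:
                return
            if Rtrap is not None and radius > Rtrap - wall_margin:
                # a circle-fit radius close to the trap radius is wall
                # circling, not a U-turn; wide turns whose fitted circle
                # extends beyond the wall are kept (only the arc must lie
                # inside, and the track points already do)
                return
            if Bd is not None:
                head_end = vel[stop]
                nh = np.linalg.norm(head_end)
                if nh > 0 and float(head_end[:2] @ Bd) / nh < 0.0:
                    return
            events.append(
                UTurnEvent(
                    fragment=fi,
                    start=start,
                    stop=stop,
                    center=(cx, cy),
                    radius=radius,
                    mean_speed=float(speed[start : stop + 1].mean()),
                )
            )

        while i < len(theta):
            cum += theta[i] - theta[i - 1]
            if direction == 0.0 and cum != 0.0:
                direction = math.copysign(1.0, cum)
            if direction * cum > direction * ext:
                ext = cum
                ext_i = i
            if direction * (ext - cum) > tol:
                flush(start, ext_i, ext)
                start = ext_i
                cum = cum - ext
                ext = 0.0
                ext_i = start
                direction = math.copysign(1.0, cum) if cum else 0.0
            i += 1
        flush(start, ext_i, ext)
    return events
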