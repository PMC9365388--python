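"""Trajectory analytics: smoothing, kinematics, PDFs, events, circle fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import trapswim as ts
from trapswim.tracks import (
    Track2D,
    _fragment_velocity,
    detect_reversals,
    detect_uturns,
    fit_circle,
    fit_peak,
    heatmap,
    instantaneous_speed,
    radial_pdf,
    smooth_track,
    wall_cutoff,
)


def _frag(x, y, fps=50.0):
    x = np.asarray(x, dtype=float)
    t = np.arange(len(x)) / fps
    return np.column_stack([t, x, np.asarray(y, dtype=float)])


# ---------------------------------------------------------------------------
# Track2D container


def test_track_validation():
    Track2D(fragments=[_frag([0, 1], [0, 0])])
    with pytest.raises(ValueError):
        Track2D(fragments=[np.zeros((2, 2))])
    with pytest.raises(ValueError):  # non-monotone time
        Track2D(fragments=[np.array([[0.1, 0, 0], [0.0, 1, 0]])])
    with pytest.raises(ValueError):  # overlapping fragments
        Track2D(fragments=[_frag([0, 1, 2], [0, 0, 0]), _frag([3, 4], [0, 0])])


def test_track_accessors():
    tr = Track2D(
        fragments=[_frag([3.0, 4.0], [4.0, 3.0])], fps=50.0, trap_radius=10.0
    )
    assert tr.n_points == 2
    assert tr.tracked_time == pytest.approx(0.04)
    assert np.allclose(tr.radii(), [5.0, 5.0])


# ---------------------------------------------------------------------------
# smoothing (hand-computed fixture)


def test_smooth_track_hand_fixture():
    # x = [0,0,3,0,0]: centre uses the full 5-point window -> 0.6,
    # neighbours use 3-point windows -> 1.0, endpoints pass through.
    tr = Track2D(fragments=[_frag([0, 0, 3, 0, 0], [1, 1, 1, 1, 1])])
    sm = smooth_track(tr, window=5)
    assert np.allclose(sm.fragments[0][:, 1], [0.0, 1.0, 0.6, 1.0, 0.0])
    assert np.allclose(sm.fragments[0][:, 2], 1.0)  # constants invariant
    assert np.array_equal(sm.fragments[0][:, 0], tr.fragments[0][:, 0])


def test_smooth_track_short_fragment_passthrough():
    tr = Track2D(fragments=[_frag([0, 5, 0], [0, 0, 0])])
    sm = smooth_track(tr, window=5)
    assert np.array_equal(sm.fragments[0], tr.fragments[0])


def test_smooth_track_rejects_even_window():
    tr = Track2D(fragments=[_frag([0, 1], [0, 0])])
    with pytest.raises(ValueError):
        smooth_track(tr, window=4)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(
    slope=st.floats(-10, 10, allow_nan=False),
    intercept=st.floats(-5, 5, allow_nan=False),
    n=st.integers(5, 40),
)
def test_smoothing_preserves_straight_lines(slope, intercept, n):
    i = np.arange(n)
    tr = Track2D(fragments=[_frag(slope * i + intercept, 0.5 * i)])
    sm = smooth_track(tr)
    assert np.allclose(sm.fragments[0], tr.fragments[0], atol=1e-9)


# ---------------------------------------------------------------------------
# wall cutoff


def test_wall_cutoff_splits_fragments():
    x = [0.0, 1.0, 20.0, 1.0, 0.0]  # middle point beyond 1.1 * R = 11
    tr = Track2D(fragments=[_frag(x, np.zeros(5))], trap_radius=10.0)
    cut = wall_cutoff(tr, 1.1)
    assert len(cut.fragments) == 2
    assert [len(f) for f in cut.fragments] == [2, 2]


def test_wall_cutoff_requires_radius():
    tr = Track2D(fragments=[_frag([0, 1], [0, 0])])
    with pytest.raises(ValueError):
        wall_cutoff(tr)


# ---------------------------------------------------------------------------
# velocities (hand-checkable polynomial fixtures)


def test_velocity_fourth_order_exact_on_quartic_interior():
    fps = 50.0
    t = np.arange(9) / fps
    x = t**4
    f = np.column_stack([t, x, np.zeros_like(t)])
    v = _fragment_velocity(f, fps)
    assert np.allclose(v[2:-2, 0], 4 * t[2:-2] ** 3, rtol=1e-9, atol=1e-9)


def test_velocity_second_order_exact_on_quadratic_everywhere():
    fps = 50.0
    t = np.arange(7) / fps
    x = 3 * t**2 - 2 * t + 1
    f = np.column_stack([t, x, np.zeros_like(t)])
    v = _fragment_velocity(f, fps)
    assert np.allclose(v[:, 0], 6 * t - 2, rtol=1e-8, atol=1e-8)


def test_instantaneous_speed_constant_velocity():
    fps = 50.0
    i = np.arange(10)
    tr = Track2D(fragments=[_frag(0.6 * i, 0.8 * i, fps)], fps=fps)
    (sp,) = instantaneous_speed(tr)
    assert np.allclose(sp, 50.0)  # |(0.6, 0.8)| per frame * 50 fps


# ---------------------------------------------------------------------------
# radial PDF and peak fit


def test_radial_pdf_normalization_exact():
    rng = np.random.default_rng(1)
    pts = rng.uniform(-8, 8, size=(4000, 2))
    pts = pts[np.hypot(pts[:, 0], pts[:, 1]) < 8.0]
    t = np.arange(len(pts)) / 50.0
    tr = Track2D(fragments=[np.column_stack([t, pts])], trap_radius=8.0)
    pdf = radial_pdf([tr], Rtrap=8.0, dr=0.1)
    assert pdf.integral() == pytest.approx(1.0, abs=1e-12)


def test_radial_pdf_multi_track_mean_and_std():
    f1 = _frag([1.05], [0.0])
    f2 = _frag([3.05], [0.0])
    t1 = Track2D(fragments=[f1], trap_radius=8.0)
    t2 = Track2D(fragments=[f2], trap_radius=8.0)
    pdf = radial_pdf([t1, t2], Rtrap=8.0, dr=0.1)
    assert pdf.n_traps == 2
    assert pdf.integral() == pytest.approx(1.0, abs=1e-12)
    assert np.any(pdf.std > 0)


def test_fit_peak_recovers_gaussian():
    r = np.arange(0.05, 10.0, 0.1)
    b_true, c_true, a_true = 7.0, 0.8, 0.12
    dens = a_true * np.exp(-((r - b_true) ** 2) / c_true**2)
    pdf = ts.RadialPDF(r=r, dr=0.1, density=dens, std=np.zeros_like(r), n_traps=1)
    peak = fit_peak(pdf, Rtrap=9.0)
    assert peak.center == pytest.approx(b_true, abs=1e-6)
    assert peak.scale == pytest.approx(c_true, abs=1e-6)
    assert peak.width == pytest.approx(c_true / math.sqrt(2), abs=1e-6)
    assert peak.distance_from_wall == pytest.approx(2.0, abs=1e-6)


def test_fit_peak_rejects_monotone_density():
    r = np.arange(0.05, 5.0, 0.1)
    pdf = ts.RadialPDF(r=r, dr=0.1, density=r.copy(), std=np.zeros_like(r), n_traps=1)
    with pytest.raises(ValueError):
        fit_peak(pdf, Rtrap=5.0)


def test_heatmap_normalization():
    rng = np.random.default_rng(2)
    pts = rng.uniform(-5, 5, size=(500, 2))
    t = np.arange(len(pts)) / 50.0
    tr = Track2D(fragments=[np.column_stack([t, pts])], trap_radius=5.0)
    m, xe, ye = heatmap([tr], bin_size=1.0)
    assert m.sum() * 1.0**2 == pytest.approx(1.0)
    assert xe[0] == pytest.approx(-5.5) and xe[-1] >= 5.5


# ---------------------------------------------------------------------------
# reversal detection


def test_detect_reversals_planted_flip():
    # straight out, abrupt reversal, straight back
    x = np.concatenate([np.arange(30), np.arange(29, -1, -1.0)]) * 0.5
    tr = Track2D(fragments=[_frag(x, np.zeros_like(x))], trap_radius=20.0)
    events, (edges, rates) = detect_reversals(tr)
    assert len(events) == 1
    ev = events[0]
    assert abs(ev.frame - 30) <= 3
    assert ev.distance_from_wall == pytest.approx(20.0 - ev.position[0])
    assert np.nansum(rates) > 0


def test_detect_reversals_none_on_smooth_arc():
    # gentle quarter circle: heading change per 6-frame lag stays tiny
    th = np.linspace(0, np.pi / 2, 200)
    tr = Track2D(fragments=[_frag(10 * np.cos(th), 10 * np.sin(th))], trap_radius=12.0)
    events, _ = detect_reversals(tr)
    assert events == []


def test_detect_reversals_unconfined_has_no_rate_part():
    x = np.concatenate([np.arange(20), np.arange(19, -1, -1.0)])
    tr = Track2D(fragments=[_frag(x, np.zeros_like(x))])
    events, rate_part = detect_reversals(tr)
    assert len(events) == 1 and rate_part is None


# ---------------------------------------------------------------------------
# circle fit and U-turns


def test_fit_circle_exact_on_noiseless_circle():
    th = np.linspace(0, 1.5 * np.pi, 40)
    pts = np.column_stack([3.0 + 7.5 * np.cos(th), -2.0 + 7.5 * np.sin(th)])
    (cx, cy), r = fit_circle(pts)
    assert cx == pytest.approx(3.0, abs=1e-9)
    assert cy == pytest.approx(-2.0, abs=1e-9)
    assert r == pytest.approx(7.5, abs=1e-9)


def test_fit_circle_rejects_collinear_and_tiny_input():
    with pytest.raises(ValueError):
        fit_circle(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]))
    with pytest.raises(ValueError):
        fit_circle(np.array([[0.0, 0.0], [1.0, 1.0]]))


@settings(deadline=None, derandomize=True, max_examples=25)
@given(
    cx=st.floats(-20, 20),
    cy=st.floats(-20, 20),
    r=st.floats(0.5, 30),
    phase=st.floats(0, 2 * math.pi),
)
def test_fit_circle_property_exact(cx, cy, r, phase):
    th = phase + np.linspace(0, 4.0, 25)
    pts = np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)])
    (fx, fy), fr = fit_circle(pts)
    assert fr == pytest.approx(r, rel=1e-6)
    assert math.hypot(fx - cx, fy - cy) < 1e-6 * max(1.0, r)


def _arc_track(radius, Rtrap=45.4, fps=50.0, speed=40.0):
    """Straight run in, a half-circle U-turn of given radius, straight run out."""
    step = speed / fps
    n_straight = 40
    x_in = np.arange(n_straight) * step - 35.0
    y_in = np.full(n_straight, -radius)
    # half-turn: heading rotates by 180 degrees
    n_arc = max(8, int(round(math.pi * radius / step)))
    th = -np.pi / 2 + np.pi * np.arange(1, n_arc + 1) / n_arc
    cx0 = x_in[-1]
    x_arc = cx0 + radius * np.cos(th)
    y_arc = radius * np.sin(th)
    x_out = x_arc[-1] - np.arange(1, n_straight + 1) * step
    y_out = np.full(n_straight, radius)
    x = np.concatenate([x_in, x_arc, x_out])
    y = np.concatenate([y_in, y_arc, y_out])
    return Track2D(
        fragments=[_frag(x, y, fps)], fps=fps, trap_radius=Rtrap, trap_center=(0.0, 0.0)
    )


def test_detect_uturns_planted_arc():
    tr = _arc_track(radius=10.0)
    events = detect_uturns(tr, Rtrap=45.4)
    assert len(events) == 1
    assert events[0].radius == pytest.approx(10.0, rel=0.1)
    assert events[0].mean_speed == pytest.approx(40.0, rel=0.15)


def test_detect_uturns_field_filter():
    tr = _arc_track(radius=10.0)
    # the planted turn ends heading along -x: accepted for B along -x only
    assert len(detect_uturns(tr, B_direction=(-1.0, 0.0), Rtrap=45.4)) == 1
    assert detect_uturns(tr, B_direction=(1.0, 0.0), Rtrap=45.4) == []


def test_detect_uturns_rejects_wall_circling():
    # a full orbit at the trap perimeter: rotation beyond 270 degrees
    Rtrap = 45.4
    th = np.linspace(0, 2 * np.pi, 700)
    r_orbit = Rtrap - 5.0
    tr = Track2D(
        fragments=[_frag(r_orbit * np.cos(th), r_orbit * np.sin(th))],
        trap_radius=Rtrap,
    )
    assert detect_uturns(tr, Rtrap=Rtrap) == []


def test_detect_uturns_ignores_straight_tracks():
    tr = Track2D(
        fragments=[_frag(np.arange(50) * 0.8, np.zeros(50))], trap_radius=45.4
    )
    assert detect_uturns(tr, Rtrap=45.4) == []
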