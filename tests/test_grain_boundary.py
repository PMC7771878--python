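import math

import numpy as np
import pytest

from conemosaic import grain_boundary as gb
from conemosaic import synthetic as syn
from conemosaic.defects import triangulate
from conemosaic.synthetic import RowTraces


def radial_traces(n_rows=24, r0=300.0, r1=500.0, tilt_deg=0.0,
                  span=math.radians(40.0)):
    """Straight traces fanning out radially, optionally tilted."""
    polys = []
    for i in range(n_rows):
        th = (i + 0.5) * span / n_rows
        u = np.array([math.cos(th), math.sin(th)])
        if tilt_deg:
            a = math.radians(tilt_deg)
            R = np.array([[math.cos(a), -math.sin(a)],
                          [math.sin(a), math.cos(a)]])
            u = R @ u
        start = r0 * np.array([math.cos(th), math.sin(th)])
        pts = start + np.outer(np.linspace(0, r1 - r0, 30), u)
        polys.append(pts)
    return RowTraces(polys)


# -- box orientation --------------------------------------------------------

def test_radial_rows_give_radial_orientation():
    rows = gb.TracedRowField(radial_traces())
    box = gb.PolarBox(350, 450, 0.1, 0.5)
    u = gb.box_row_orientation(rows, box)
    th_mid = math.atan2(u[1], u[0])
    assert 0.1 < th_mid < 0.5


def test_weighted_mean_of_two_rows():
    # two straight rows at +-10 degrees with vertex weights 3:1
    up = np.array([[math.cos(math.radians(a)), math.sin(math.radians(a))]
                   for a in (10.0, -10.0)])
    r = np.linspace(100, 200, 40)
    poly_heavy = np.outer(r, up[1])                  # 40 vertices at -10 deg
    poly_light = np.outer(r[::3], up[0])             # ~13 vertices at +10 deg
    rows = gb.TracedRowField(RowTraces([poly_heavy, poly_light]))
    box = gb.PolarBox(0, 300, -1.0, 1.0)
    u = gb.box_row_orientation(rows, box)
    ang = math.degrees(math.atan2(u[1], u[0]))
    # 3:1 weighting pulls the mean toward -10: arctan(0.5 tan 10) ~ 5.04
    assert ang == pytest.approx(-5.04, abs=0.4)


def test_empty_box_is_undefined():
    rows = gb.TracedRowField(radial_traces())
    assert gb.box_row_orientation(rows, gb.PolarBox(0, 10, 0, 0.1)) is None


# -- five-box rotation measure ---------------------------------------------

def _bicrystal(gamma_deg, r0=10000.0, n_rows=40, spacing=6.0):
    """Two grains of straight parallel rows tilted +-gamma; the interface
    runs along the radial direction through (r0, 0), far enough from the
    polar origin that the curvilinear baseline of the five-box measure is
    negligible."""
    polys = []
    for i in range(n_rows):
        y = (i - n_rows / 2 + 0.5) * spacing
        g = math.radians(gamma_deg if y > 0 else -gamma_deg)
        u = np.array([math.cos(g), math.sin(g)])
        start = np.array([r0 - 150.0, y])
        polys.append(start + np.outer(np.linspace(0, 300, 40), u))
    return RowTraces(polys)


def test_uniform_orientation_field_gives_zero_rotation():
    rows = gb.TracedRowField(_bicrystal(0.0))
    d23, d45, rms = gb.dphi_rms(rows, (10000.0, 0.0), 60.0)
    assert rms == pytest.approx(0.0, abs=1e-9)


@pytest.mark.parametrize("gamma", [2.0, 4.0])
def test_bicrystal_misorientation_recovered(gamma):
    rows = gb.TracedRowField(_bicrystal(gamma))
    d23, d45, rms = gb.dphi_rms(rows, (10000.0, 0.0), 60.0)
    assert d45 == pytest.approx(2 * gamma, abs=1.0)


def test_read_formula_on_constructed_boundary(spec):
    # a boundary of linear defect density 1/L rotates the domains by ~|b|/L
    L = 40.0
    theta = spec.oblique / L                 # Read's formula, radians
    rows = gb.TracedRowField(_bicrystal(math.degrees(theta) / 2))
    group = np.column_stack([np.arange(9900.0, 10100.0, L), np.zeros(5)])
    rot = gb.margin_domain_rotation(rows, group, (9900.0, 10100.0))
    assert rot == pytest.approx(math.degrees(theta), rel=0.10)


def test_margin_rotation_zero_without_defects():
    rows = gb.TracedRowField(_bicrystal(0.0))
    group = np.array([[10000.0, 0.0]])
    rot = gb.margin_domain_rotation(rows, group, (9900.0, 10100.0))
    assert rot == pytest.approx(0.0, abs=1e-9)


def test_margin_rotation_invariant_under_rigid_rotation():
    traces = _bicrystal(8.0)
    rot0 = gb.margin_domain_rotation(gb.TracedRowField(traces),
                                     np.array([[10000.0, 0.0]]),
                                     (9900.0, 10100.0))
    a = 0.8
    R = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
    traces2 = RowTraces([p @ R.T for p in traces.polylines])
    rot1 = gb.margin_domain_rotation(gb.TracedRowField(traces2),
                                     np.array([[10000.0, a]]),
                                     (9900.0, 10100.0))
    assert rot1 == pytest.approx(rot0, abs=0.5)


# -- primary detector on generator samples ---------------------------------

def test_clustered_defects_called_in_boundaries(clustered_sample, alpha):
    s = clustered_sample
    rows = gb.TracedRowField(s.row_traces, period=alpha)
    dp = np.array([[d.s_um, d.angle_rad] for d in s.defects_truth])
    _calls, frac = gb.call_gb_primary(rows, dp, delta_r=40.0, cutoff_deg=12.0)
    assert frac >= 0.9


def test_uniform_defects_called_less_often(clustered_sample, uniform_sample, alpha):
    rows_c = gb.TracedRowField(clustered_sample.row_traces, period=alpha)
    dp_c = np.array([[d.s_um, d.angle_rad]
                     for d in clustered_sample.defects_truth])
    _c, frac_c = gb.call_gb_primary(rows_c, dp_c, 40.0, 12.0)
    rows_u = gb.TracedRowField(uniform_sample.row_traces, period=alpha)
    dp_u = np.array([[d.s_um, d.angle_rad]
                     for d in uniform_sample.defects_truth])
    _u, frac_u = gb.call_gb_primary(rows_u, dp_u, 40.0, 12.0)
    assert frac_u < frac_c - 0.2


def test_zero_cutoff_flags_everything(clustered_sample, alpha):
    rows = gb.TracedRowField(clustered_sample.row_traces, period=alpha)
    dp = np.array([[d.s_um, d.angle_rad]
                   for d in clustered_sample.defects_truth])
    _calls, frac = gb.call_gb_primary(rows, dp, 40.0, 0.0)
    assert frac == 1.0


def test_fraction_monotone_in_cutoff(clustered_sample, alpha):
    rows = gb.TracedRowField(clustered_sample.row_traces, period=alpha)
    dp = np.array([[d.s_um, d.angle_rad]
                   for d in clustered_sample.defects_truth])
    fracs = [gb.call_gb_primary(rows, dp, 40.0, c)[1]
             for c in (0.0, 8.0, 12.0, 16.0, 24.0)]
    assert all(a >= b for a, b in zip(fracs, fracs[1:]))


def test_weak_delta_r_dependence(clustered_sample, alpha):
    rows = gb.TracedRowField(clustered_sample.row_traces, period=alpha)
    dp = np.array([[d.s_um, d.angle_rad]
                   for d in clustered_sample.defects_truth])
    _c1, f1 = gb.call_gb_primary(rows, dp, 30.0, 12.0)
    _c2, f2 = gb.call_gb_primary(rows, dp, 60.0, 12.0)
    assert abs(f1 - f2) < 0.05


# -- row bonds --------------------------------------------------------------

def test_row_bond_degrees_on_planted_lattice(clean_sample, spec, alpha):
    s = clean_sample
    tri = triangulate(s.xy, wrap=("angle", alpha), spec=spec, center=(0.0, 0.0))
    _field, degree, classes = gb.extract_row_bonds(tri, center=(0.0, 0.0))
    # regular interior cones carry two row bonds; each planted insertion
    # produces exactly one three-bond cone
    assert len(classes["Y"]) == 2
    assert len(classes["regular"]) > 0.9 * tri.interior().sum()
    truth = np.array([d.xy for d in s.defects_truth])
    for i in classes["Y"]:
        d = np.min(np.hypot(truth[:, 0] - s.xy[i, 0], truth[:, 1] - s.xy[i, 1]))
        assert d < 2.0 * spec.a_col


def test_reverse_y_has_one_row_bond(spec, alpha):
    sched = syn.CustomSchedule([(14, 0.35 * alpha, "reverseY"),
                                (14, 0.75 * alpha, "Y")])
    s = syn.build_frustum_mosaic(spec, 120, 28, insertion_mode=sched, seed=0)
    tri = triangulate(s.xy, wrap=("angle", alpha), spec=spec, center=(0.0, 0.0))
    _f, _deg, classes = gb.extract_row_bonds(tri, center=(0.0, 0.0))
    assert len(classes["reverseY"]) >= 1


# -- chain detector ---------------------------------------------------------

def test_collinear_chain_scores_one():
    pts = np.array([[0, 0], [0, 1], [0, 2], [0, 3], [0, 4]], float)
    scores = gb.chain_scores(pts)
    assert scores[0][1] == pytest.approx(1.0)


def test_l_shaped_chain_scores_sqrt2_over_2():
    pts = np.array([[0, 0], [0, 1], [0, 2], [1, 2], [2, 2]], float)
    scores = gb.chain_scores(pts)
    assert scores[0][1] == pytest.approx(math.sqrt(2) / 2, abs=1e-6)
    calls, _frac = gb.call_gb_chain(scores)
    assert not calls[0].in_gb


def test_chain_membership_propagates():
    # five collinear defects plus one offset: the offset defect's own chain
    # bends, but it belongs to no passing chain; the collinear ones flag
    # each other including members whose own chain fails
    line = np.column_stack([np.zeros(5), np.arange(5.0)])
    outlier = np.array([[4.0, 2.0]])
    pts = np.vstack([line, outlier])
    scores = gb.chain_scores(pts)
    calls, _ = gb.call_gb_chain(scores)
    flagged = {c.defect_index for c in calls if c.in_gb}
    assert set(range(5)) <= flagged


def test_detectors_agree_on_strongly_clustered(spec, alpha):
    s = syn.build_frustum_mosaic(spec, 200, 95,
                                 insertion_mode=syn.GrainBoundaryMode(4, 0.25),
                                 seed=1)
    rows = gb.TracedRowField(s.row_traces, period=alpha)
    dp = np.array([[d.s_um, d.angle_rad] for d in s.defects_truth])
    calls_p, _ = gb.call_gb_primary(rows, dp, 40.0, 12.0)
    xy = np.array([d.xy for d in s.defects_truth])
    calls_c, _ = gb.call_gb_chain(gb.chain_scores(xy, wrap=("angle", alpha)))
    agree = [p.in_gb == c.in_gb for p, c in zip(calls_p, calls_c)
             if p.defined]
    assert np.mean(agree) >= 0.8
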