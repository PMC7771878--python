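import math

import numpy as np
import pytest
from scipy.spatial import cKDTree

from conemosaic import synthetic as syn
from conemosaic.defects import (burgers_circuit, classify_core_polygons,
                                coordination_census, find_dislocations,
                                find_vacancies, fit_plane, match_timepoints,
                                project_to_plane, triangulate)

from conftest import match_cores_to_truth


# -- triangulation ----------------------------------------------------------

def test_unit_square_triangulation():
    pts = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], float)
    tri = triangulate(pts)
    assert len(tri.edges) == 5


def test_duplicate_points_rejected():
    pts = np.array([[0, 0], [1, 0], [1, 0], [0, 1]], float)
    with pytest.raises(ValueError):
        triangulate(pts)


def test_collinear_points_rejected():
    pts = np.column_stack([np.arange(5.0), np.arange(5.0)])
    with pytest.raises(ValueError):
        triangulate(pts)


def test_perfect_lattice_all_interior_six(cylinder_sample, spec):
    s = cylinder_sample
    tri = triangulate(s.xy, wrap=("x", s.geometry.s_top))
    coord, non6 = coordination_census(tri)
    assert len(non6) == 0
    assert np.all(coord[tri.interior()] == 6)


def test_census_invariant_under_rigid_transform(clean_sample, spec, alpha):
    s = clean_sample
    tri = triangulate(s.xy, wrap=("angle", alpha), spec=spec, center=(0.0, 0.0))
    th = 0.7
    R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    t = np.array([123.0, -45.0])
    xy2 = s.xy @ R.T + t
    tri2 = triangulate(xy2, wrap=("angle", alpha), spec=spec,
                       center=tuple(t))
    assert np.array_equal(np.sort(tri.coordination),
                          np.sort(tri2.coordination))


# -- dislocation cores ------------------------------------------------------

def test_planted_insertions_appear_as_adjacent_57_pairs(clean_sample, spec, alpha):
    s = clean_sample
    tri = triangulate(s.xy, wrap=("angle", alpha), spec=spec, center=(0.0, 0.0))
    cores, report = find_dislocations(tri, spec, (0.0, 0.0))
    assert len(cores) == 2
    assert all(c.adjacent and c.kind == "Y" for c in cores)
    assert not report["unpaired_5"] and not report["unpaired_7"]
    truth = np.array([d.xy for d in s.defects_truth])
    pos = np.array([c.position for c in cores])
    assert match_cores_to_truth(pos, truth, spec.a_col) == 2


def test_row_deletion_classified_reverse_y(spec, alpha):
    sched = syn.CustomSchedule([(14, 0.35 * alpha, "reverseY"),
                                (14, 0.75 * alpha, "Y")])
    s = syn.build_frustum_mosaic(spec, 120, 28, insertion_mode=sched, seed=0)
    tri = triangulate(s.xy, wrap=("angle", alpha), spec=spec, center=(0.0, 0.0))
    cores, _ = find_dislocations(tri, spec, (0.0, 0.0))
    kinds = sorted(c.kind for c in cores)
    assert "reverseY" in kinds and "Y" in kinds
    # opposite Burgers orientations: radial components have opposite signs
    by_kind = {c.kind: c for c in cores}
    r_y = by_kind["Y"].position / np.linalg.norm(by_kind["Y"].position)
    r_r = by_kind["reverseY"].position / np.linalg.norm(by_kind["reverseY"].position)
    s_y = np.sign(by_kind["Y"].burgers @ r_y)
    s_r = np.sign(by_kind["reverseY"].burgers @ r_r)
    assert abs(np.linalg.norm(by_kind["Y"].burgers) - spec.oblique) < 0.1 * spec.oblique


# -- Burgers circuits -------------------------------------------------------

def test_burgers_circuit_around_y_is_oblique_vector(clean_sample, spec, alpha):
    s = clean_sample
    tri = triangulate(s.xy, wrap=("angle", alpha), spec=spec, center=(0.0, 0.0))
    cores, _ = find_dislocations(tri, spec, (0.0, 0.0))
    for c in cores:
        b = burgers_circuit(tri, c, circuit_radius=2, spec=spec,
                            center=(0.0, 0.0))
        assert np.linalg.norm(b) == pytest.approx(spec.oblique, abs=0.05)


def test_burgers_circuit_defect_free_closes(clean_sample, spec, alpha):
    s = clean_sample
    smid = s.geometry.s_top + 14 * spec.ring_spacing
    pos = np.array([smid * math.cos(0.5 * alpha), smid * math.sin(0.5 * alpha)])
    tri = triangulate(s.xy, wrap=("angle", alpha), spec=spec, center=(0.0, 0.0))
    b = burgers_circuit(tri, pos, circuit_radius=2, spec=spec, center=(0.0, 0.0))
    assert np.linalg.norm(b) == pytest.approx(0.0, abs=1e-9)


def test_burgers_circuit_double_row_is_column_vector(spec, alpha):
    # two insertions stacked at the same angle merge into a double-row
    # defect whose circuit deficit is the full column spacing
    sched = syn.CustomSchedule([(14, 0.5 * alpha, "Y"),
                                (14, 0.5 * alpha + 1e-3, "Y")])
    s = syn.build_frustum_mosaic(spec, 120, 28, insertion_mode=sched, seed=0)
    tri = triangulate(s.xy, wrap=("angle", alpha), spec=spec, center=(0.0, 0.0))
    smid = s.geometry.s_top + 17 * spec.ring_spacing
    pos = np.array([smid * math.cos(0.5 * alpha), smid * math.sin(0.5 * alpha)])
    b = burgers_circuit(tri, pos, circuit_radius=4, spec=spec, center=(0.0, 0.0))
    assert np.linalg.norm(b) == pytest.approx(spec.a_col, abs=0.05)


def test_burgers_additive_over_enclosed_cores(spec, alpha):
    # circuit enclosing two like-signed insertions reads the vector sum
    sched = syn.CustomSchedule([(14, 0.48 * alpha, "Y"),
                                (14, 0.52 * alpha, "Y")])
    s = syn.build_frustum_mosaic(spec, 160, 28, insertion_mode=sched, seed=0)
    tri = triangulate(s.xy, wrap=("angle", alpha), spec=spec, center=(0.0, 0.0))
    cores, _ = find_dislocations(tri, spec, (0.0, 0.0))
    singles = []
    for c in cores:
        singles.append(burgers_circuit(tri, c, 2, spec, (0.0, 0.0)))
    mid = np.mean([c.position for c in cores], axis=0)
    total = burgers_circuit(tri, mid, 5, spec, (0.0, 0.0))
    assert np.linalg.norm(total - sum(singles)) < 0.35 * spec.a_col


# -- registration -----------------------------------------------------------

def test_match_identical_sets_is_identity(glide_sample):
    s = glide_sample
    corr = match_timepoints(s.xy, s.xy, s.ids, s.ids)
    assert abs(corr.rotation_rad) < 1e-6
    assert np.allclose(corr.translation_um, 0.0, atol=1e-3)
    assert all(a == b for a, b in corr.id_map.items())
    assert not corr.unmatched_t0


def test_match_recovers_planted_transform_on_patch(glide_sample, alpha):
    s = glide_sample
    rot, trans = math.radians(5.0), (30.0, -12.0)
    pair = syn.make_timepoint_pair(s, 6, rigid_transform=(rot, trans),
                                   jitter_um=0.3, seed=2)
    t1 = pair.sample_t1
    sel0 = (s.phi > 0.25 * alpha) & (s.phi < 0.55 * alpha)
    sel1 = (t1.phi > 0.25 * alpha) & (t1.phi < 0.55 * alpha)
    corr = match_timepoints(s.xy[sel0], pair.xy_t1[sel1],
                            s.ids[sel0], pair.ids_t1[sel1])
    assert math.degrees(corr.rotation_rad) == pytest.approx(5.0, abs=0.15)
    assert corr.translation_um[0] == pytest.approx(30.0, abs=0.5)
    assert corr.translation_um[1] == pytest.approx(-12.0, abs=0.5)
    # every interior match correct, and forward/reverse agree by construction
    assert all(a == b for a, b in corr.id_map.items())
    assert len(corr.id_map) >= 0.9 * sel0.sum()


# -- glide ------------------------------------------------------------------

def test_single_bond_flip_per_row_of_glide(glide_sample):
    from conemosaic.defects import detect_glide

    for events, expected in [([], [0, 0]), ([(0, 1)], [1, 0])]:
        pair = syn.make_timepoint_pair(glide_sample, 6, events, seed=1)
        res = detect_glide(pair)
        assert [r["rows"] for r in res] == expected
    # defects whose local registry cannot realize a clean flip refuse the
    # surgery instead of producing an ambiguous pair
    with pytest.raises(ValueError):
        syn.make_timepoint_pair(glide_sample, 6, [(1, 1)], seed=1)


# -- plane fitting ----------------------------------------------------------

def test_plane_fit_and_projection():
    rng = np.random.default_rng(0)
    n = 400
    pts = np.column_stack([rng.uniform(0, 100, n), rng.uniform(0, 100, n),
                           np.zeros(n)])
    origin, normal, rmse = fit_plane(pts)
    assert rmse == pytest.approx(0.0, abs=1e-10)
    p2 = project_to_plane(pts, origin, normal)
    d3 = np.linalg.norm(pts[10, :2] - pts[20, :2])
    d2 = np.linalg.norm(p2[10] - p2[20])
    assert d2 == pytest.approx(d3, abs=1e-9)
    # vertical Gaussian noise comes back as the rmse
    noisy = pts + np.column_stack([np.zeros((n, 2)), rng.normal(0, 1.5, n)])
    assert fit_plane(noisy)[2] == pytest.approx(1.5, rel=0.1)


# -- honeycomb cores --------------------------------------------------------

def test_glide_and_shuffle_core_polygons(spec, alpha):
    # a lightly annealed sample leaves clean honeycomb registries at the core
    sched = syn.CustomSchedule([(14, 0.3 * alpha, "Y"), (14, 0.7 * alpha, "Y")])
    s = syn.build_frustum_mosaic(spec, 120, 28, insertion_mode=sched, seed=0,
                                 anneal_sweeps=8)
    cx, cy = s.defects_truth[0].xy
    dec_g = syn.decorate_full_mosaic(s, core_style="glide")
    label_g, census_g = classify_core_polygons(dec_g["R"],
                                               (cx, cy, 2.2 * spec.a_col))
    assert label_g == "glide"
    assert census_g.get(5) == 1 and census_g.get(7) == 1
    dec_s = syn.decorate_full_mosaic(s, core_style="shuffle")
    label_s, census_s = classify_core_polygons(dec_s["R"],
                                               (cx, cy, 2.2 * spec.a_col))
    assert label_s == "shuffle"
    assert census_s.get(8) == 1


# -- vacancies --------------------------------------------------------------

def test_vacancy_search_reports_missing_unit_cell(clean_sample, spec):
    s = clean_sample
    interior = (s.s > s.s.min() + 2 * spec.a_col) & \
        (s.s < s.s.max() - 2 * spec.a_col)
    # the intact mosaic has no unit-cell-sized hole near the probe site;
    # removing a cone and its first shell opens one there
    victim = np.nonzero(interior)[0][len(s.xy) // 3]
    vx, vy = s.xy[victim]

    def near_victim(holes):
        return [h for h in holes
                if np.hypot(h[0] - vx, h[1] - vy) < 1.5 * spec.a_col]

    base = near_victim(find_vacancies(s.xy, spec, factor=1.25))
    d = np.hypot(s.xy[:, 0] - vx, s.xy[:, 1] - vy)
    holes = near_victim(find_vacancies(s.xy[d > 1.1 * spec.oblique], spec,
                                       factor=1.25))
    assert len(base) == 0
    assert len(holes) >= 1
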