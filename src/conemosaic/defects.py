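"""Dislocation analysis of UV-cone point sets.

Coordination defects, Burgers vectors, timepoint matching and glide (bond
flip) detection.  The nearest-neighbor graph is a Delaunay triangulation;
for lattices with known anisotropy and polar frame the triangulation is
computed in isotropy-restoring coordinates (radial distances divided by
``a_row``, tangential arc multiplied by ``sqrt(3)/a_col``), in which the
six lattice neighbors are equidistant and the Delaunay topology is
maximally robust to strain.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from conemosaic.lattice import LatticeSpec

__all__ = [
    "Triangulation",
    "DislocationCore",
    "Correspondence",
    "triangulate",
    "coordination_census",
    "find_dislocations",
    "burgers_circuit",
    "match_timepoints",
    "detect_glide",
    "fit_plane",
    "project_to_plane",
    "classify_core_polygons",
    "find_vacancies",
]


# --------------------------------------------------------------------------
# triangulation
# --------------------------------------------------------------------------

@dataclass
class Triangulation:
    """Undirected nearest-neighbor graph of a 2D point set.

    ``boundary`` marks nodes within one lattice spacing of the convex hull
    (or of the annular domain edges when a polar frame is given); their
    coordination is unreliable and they are excluded from the defect
    census.
    """

    xy: np.ndarray                    # (n, 2) positions um
    edges: set[tuple[int, int]]       # i < j
    neighbors: dict[int, set[int]] = field(repr=False, default_factory=dict)
    boundary: np.ndarray | None = None
    spec: LatticeSpec | None = None
    center: tuple[float, float] | None = None

    @property
    def n_points(self) -> int:
        return len(self.xy)

    @property
    def coordination(self) -> np.ndarray:
        return np.array([len(self.neighbors.get(i, ())) for i in range(self.n_points)])

    def interior(self) -> np.ndarray:
        if self.boundary is None:
            return np.ones(self.n_points, dtype=bool)
        return ~self.boundary


def _edges_from_simplices(simplices: np.ndarray) -> set[tuple[int, int]]:
    e = set()
    for simp in simplices:
        for a in range(3):
            for b in range(a + 1, 3):
                i, j = int(simp[a]), int(simp[b])
                e.add((min(i, j), max(i, j)))
    return e


def _neighbor_map(edges: set[tuple[int, int]]) -> dict[int, set[int]]:
    nb: dict[int, set[int]] = defaultdict(set)
    for i, j in edges:
        nb[i].add(j)
        nb[j].add(i)
    return dict(nb)


def _check_degenerate(xy: np.ndarray) -> None:
    if len(xy) < 3:
        raise ValueError("need at least 3 points to triangulate")
    d = cKDTree(xy).query_pairs(1e-9)
    if d:
        raise ValueError(f"duplicate points: {sorted(d)[:5]}")
    if np.linalg.matrix_rank(xy - xy.mean(axis=0)) < 2:
        raise ValueError("points are collinear")


def triangulate(
    points: np.ndarray,
    wrap: tuple[str, float] | None = None,
    spec: LatticeSpec | None = None,
    center: tuple[float, float] | None = None,
    boundary_band: float | None = None,
    band_anchor: float | None = None,
) -> Triangulation:
    """Delaunay nearest-neighbor graph of a point set.

    Parameters
    ----------
    points
        (n, 2) positions in um.
    wrap
        Optional periodic identification: ``("angle", alpha)`` rotates
        ghost copies by ``+-alpha`` about ``center`` (flattened frustum);
        ``("x", L)`` or ``("y", L)`` translates ghost copies (periodic
        strip).
    spec, center
        When both are given the triangulation is computed band-wise in
        isotropy-restoring polar coordinates, which is far more robust for
        the anisotropic cone lattice than Delaunay on raw positions.
    boundary_band
        Width (um) of the edge band flagged as boundary.  Defaults to one
        column spacing when ``spec`` is known, otherwise to the median
        nearest-neighbor distance.  The ragged alternating-ring rim of
        frustum samples makes a band of twice the column spacing the safer
        choice there.
    """
    xy = np.asarray(points, dtype=float)
    _check_degenerate(xy)

    if spec is not None and center is not None:
        tri = _triangulate_polar(xy, spec, center, wrap, s0=band_anchor)
    else:
        tri = _triangulate_plain(xy, wrap, center)
    tri.spec = spec
    tri.center = center

    # boundary mask
    if boundary_band is None:
        if spec is not None:
            boundary_band = 2.0 * spec.a_col
        else:
            d, _ = cKDTree(xy).query(xy, k=2)
            boundary_band = 1.5 * float(np.median(d[:, 1]))
    tri.boundary = _boundary_mask(xy, wrap, center, boundary_band)
    return tri


def _triangulate_plain(xy, wrap, center) -> Triangulation:
    n = len(xy)
    if wrap is None:
        dt = Delaunay(xy)
        edges = _edges_from_simplices(dt.simplices)
    else:
        kind, period = wrap
        ghosts = [xy]
        for sgn in (-1.0, 1.0):
            if kind == "angle":
                cx, cy = center if center is not None else (0.0, 0.0)
                a = sgn * period
                R = np.array([[math.cos(a), -math.sin(a)],
                              [math.sin(a), math.cos(a)]])
                ghosts.append((xy - (cx, cy)) @ R.T + (cx, cy))
            elif kind == "x":
                ghosts.append(xy + (sgn * period, 0.0))
            elif kind == "y":
                ghosts.append(xy + (0.0, sgn * period))
            else:
                raise ValueError(f"unknown wrap kind {kind!r}")
        allp = np.vstack(ghosts)
        dt = Delaunay(allp)
        edges = set()
        for i, j in _edges_from_simplices(dt.simplices):
            if i < n or j < n:
                edges.add((min(i % n, j % n), max(i % n, j % n)))
        edges = {(i, j) for i, j in edges if i != j}
    t = Triangulation(xy=xy, edges=edges)
    t.neighbors = _neighbor_map(edges)
    return t


def _triangulate_polar(xy, spec: LatticeSpec, center, wrap,
                       band_rings: float = 16.0, overlap: float = 8.0,
                       s0: float | None = None) -> Triangulation:
    """Band-wise Delaunay in isotropy-restoring polar coordinates."""
    cx, cy = center
    rel = xy - (cx, cy)
    s = np.hypot(rel[:, 0], rel[:, 1])
    phi = np.arctan2(rel[:, 1], rel[:, 0])
    alpha = None
    if wrap is not None and wrap[0] == "angle":
        alpha = wrap[1]
        phi = np.mod(phi, alpha)
    n = len(xy)
    ring = spec.ring_spacing
    if s0 is None:
        s0 = s.min()
    kap = (s - s0) / ring
    edges: set[tuple[int, int]] = set()
    b0 = 0.0
    scale_t = math.sqrt(3.0) / spec.a_col
    while b0 < kap.max() + 1.0:
        m = (kap >= b0 - overlap) & (kap <= b0 + band_rings + overlap)
        idx = np.nonzero(m)[0]
        if len(idx) >= 5:
            s_c = s0 + (b0 + band_rings / 2.0) * ring
            shifts = (0.0,) if alpha is None else (-alpha, 0.0, alpha)
            xs, ys, ids, org = [], [], [], []
            for sh in shifts:
                xs.append((phi[idx] + sh) * s_c * scale_t)
                ys.append(s[idx] / spec.a_row)
                ids.append(idx)
                org.append(np.full(len(idx), sh == 0.0))
            X = np.column_stack([np.concatenate(xs), np.concatenate(ys)])
            ids_ = np.concatenate(ids)
            org_ = np.concatenate(org)
            if len(X) >= 3 and np.linalg.matrix_rank(X - X.mean(0)) == 2:
                dt = Delaunay(X)
                for a, b in _edges_from_simplices(dt.simplices):
                    ii, jj = int(ids_[a]), int(ids_[b])
                    if ii == jj or not (org_[a] or org_[b]):
                        continue
                    km = 0.5 * (kap[ii] + kap[jj])
                    if b0 <= km < b0 + band_rings:
                        edges.add((min(ii, jj), max(ii, jj)))
        b0 += band_rings
    t = Triangulation(xy=xy, edges=edges)
    t.neighbors = _neighbor_map(edges)
    return t


def _boundary_mask(xy, wrap, center, band: float) -> np.ndarray:
    n = len(xy)
    mask = np.zeros(n, dtype=bool)
    if wrap is not None and wrap[0] == "angle" and center is not None:
        rel = xy - np.asarray(center)
        s = np.hypot(rel[:, 0], rel[:, 1])
        mask |= (s < s.min() + band) | (s > s.max() - band)
    elif wrap is not None and wrap[0] in ("x", "y"):
        ax = 1 if wrap[0] == "x" else 0     # non-periodic axis
        v = xy[:, ax]
        mask |= (v < v.min() + band) | (v > v.max() - band)
    else:
        from scipy.spatial import ConvexHull
        hull = ConvexHull(xy)
        # distance to hull edges
        pts = xy
        for k in range(len(hull.vertices)):
            p = xy[hull.vertices[k]]
            q = xy[hull.vertices[(k + 1) % len(hull.vertices)]]
            pq = q - p
            t = np.clip(((pts - p) @ pq) / (pq @ pq), 0.0, 1.0)
            d = np.hypot(*(pts - p - t[:, None] * pq).T)
            mask |= d < band
    return mask


# --------------------------------------------------------------------------
# census and dislocations
# --------------------------------------------------------------------------

def coordination_census(tri: Triangulation) -> tuple[np.ndarray, np.ndarray]:
    """Per-node coordination and the indices of non-6 interior nodes."""
    coord = tri.coordination
    non6 = np.nonzero(tri.interior() & (coord != 6))[0]
    return coord, non6


@dataclass
class DislocationCore:
    """A five/seven-coordinated pair and its Burgers vector."""

    id5: int
    id7: int
    position: np.ndarray            # midpoint of the 5-7 bond, um
    burgers: np.ndarray             # 2D vector um
    kind: str                       # "Y" | "reverseY" | "double_row"
    adjacent: bool = True


def _local_radial(position: np.ndarray, center) -> np.ndarray:
    r = position - np.asarray(center, dtype=float)
    nr = np.linalg.norm(r)
    return r / nr if nr > 0 else np.array([1.0, 0.0])


def find_dislocations(
    tri: Triangulation,
    spec: LatticeSpec | None = None,
    center: tuple[float, float] | None = None,
) -> tuple[list[DislocationCore], dict]:
    """Pair 5- and 7-coordinated interior nodes into dislocation cores.

    Five-nodes are paired with their nearest seven-nodes (ties broken by
    distance, then by node id).  A pair joined by a triangulation bond is
    a single dislocation; its Burgers vector is the oblique lattice vector
    perpendicular to the 5-7 axis.  The sign convention follows the
    radial frame: an insertion seen from the retinal center (a Y-junction)
    has its five-node on the peripheral side of the seven-node, a reverse
    Y-junction the opposite.  Non-adjacent pairs at a column-vector
    distance are classified as double-row insertions.

    Returns ``(cores, report)`` where ``report`` lists unpaired nodes
    instead of silently dropping them.
    """
    spec = spec or tri.spec
    center = center if center is not None else (tri.center or (0.0, 0.0))
    coord = tri.coordination
    inter = tri.interior()
    fives = [i for i in np.nonzero(inter & (coord == 5))[0]]
    sevens = [i for i in np.nonzero(inter & (coord == 7))[0]]
    cores: list[DislocationCore] = []
    report = {"unpaired_5": [], "unpaired_7": []}
    if not fives or not sevens:
        report["unpaired_5"] = list(map(int, fives))
        report["unpaired_7"] = list(map(int, sevens))
        return cores, report

    a_col = spec.a_col if spec is not None else None
    xy = tri.xy
    d = np.hypot(*(xy[fives][:, None, :] - xy[sevens][None, :, :]).transpose(2, 0, 1))
    # greedy mutual pairing by ascending distance; id tie-break via stable order
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None, kind="stable"),
                                       d.shape))[0]
    dmax = 2.5 * a_col if a_col else np.inf
    used5: set[int] = set()
    used7: set[int] = set()
    for i5, i7 in order:
        if i5 in used5 or i7 in used7:
            continue
        if d[i5, i7] > dmax:
            break
        used5.add(int(i5))
        used7.add(int(i7))
        n5, n7 = fives[i5], sevens[i7]
        p5, p7 = xy[n5], xy[n7]
        mid = 0.5 * (p5 + p7)
        axis = p7 - p5
        adjacent = (min(n5, n7), max(n5, n7)) in tri.edges
        rhat = _local_radial(mid, center)
        that = np.array([-rhat[1], rhat[0]])
        # Burgers vector: perpendicular to the 5->7 axis, of oblique length,
        # oriented so that its tangential sense matches the extra row side.
        perp = np.array([-axis[1], axis[0]])
        nperp = np.linalg.norm(perp)
        perp = perp / nperp if nperp > 0 else that
        if spec is not None:
            if adjacent:
                b = perp * spec.oblique
            else:
                b = perp * spec.a_col
        else:
            b = perp * np.linalg.norm(axis)
        # sign of the dislocation: insertion (Y) vs deletion (reverse Y)
        # from the radial component of the 5->7 axis: for an inserted row
        # the seven sits on the central side of the five.
        radial_57 = float(np.dot(axis, rhat))
        kind = "double_row" if not adjacent else ("Y" if radial_57 <= 0 else "reverseY")
        cores.append(DislocationCore(int(n5), int(n7), mid, b, kind, adjacent))
    report["unpaired_5"] = [int(fives[i]) for i in range(len(fives)) if i not in used5]
    report["unpaired_7"] = [int(sevens[i]) for i in range(len(sevens)) if i not in used7]
    return cores, report


# --------------------------------------------------------------------------
# Burgers circuit
# --------------------------------------------------------------------------

def burgers_circuit(
    tri: Triangulation,
    core: DislocationCore | np.ndarray,
    circuit_radius: int = 2,
    spec: LatticeSpec | None = None,
    center: tuple[float, float] | None = None,
) -> np.ndarray:
    """Closure deficit of an M x N parallelogram circuit around a core.

    The circuit walks ``circuit_radius`` lattice steps along each of the
    two oblique lattice directions (down one side, across, back up and
    across again); in a perfect lattice it closes, around a dislocation it
    fails to close by the Burgers vector.  Raises if the walk leaves the
    triangulation interior or if the loop encloses a second core.
    """
    spec = spec or tri.spec
    if spec is None:
        raise ValueError("burgers_circuit needs a LatticeSpec")
    center = center if center is not None else (tri.center or (0.0, 0.0))
    pos = core.position if isinstance(core, DislocationCore) else np.asarray(core)

    rhat = _local_radial(pos, center)
    that = np.array([-rhat[1], rhat[0]])
    # oblique lattice step directions in the local frame
    u = rhat * (spec.a_row / 2.0) + that * (spec.a_col / 2.0)
    v = -rhat * (spec.a_row / 2.0) + that * (spec.a_col / 2.0)

    # start from a node about circuit_radius steps "below" the core
    start_target = pos - that * (circuit_radius + 0.5) * (spec.a_col / 2.0) \
        - rhat * 0.25 * spec.a_row
    start = int(np.argmin(np.hypot(*(tri.xy - start_target).T)))

    m = circuit_radius
    # closed parallelogram of 2m steps along each oblique direction
    path = [(u, 2 * m), (v, 2 * m), (-u, 2 * m), (-v, 2 * m)]
    node = start
    visited = [node]
    for direction, steps in path:
        for _ in range(steps):
            node = _step(tri, node, direction)
            visited.append(node)
    deficit = tri.xy[visited[-1]] - tri.xy[visited[0]]

    # the walk must stay clear of the domain rim, where missing neighbors
    # would derail the steps
    rel = tri.xy[visited] - np.asarray(center, dtype=float)
    s_vis = np.hypot(rel[:, 0], rel[:, 1])
    s_all = np.hypot(*(tri.xy - np.asarray(center, dtype=float)).T)
    guard = 0.6 * spec.a_col
    if s_vis.min() < s_all.min() + guard or s_vis.max() > s_all.max() - guard:
        raise ValueError("Burgers circuit crosses the domain boundary")

    # a Burgers vector is a lattice vector; the raw closure deficit also
    # carries the elastic strain integrated along the circuit, so snap it
    # to the nearest lattice vector of the local frame
    candidates = [mm * u + nn * v
                  for mm in range(-2, 3) for nn in range(-2, 3)]
    raw = -deficit
    snapped = min(candidates, key=lambda c: np.linalg.norm(raw - c))
    if np.linalg.norm(raw - snapped) > 0.45 * spec.a_col:
        raise ValueError(
            f"circuit deficit {raw} is not close to any lattice vector; "
            "the circuit may enclose more than one core")
    return snapped


def _step(tri: Triangulation, node: int, direction: np.ndarray) -> int:
    """Move to the neighbor best aligned with ``direction``."""
    best, best_cos = None, 0.7
    dn = direction / np.linalg.norm(direction)
    for nb in tri.neighbors.get(node, ()):  # pragma: no branch
        v = tri.xy[nb] - tri.xy[node]
        c = float(v @ dn / np.linalg.norm(v))
        if c > best_cos:
            best, best_cos = nb, c
    if best is None:
        raise ValueError(f"no neighbor of node {node} along circuit direction")
    return best


# --------------------------------------------------------------------------
# timepoint matching
# --------------------------------------------------------------------------

@dataclass
class Correspondence:
    """Injective id map between two timepoints with the rigid alignment."""

    id_map: dict[int, int]            # t0 id -> t1 id
    rotation_rad: float
    translation_um: tuple[float, float]
    unmatched_t0: list[int]
    unmatched_t1: list[int]
    rmse_um: float


def _refine_icp(p0, p1, tree1, spacing, theta0: float,
                n_iter: int = 20) -> tuple[float, np.ndarray]:
    """Iterative closest point refinement from a rotation seed.

    The initial translation is the modal nearest-neighbor displacement
    under the seed rotation (about the first set's centroid); afterwards
    alternating nearest-neighbor association and a Kabsch rigid update
    with a tightening distance gate.
    """
    c0 = p0.mean(axis=0)
    R0 = np.array([[math.cos(theta0), -math.sin(theta0)],
                   [math.sin(theta0), math.cos(theta0)]])
    q0 = (p0 - c0) @ R0.T + c0
    _d, j = tree1.query(q0, k=1)
    disp = p1[j] - q0
    h = spacing / 2.0
    keys = np.round(disp / h).astype(int)
    uniq, counts = np.unique(keys, axis=0, return_counts=True)
    sel = np.all(keys == uniq[int(np.argmax(counts))], axis=1)
    t = disp[sel].mean(axis=0) + c0 - R0 @ c0
    theta = theta0

    gates = np.concatenate([np.linspace(1.0, 0.5, max(n_iter - 5, 1)),
                            np.full(5, 0.5)])
    for gate in gates:
        R = np.array([[math.cos(theta), -math.sin(theta)],
                      [math.sin(theta), math.cos(theta)]])
        dist, j = tree1.query(p0 @ R.T + t, k=1)
        keep = dist < gate * spacing
        if keep.sum() < 3:
            continue
        A = p0[keep]
        B = p1[j[keep]]
        ca, cb = A.mean(0), B.mean(0)
        H = (A - ca).T @ (B - cb)
        U, _S, Vt = np.linalg.svd(H)
        D = np.diag([1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
        Rn = Vt.T @ D @ U.T
        theta, t = math.atan2(Rn[1, 0], Rn[0, 0]), cb - (Rn @ ca)
    return theta, t


def match_timepoints(
    points_t0: np.ndarray,
    points_t1: np.ndarray,
    ids_t0: np.ndarray | None = None,
    ids_t1: np.ndarray | None = None,
    n_iter: int = 30,
) -> Correspondence:
    """Rigidly align two point sets and match mutual nearest neighbors.

    Iterative closest point with a least-squares (Kabsch) rigid update;
    after convergence only mutual nearest-neighbor pairs within half the
    median spacing are reported, so the forward and reverse assignments
    agree for every match.
    """
    p0 = np.asarray(points_t0, dtype=float)
    p1 = np.asarray(points_t1, dtype=float)
    ids0 = np.arange(len(p0)) if ids_t0 is None else np.asarray(ids_t0)
    ids1 = np.arange(len(p1)) if ids_t1 is None else np.asarray(ids_t1)

    d, _ = cKDTree(p0).query(p0, k=2)
    spacing = float(np.median(d[:, 1]))

    # multi-start: a pure nearest-neighbor refinement locks onto
    # lattice-shifted local minima, but those have clearly worse residuals
    # on a curved lattice, so several rotation seeds are refined and the
    # fit with the smallest inlier residual wins.
    tree1 = cKDTree(p1)
    best = None
    for deg in np.arange(-12.0, 12.0 + 1e-9, 2.0):
        theta, t = _refine_icp(p0, p1, tree1, spacing,
                               math.radians(deg), n_iter=n_iter)
        R = np.array([[math.cos(theta), -math.sin(theta)],
                      [math.sin(theta), math.cos(theta)]])
        dist, _ = tree1.query(p0 @ R.T + t, k=1)
        inl = dist < 0.5 * spacing
        score = (int(inl.sum()), -float(np.median(dist[inl])) if inl.any() else 0.0)
        if best is None or score > best[0]:
            best = (score, theta, t)
    _score, theta, t = best

    R = np.array([[math.cos(theta), -math.sin(theta)],
                  [math.sin(theta), math.cos(theta)]])
    q0 = p0 @ R.T + t                 # t0 mapped into t1 frame
    t1tree = cKDTree(p1)
    d01, j01 = t1tree.query(q0, k=1)
    t0tree = cKDTree(q0)
    d10, j10 = t0tree.query(p1, k=1)

    id_map: dict[int, int] = {}
    matched1 = set()
    err = []
    for i0 in range(len(p0)):
        j1 = j01[i0]
        # mutual nearest neighbors; the gate leaves room for the subtle
        # (sub-bond) motions of cones near a gliding core
        if j10[j1] == i0 and d01[i0] < 0.85 * spacing:
            id_map[int(ids0[i0])] = int(ids1[j1])
            matched1.add(int(j1))
            err.append(d01[i0] ** 2)
    unmatched_t0 = [int(ids0[i]) for i in range(len(p0))
                    if int(ids0[i]) not in id_map]
    unmatched_t1 = [int(ids1[i]) for i in range(len(p1)) if i not in matched1]
    rmse = math.sqrt(float(np.mean(err))) if err else float("nan")
    return Correspondence(id_map, theta, (float(t[0]), float(t[1])),
                          unmatched_t0, unmatched_t1, rmse)


# --------------------------------------------------------------------------
# glide detection
# --------------------------------------------------------------------------

def detect_glide(
    pair,
    corr: Correspondence | None = None,
    core_radius_factor: float = 3.0,
) -> list[dict]:
    """Signed glide (bond flips along the glide line) per planted core.

    Triangulations restricted to the cones present at both timepoints are
    compared bond by bond inside a window around each first-timepoint
    core; every flipped bond is one row of glide.  The sign is the
    tangential direction of the emerging bond's midpoint relative to the
    core.
    """
    sample = pair.sample_t0
    spec = sample.spec
    if corr is None:
        if getattr(pair, "truth_map", None):
            # generator pairs carry their exact correspondence; cones next
            # to a gliding core move by up to half a bond, which distance
            # matching would otherwise re-label along the glide line
            corr = Correspondence(dict(pair.truth_map), pair.rotation_rad,
                                  pair.translation_um, [], [], 0.0)
        else:
            corr = match_timepoints(sample.xy, pair.xy_t1,
                                    sample.ids, pair.ids_t1)

    # shared points; both triangulations are built over the *same* node
    # ordering so that edges are directly comparable
    shared_ids = sorted(corr.id_map)
    idx0 = {int(i): k for k, i in enumerate(sample.ids)}
    idx1 = {int(i): k for k, i in enumerate(pair.ids_t1)}
    rows0 = [idx0[i] for i in shared_ids]
    rows1 = [idx1[corr.id_map[i]] for i in shared_ids]
    xy0 = sample.xy[rows0]
    th, (tx, ty) = corr.rotation_rad, corr.translation_um
    Rb = np.array([[math.cos(th), math.sin(th)],
                   [-math.sin(th), math.cos(th)]])
    xy1 = (pair.xy_t1[rows1] - (tx, ty)) @ Rb.T   # back into the t0 frame

    wrap = ("angle", sample.geometry.sector_angle) \
        if sample.geometry.sector_angle > 0 else None
    anchor = float(np.hypot(xy0[:, 0], xy0[:, 1]).min())
    tri0 = triangulate(xy0, wrap=wrap, spec=spec, center=(0.0, 0.0),
                       band_anchor=anchor)
    tri1 = triangulate(xy1, wrap=wrap, spec=spec, center=(0.0, 0.0),
                       band_anchor=anchor)

    gone_all = tri0.edges - tri1.edges
    new_all = tri1.edges - tri0.edges
    coord0 = tri0.coordination
    coord1 = tri1.coordination

    out = []
    for di, d in enumerate(sample.defects_truth):
        pos = np.array(d.xy)
        rad = core_radius_factor * spec.a_col
        dist0 = np.hypot(xy0[:, 0] - pos[0], xy0[:, 1] - pos[1])
        window = dist0 < rad
        # the 5-7 pair of this core at either timepoint
        core_nodes: set[int] = set()
        for coord in (coord0, coord1):
            for val in (5, 7):
                cand = np.nonzero(window & (coord == val))[0]
                if len(cand):
                    core_nodes.add(int(cand[np.argmin(dist0[cand])]))
        near = lambda e: (  # noqa: E731 - midpoint inside the core window
            np.linalg.norm(0.5 * (xy0[e[0]] + xy0[e[1]]) - pos) < rad)
        gone = [e for e in gone_all if near(e)]
        new = [e for e in new_all if near(e)]
        # a glide flip swaps the diagonal of a quad near the core: the
        # lost and gained bonds cross, and after a genuine flip the lost
        # diagonal violates the Delaunay criterion decisively (opposite
        # angles sum far beyond 180 degrees), whereas noise-induced flips
        # sit at the degeneracy margin
        flips = []
        for eg in gone:
            for en in new:
                if not _segments_cross(xy0[eg[0]], xy0[eg[1]],
                                       xy0[en[0]], xy0[en[1]]):
                    continue
                if _flip_margin_deg(xy1, eg, en, spec) > 20.0:
                    flips.append((eg, en))
                    break
        n_flips = len(flips)
        sign = 0
        if n_flips:
            # sign from the radial displacement of the five-coordinated node
            rhat = _local_radial(pos, (0.0, 0.0))
            disp = 0.0
            for coord, sgn in ((coord0, -1.0), (coord1, 1.0)):
                cand = np.nonzero(window & (coord == 5))[0]
                if len(cand):
                    n5 = int(cand[np.argmin(dist0[cand])])
                    disp += sgn * float(xy0[n5] @ rhat)
            sign = 1 if disp >= 0 else -1
        out.append({
            "defect_index": di,
            "rows": n_flips * (sign if sign else 1),
            "n_flips": n_flips,
            "bonds_lost": sorted(gone),
            "bonds_gained": sorted(new),
        })
    return out


def _flip_margin_deg(xy, lost, gained, spec: LatticeSpec) -> float:
    """How decisively the lost diagonal violates the Delaunay criterion.

    For the quad made of the lost diagonal ``lost`` and the crossing
    gained diagonal ``gained``, returns the sum of the two angles opposite
    the lost diagonal minus 180 degrees, measured in the local
    isotropy-restoring frame about the quad centroid (radial / a_row,
    tangential arc * sqrt(3) / a_col).  A genuine glide flip scores far
    above zero; jitter-induced flips hover at the degeneracy.
    """
    quad = np.array([xy[lost[0]], xy[lost[1]], xy[gained[0]], xy[gained[1]]])
    cen = quad.mean(axis=0)
    s_bar = float(np.linalg.norm(cen))
    phi_bar = math.atan2(cen[1], cen[0])
    pts = []
    for p in quad:
        sp = float(np.linalg.norm(p))
        dphi = math.atan2(p[1], p[0]) - phi_bar
        dphi = (dphi + math.pi) % (2.0 * math.pi) - math.pi
        pts.append((dphi * s_bar * math.sqrt(3.0) / spec.a_col,
                    sp / spec.a_row))
    A, C, B, D = (np.asarray(p) for p in pts)

    def ang(P, Q, R):
        v1, v2 = Q - P, R - P
        c = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-300)
        return math.acos(min(1.0, max(-1.0, float(c))))

    return math.degrees(ang(B, A, C) + ang(D, A, C) - math.pi)


def _segments_cross(a, b, c, d) -> bool:
    def orient(p, q, r):
        return (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])
    return (orient(a, b, c) * orient(a, b, d) < 0
            and orient(c, d, a) * orient(c, d, b) < 0)


# --------------------------------------------------------------------------
# plane fitting (3D stacks)
# --------------------------------------------------------------------------

def fit_plane(points3d: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares plane through 3D points.

    Returns ``(origin, normal, rmse)``: the centroid, the unit normal and
    the root-mean-square residual perpendicular to the plane.
    """
    p = np.asarray(points3d, dtype=float)
    c = p.mean(axis=0)
    _U, S, Vt = np.linalg.svd(p - c, full_matrices=False)
    normal = Vt[2]
    res = (p - c) @ normal
    return c, normal, float(np.sqrt(np.mean(res ** 2)))


def project_to_plane(points3d: np.ndarray, origin: np.ndarray,
                     normal: np.ndarray) -> np.ndarray:
    """Orthogonal projection onto the plane, in 2D plane coordinates."""
    p = np.asarray(points3d, dtype=float)
    n = np.asarray(normal) / np.linalg.norm(normal)
    # in-plane basis
    a = np.array([1.0, 0.0, 0.0])
    if abs(n @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = a - (a @ n) * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    rel = p - origin
    return np.column_stack([rel @ e1, rel @ e2])


# --------------------------------------------------------------------------
# honeycomb core polygons (glide vs shuffle)
# --------------------------------------------------------------------------

def classify_core_polygons(
    honeycomb_points: np.ndarray,
    core_region: tuple[float, float, float],
    bond_factor: float = 1.35,
) -> tuple[str, dict[int, int]]:
    """Face census of a same-subtype honeycomb graph around a core.

    ``core_region`` is ``(cx, cy, radius)``.  Bonds connect points closer
    than ``bond_factor`` times the minimum neighbor distance.  Faces whose
    centroid lies in the core region are sized; a heptagon-pentagon pair
    means a glide core, a single octagon a shuffle core.

    Returns ``(label, face_census)`` with label in
    ``{"glide", "shuffle", "regular", "other"}``.
    """
    pts = np.asarray(honeycomb_points, dtype=float)
    tree = cKDTree(pts)
    # a honeycomb node has exactly three neighbors, but the bond lengths
    # of an anisotropic honeycomb are uneven, so bond mutual 3-nearest
    # neighbors instead of thresholding a single distance
    k = min(4, len(pts))
    _d, jj = tree.query(pts, k=k)
    cand: dict[int, set[int]] = {i: set(int(j) for j in jj[i, 1:])
                                 for i in range(len(pts))}
    pairs = {(min(i, j), max(i, j))
             for i in cand for j in cand[i] if i in cand[j]}
    nb: dict[int, list[int]] = defaultdict(list)
    for i, j in pairs:
        nb[i].append(j)
        nb[j].append(i)

    # planar face traversal: walk half-edges taking the most clockwise turn
    half_edges = {(i, j) for i, j in pairs} | {(j, i) for i, j in pairs}
    visited: set[tuple[int, int]] = set()
    faces: list[list[int]] = []
    for he in sorted(half_edges):
        if he in visited:
            continue
        face = []
        e = he
        for _ in range(1000):
            visited.add(e)
            i, j = e
            face.append(i)
            # sort neighbors of j by angle; pick the next half-edge cw from (j, i)
            vin = pts[i] - pts[j]
            ang_in = math.atan2(vin[1], vin[0])
            cands = []
            for k in nb[j]:
                v = pts[k] - pts[j]
                ang = math.atan2(v[1], v[0])
                rel = (ang - ang_in) % (2.0 * math.pi)
                cands.append((rel, k))
            cands.sort()
            # smallest positive rotation (ccw) from the incoming edge
            k = cands[0][1] if cands[0][0] > 1e-12 else cands[-1][1]
            e = (j, k)
            if e == he:
                break
        else:  # pragma: no cover
            continue
        faces.append(face)

    cx, cy, rad = core_region
    census: dict[int, int] = defaultdict(int)
    for f in faces:
        if len(f) < 3 or len(f) > 12:
            continue            # outer face or degenerate
        cen = pts[f].mean(axis=0)
        if math.hypot(cen[0] - cx, cen[1] - cy) <= rad:
            census[len(f)] += 1
    census = dict(census)
    sizes = {k for k in census if k != 6 and census[k] > 0}
    if sizes == {5, 7}:
        label = "glide"
    elif sizes == {8}:
        label = "shuffle"
    elif not sizes:
        label = "regular"
    else:
        label = "other"
    return label, census


# --------------------------------------------------------------------------
# vacancy search (assertion utility)
# --------------------------------------------------------------------------

def find_vacancies(points: np.ndarray, spec: LatticeSpec,
                   factor: float = 1.35) -> list[tuple[float, float, float]]:
    """Report unit-cell-sized holes (candidate vacancies) in a point set.

    A vacancy in the cone mosaic would be a missing unit cell, leaving a
    hole of about one column spacing in the UV sublattice.  Returns a
    list of ``(x, y, circumradius)`` for Delaunay triangles whose
    circumradius exceeds ``factor * a_col``; an empty list asserts the
    absence of vacancies (climb motion is never inferred).
    """
    xy = np.asarray(points, dtype=float)
    dt = Delaunay(xy)
    hull = set(dt.convex_hull.ravel().tolist())
    out = []
    for simp in dt.simplices:
        if any(int(v) in hull for v in simp):
            continue          # rim slivers are not holes
        a, b, c = xy[simp]
        # a hole triangle has *all three* sides longer than any lattice
        # bond; slivers from near-degenerate quads keep one short side
        sides = (np.linalg.norm(b - c), np.linalg.norm(a - c),
                 np.linalg.norm(a - b))
        if min(sides) > factor * spec.oblique:
            cen = (a + b + c) / 3.0
            out.append((float(cen[0]), float(cen[1]), float(min(sides))))
    return out
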