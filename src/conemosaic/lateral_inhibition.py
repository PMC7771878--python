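"""Lateral-inhibition fate dynamics on a static disordered cell packing.

The contrasting model to repulsion-driven crystallization: cells do not
move; a wave of de-inhibition sweeps across a disordered packing and each
cell's fate ``u`` evolves under inhibitory signaling from its neighbors,

    tau du_i/dt = f(u_i - s_i) - u_i,       f(y) = (1 + tanh(4 y)) / 2,

with the received signal ``s_i = s0(x_i, t) + sum_j c_ij D*(u_j)``, a
Gaussian coupling ``c_ij = exp(-d_ij^2 / (2 l^2))`` over centroid
distances (no self-signaling), ligand activity
``D*(u) = (a0 + 3 u^3 / (1 + u^2) * a1) * u`` and a moving sigmoidal
release front ``s0 = S0 sigma((x - v t) / (eps sqrt(A0)))`` with
``v = l / (4 tau)``.  High-fate (u ~ 1) cells form a triangular pattern
whose defect load grows as the signaling range ``l`` approaches the cell
size -- the regime relevant to the cone mosaic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import Delaunay, Voronoi, cKDTree

__all__ = [
    "CellPacking",
    "LIParams",
    "FateTrajectory",
    "generate_packing",
    "coupling_weights",
    "external_signal",
    "fate_rhs",
    "integrate_fates",
    "pattern_census",
]


# --------------------------------------------------------------------------
# packing
# --------------------------------------------------------------------------

@dataclass
class CellPacking:
    """Disordered polygonal packing, periodic across the y (front-transverse)
    boundary, walls at x = 0 and x = Lx."""

    centroids: np.ndarray                  # (n, 2)
    polygons: list[np.ndarray]             # cell vertex loops
    areas: np.ndarray
    adjacency: sp.csr_matrix               # symmetric 0/1
    Lx: float
    Ly: float

    @property
    def n_cells(self) -> int:
        return len(self.centroids)

    @property
    def mean_area(self) -> float:
        return float(np.mean(self.areas))


def _voronoi_cells(pts: np.ndarray, Lx: float, Ly: float):
    """Voronoi polygons and adjacency, periodic in y, mirrored in x."""
    n = len(pts)
    tiles = [pts,
             pts + (0.0, Ly), pts - (0.0, Ly)]
    # mirror across the x walls so boundary cells close
    for base in list(tiles):
        m0 = base.copy()
        m0[:, 0] = -m0[:, 0]
        m1 = base.copy()
        m1[:, 0] = 2.0 * Lx - m1[:, 0]
        tiles.extend([m0, m1])
    allp = np.vstack(tiles)
    vor = Voronoi(allp)
    polys = []
    areas = np.empty(n)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        verts = vor.vertices[region]
        polys.append(verts)
        x, y = verts[:, 0], verts[:, 1]
        areas[i] = 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))
    rows, cols = [], []
    for (a, b) in vor.ridge_points:
        ia, ib = a % n, b % n
        # keep ridges between a base cell and any image of another cell,
        # except mirror self-images
        if a < 3 * n or b < 3 * n:
            if ia != ib:
                rows.extend([ia, ib])
                cols.extend([ib, ia])
    data = np.ones(len(rows))
    adj = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    adj.data[:] = 1.0
    return polys, areas, adj


def generate_packing(n_cells: int, seed: int = 0,
                     relax_iters: int = 2, aspect: float = 2.0) -> CellPacking:
    """Disordered periodic packing from a relaxed Voronoi tessellation.

    Uniform random seeds are tessellated and relaxed ``relax_iters``
    Lloyd steps toward the centroidal configuration; a couple of steps
    leave a disordered but space-filling packing of unit mean area (the
    stand-in for an equal-tension vertex-model tissue).
    """
    rng = np.random.default_rng(seed)
    Ly = math.sqrt(n_cells / aspect)
    Lx = aspect * Ly
    pts = np.column_stack([rng.uniform(0.0, Lx, n_cells),
                           rng.uniform(0.0, Ly, n_cells)])
    for _ in range(relax_iters):
        polys, _areas, _adj = _voronoi_cells(pts, Lx, Ly)
        new = []
        for verts in polys:
            x, y = verts[:, 0], verts[:, 1]
            a = 0.5 * (np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))
            cx = np.sum((x + np.roll(x, 1)) * (x * np.roll(y, 1) - np.roll(x, 1) * y)) / (6.0 * a)
            cy = np.sum((y + np.roll(y, 1)) * (x * np.roll(y, 1) - np.roll(x, 1) * y)) / (6.0 * a)
            new.append((cx, cy))
        pts = np.asarray(new)
        pts[:, 0] = np.clip(pts[:, 0], 1e-6, Lx - 1e-6)
        pts[:, 1] = np.mod(pts[:, 1], Ly)
    polys, areas, adj = _voronoi_cells(pts, Lx, Ly)
    return CellPacking(pts, polys, areas, adj, Lx, Ly)


# --------------------------------------------------------------------------
# model parameters and right-hand side
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LIParams:
    """Signaling range ``l`` is in units of sqrt(mean cell area)."""

    l: float
    tau: float = 1.0
    S0: float = 1.0
    eps: float = 1.0 / 50.0
    a0: float = 0.05
    a1: float = 0.95

    @property
    def v(self) -> float:
        return self.l / (4.0 * self.tau)


def sigma(y):
    return 0.5 * (1.0 + np.tanh(2.0 * y))


def coupling_weights(packing: CellPacking, l: float,
                     cutoff_factor: float = 4.0) -> sp.csr_matrix:
    """Sparse Gaussian coupling ``c_ij = exp(-d_ij^2 / 2 l^2)``.

    Distances are centroid to centroid, periodic across the y boundary;
    pairs beyond ``cutoff_factor * l`` are dropped (weight < e^-8) and
    cells never signal to themselves.
    """
    pts = packing.centroids
    n = len(pts)
    cut = cutoff_factor * l
    tiled = np.vstack([pts, pts + (0.0, packing.Ly), pts - (0.0, packing.Ly)])
    tree = cKDTree(tiled)
    base = cKDTree(pts)
    pairs = base.query_ball_tree(tree, cut)
    rows, cols, vals = [], [], []
    for i, lst in enumerate(pairs):
        for j in lst:
            jj = j % n
            if jj == i:
                continue
            d = np.linalg.norm(pts[i] - tiled[j])
            rows.append(i)
            cols.append(jj)
            vals.append(math.exp(-d * d / (2.0 * l * l)))
    c = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    c.sum_duplicates()
    return c


def external_signal(x, t: float, params: LIParams, A0: float):
    """Moving inhibition front ``s0(x, t)``; high ahead of the front."""
    return params.S0 * sigma((x - params.v * t) / (params.eps * math.sqrt(A0)))


def ligand_output(u, params: LIParams):
    """Signal produced by a cell of fate u: ``D*(u) = a(u) * u``."""
    a = params.a0 + (3.0 * u ** 3 / (1.0 + u ** 2)) * params.a1
    return a * u


def fate_rhs(t: float, u: np.ndarray, packing: CellPacking,
             params: LIParams, c: sp.csr_matrix, A0: float) -> np.ndarray:
    s = external_signal(packing.centroids[:, 0], t, params, A0) \
        + c @ ligand_output(u, params)
    f = sigma(2.0 * (u - s))
    return (f - u) / params.tau


@dataclass
class FateTrajectory:
    t: np.ndarray
    u: np.ndarray                 # (n_times, n_cells)
    packing: CellPacking
    params: LIParams
    c: sp.csr_matrix = field(repr=False, default=None)

    @property
    def final(self) -> np.ndarray:
        return self.u[-1]


def integrate_fates(packing: CellPacking, params: LIParams,
                    t_end: float | None = None, rtol: float = 1e-6,
                    atol: float = 1e-8, n_snapshots: int = 8) -> FateTrajectory:
    """Integrate the fate dynamics from ``u = 0`` until the pattern is set.

    ``t_end`` defaults to the time for the front to cross the packing
    plus a settling margin of ``20 tau``.  Raises if the integrator fails.
    """
    A0 = packing.mean_area
    c = coupling_weights(packing, params.l * math.sqrt(A0))
    if t_end is None:
        t_end = packing.Lx / params.v + 20.0 * params.tau
    u0 = np.zeros(packing.n_cells)
    ts = np.linspace(0.0, t_end, n_snapshots)
    sol = solve_ivp(fate_rhs, (0.0, t_end), u0, t_eval=ts,
                    args=(packing, params, c, A0),
                    method="RK45", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"fate integration failed: {sol.message}")
    u = sol.y.T
    if u.min() < -0.05 or u.max() > 1.05:
        raise RuntimeError("fate variable left the [-0.05, 1.05] band")
    return FateTrajectory(sol.t, u, packing, params, c)


# --------------------------------------------------------------------------
# pattern census
# --------------------------------------------------------------------------

def pattern_census(u: np.ndarray, packing: CellPacking,
                   u_threshold: float = 0.5,
                   x_range: tuple[float, float] | None = None) -> dict:
    """Census of the high-fate pattern.

    High-fate cells (``u > u_threshold``) are triangulated (periodic in
    y); interior nodes with coordination other than six are defects.  The
    number of intervening low-fate cells between two pattern-adjacent
    high-fate cells is the shortest-path hop count through the cell
    adjacency graph minus one.

    ``x_range`` restricts the census to a sub-window (e.g. the
    late-patterned half).  Returns counts, the defect indices, spacing
    statistics and the mean intervening-cell count.
    """
    high = np.nonzero(u > u_threshold)[0]
    pts = packing.centroids[high]
    out = {"n_high": len(high), "high_indices": high}
    if len(high) < 5:
        out.update({"n_defects": 0, "defect_fraction": float("nan"),
                    "intervening_mean": float("nan"), "spacing_mean": float("nan")})
        return out

    # periodic triangulation in y
    n = len(pts)
    tiled = np.vstack([pts, pts + (0.0, packing.Ly), pts - (0.0, packing.Ly)])
    tri = Delaunay(tiled)
    nbrs: dict[int, set[int]] = {i: set() for i in range(n)}
    for simp in tri.simplices:
        for a in range(3):
            for b in range(3):
                if a != b and (simp[a] < n or simp[b] < n):
                    ia, ib = int(simp[a]) % n, int(simp[b]) % n
                    if ia != ib:
                        nbrs[ia].add(ib)
                        nbrs[ib].add(ia)
    coord = np.array([len(nbrs[i]) for i in range(n)])

    # interior: away from the x walls by one pattern spacing
    d_nn = []
    for i in range(n):
        if nbrs[i]:
            d_nn.append(min(np.linalg.norm(pts[i] - pts[j]) for j in nbrs[i]))
    spacing = float(np.median(d_nn)) if d_nn else float("nan")
    lo = x_range[0] if x_range else spacing
    hi = x_range[1] if x_range else packing.Lx - spacing
    interior = (pts[:, 0] > max(lo, spacing)) & (pts[:, 0] < min(hi, packing.Lx - spacing))

    defects = np.nonzero(interior & (coord != 6))[0]
    n_int = int(interior.sum())

    # intervening low-fate cells between pattern neighbors
    graph = packing.adjacency
    hops = []
    high_set = set(int(h) for h in high)
    dist = dijkstra(graph, directed=False, unweighted=True,
                    indices=high, limit=12)
    hi_index = {int(h): k for k, h in enumerate(high)}
    for i in range(n):
        if not interior[i]:
            continue
        for j in nbrs[i]:
            if j <= i:
                continue
            h = dist[hi_index[int(high[i])], int(high[j])]
            if np.isfinite(h):
                hops.append(h - 1.0)
    out.update({
        "n_defects": int(len(defects)),
        "n_interior": n_int,
        "defect_fraction": len(defects) / n_int if n_int else float("nan"),
        "defect_indices": high[defects],
        "intervening_mean": float(np.mean(hops)) if hops else float("nan"),
        "intervening_counts": np.asarray(hops),
        "spacing_mean": spacing,
    })
    return out
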