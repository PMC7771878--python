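"""Grain-boundary detection in row-traced and simulated cone mosaics.

Two detectors decide, per Y-junction, membership in a grain boundary:

* the *primary* detector measures how much the local row orientation
  rotates in five polar boxes around the defect (``dphi_rms`` against an
  angular cutoff, 12 degrees by default);
* the *chain* detector looks for approximately straight chains of five
  mutually nearest Y-junctions (linearity score against ``a_gb = 7/8``).

Row orientation comes either from traced rows (polylines, weighted by
vertex count) or from "row bonds" of a simulated density-peak lattice
(bonds best aligned with the inward radial direction, weighted by length).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from conemosaic.synthetic import RowTraces

__all__ = [
    "PolarBox",
    "TracedRowField",
    "RowBondField",
    "PrimaryGBCall",
    "ChainGBCall",
    "box_row_orientation",
    "dphi_rms",
    "call_gb_primary",
    "extract_row_bonds",
    "chain_scores",
    "call_gb_chain",
    "margin_domain_rotation",
]


@dataclass(frozen=True)
class PolarBox:
    """Axis-aligned box in polar coordinates about ``center``."""

    r_lo: float
    r_hi: float
    th_lo: float
    th_hi: float

    def contains(self, r: np.ndarray, th: np.ndarray) -> np.ndarray:
        return (r >= self.r_lo) & (r < self.r_hi) \
            & (th >= self.th_lo) & (th < self.th_hi)


# --------------------------------------------------------------------------
# row-orientation fields
# --------------------------------------------------------------------------

class TracedRowField:
    """Row orientation from traced polylines (center -> periphery).

    Within a box each intersecting row contributes its principal direction
    (PCA of its vertices inside the box), signed to run from center to
    periphery, with weight equal to the number of vertices in the box.
    """

    def __init__(self, traces: RowTraces, center=(0.0, 0.0),
                 period: float | None = None):
        self.center = np.asarray(center, dtype=float)
        self.period = period
        self.rows = []
        for poly in traces.polylines:
            if len(poly) < 2:
                continue
            rel = poly - self.center
            r = np.hypot(rel[:, 0], rel[:, 1])
            th = np.arctan2(rel[:, 1], rel[:, 0])
            if period is not None:
                th = np.mod(th, period)
            self.rows.append((poly, r, th))

    def _row_items(self, box: PolarBox):
        for poly, r, th in self.rows:
            for shift in self._shifts(box):
                m = box.contains(r, th + shift)
                if m.sum() >= 2:
                    yield poly[m], int(m.sum())

    def _shifts(self, box: PolarBox):
        if self.period is None:
            return (0.0,)
        return (-self.period, 0.0, self.period)

    def orientations(self, box: PolarBox):
        """Yield (unit orientation, weight) per row intersecting the box."""
        for pts, w in self._row_items(box):
            c = pts.mean(axis=0)
            X = pts - c
            _w, V = np.linalg.eigh(X.T @ X)
            u = V[:, -1]                      # principal direction
            # orient center -> periphery along the trace
            if float(u @ (pts[-1] - pts[0])) < 0:
                u = -u
            yield u, w


class RowBondField:
    """Row orientation from directed row bonds of a peak lattice.

    Bonds run (mostly) from the center outward; the weight of a bond is
    its length, and a bond counts for a box when it lies entirely inside.
    """

    def __init__(self, starts: np.ndarray, ends: np.ndarray,
                 center=(0.0, 0.0), period: float | None = None):
        self.center = np.asarray(center, dtype=float)
        self.period = period
        self.starts = np.asarray(starts, dtype=float)
        self.ends = np.asarray(ends, dtype=float)
        rel_s = self.starts - self.center
        rel_e = self.ends - self.center
        self.r_s = np.hypot(rel_s[:, 0], rel_s[:, 1])
        self.r_e = np.hypot(rel_e[:, 0], rel_e[:, 1])
        self.th_s = np.arctan2(rel_s[:, 1], rel_s[:, 0])
        self.th_e = np.arctan2(rel_e[:, 1], rel_e[:, 0])
        if period is not None:
            self.th_s = np.mod(self.th_s, period)
            self.th_e = np.mod(self.th_e, period)

    def orientations(self, box: PolarBox):
        shifts = (0.0,) if self.period is None \
            else (-self.period, 0.0, self.period)
        for shift in shifts:
            inside = (box.contains(self.r_s, self.th_s + shift)
                      & box.contains(self.r_e, self.th_e + shift))
            for i in np.nonzero(inside)[0]:
                v = self.ends[i] - self.starts[i]
                ell = float(np.hypot(v[0], v[1]))
                if ell > 0:
                    # orient outward (center -> periphery)
                    if self.r_e[i] < self.r_s[i]:
                        v = -v
                    yield v / ell, ell


def box_row_orientation(rows, box: PolarBox) -> np.ndarray | None:
    """Weighted mean row orientation in a polar box, as a unit vector.

    Returns None when no row element intersects the box (undefined
    orientation).
    """
    acc = np.zeros(2)
    total = 0.0
    for u, w in rows.orientations(box):
        acc += w * np.asarray(u, dtype=float)
        total += w
    if total == 0.0 or np.linalg.norm(acc) == 0.0:
        return None
    return acc / np.linalg.norm(acc)


# --------------------------------------------------------------------------
# primary detector (five-box row-rotation measure)
# --------------------------------------------------------------------------

@dataclass
class PrimaryGBCall:
    defect_index: int
    r0: float
    theta0: float
    dphi23_deg: float
    dphi45_deg: float
    dphi_rms_deg: float
    in_gb: bool
    delta_r: float
    cutoff_deg: float
    boxes: list = field(default_factory=list, repr=False)
    unit_vectors: list = field(default_factory=list, repr=False)

    @property
    def defined(self) -> bool:
        return not math.isnan(self.dphi_rms_deg)


def _five_boxes(r0: float, th0: float, dr: float) -> list[PolarBox]:
    """The five averaging boxes around a defect at polar ``(r0, th0)``.

    Box 1 is centered on the defect; boxes 2/3 flank it radially and
    boxes 4/5 angularly, each of radial extent ``dr`` and angular extent
    ``dr / r0``.
    """
    half_th = 0.5 * dr / r0
    return [
        PolarBox(r0 - dr / 2, r0 + dr / 2, th0 - half_th, th0 + half_th),
        PolarBox(r0 - 3 * dr / 2, r0 - dr / 2, th0 - half_th, th0 + half_th),
        PolarBox(r0 + dr / 2, r0 + 3 * dr / 2, th0 - half_th, th0 + half_th),
        PolarBox(r0 - dr / 2, r0 + dr / 2, th0 - 3 * half_th, th0 - half_th),
        PolarBox(r0 - dr / 2, r0 + dr / 2, th0 + half_th, th0 + 3 * half_th),
    ]


def dphi_rms(rows, defect_polar: tuple[float, float],
             delta_r: float) -> tuple[float, float, float]:
    """Row-orientation rotation about a defect, degrees.

    Returns ``(dphi23, dphi45, dphi_rms)`` where 2/3 are the radially
    flanking boxes and 4/5 the angularly flanking ones;
    ``dphi_rms = sqrt(dphi45**2 + dphi23**2)``.  NaNs when any flanking
    box has undefined orientation.
    """
    r0, th0 = defect_polar
    boxes = _five_boxes(r0, th0, delta_r)
    us = [box_row_orientation(rows, b) for b in boxes]
    if any(u is None for u in us[1:]):
        return (float("nan"),) * 3
    def angle(u, v):
        return math.degrees(math.acos(min(1.0, max(-1.0, float(u @ v)))))
    d23 = angle(us[1], us[2])
    d45 = angle(us[3], us[4])
    return d23, d45, math.hypot(d23, d45)


def call_gb_primary(
    rows,
    defects_polar: np.ndarray,
    delta_r: float = 100.0,
    cutoff_deg: float = 12.0,
) -> tuple[list[PrimaryGBCall], float]:
    """Per-defect grain-boundary calls by the five-box rotation measure.

    ``defects_polar`` is (n, 2) of ``(r, theta)`` defect positions about
    the row field's center.  Returns the calls and the in-GB fraction over
    defects with a defined measure.
    """
    calls = []
    n_def = 0
    n_in = 0
    for i, (r0, th0) in enumerate(np.atleast_2d(defects_polar)):
        d23, d45, rms = dphi_rms(rows, (float(r0), float(th0)), delta_r)
        in_gb = (not math.isnan(rms)) and rms > cutoff_deg
        calls.append(PrimaryGBCall(i, float(r0), float(th0), d23, d45, rms,
                                   in_gb, delta_r, cutoff_deg))
        if not math.isnan(rms):
            n_def += 1
            n_in += int(in_gb)
    frac = n_in / n_def if n_def else float("nan")
    return calls, frac


# --------------------------------------------------------------------------
# row bonds from simulated peak lattices
# --------------------------------------------------------------------------

def extract_row_bonds(tri, center=(0.0, 0.0)) -> tuple[RowBondField, np.ndarray, dict]:
    """Directed row bonds of a triangulated peak lattice.

    Every peak selects the one bond best aligned with the *inward* radial
    direction (the largest positive dot product with ``-rhat``); that bond
    is its inward row bond.  A regular interior peak then carries two row
    bonds (one in, one out), a Y-junction peak three (one in, two out) and
    a reverse Y-junction peak one.

    Returns ``(field, degree, classes)`` where ``field`` feeds the primary
    detector, ``degree`` is the per-peak row-bond count and ``classes``
    maps ``"Y"`` / ``"reverseY"`` to peak index arrays.
    """
    xy = tri.xy
    c = np.asarray(center, dtype=float)
    starts, ends = [], []
    inward_of = {}
    for i in range(len(xy)):
        rel = xy[i] - c
        nr = np.linalg.norm(rel)
        if nr == 0 or not tri.neighbors.get(i):
            continue
        inward = -rel / nr
        best, best_dot = None, 0.0
        for j in tri.neighbors[i]:
            v = xy[j] - xy[i]
            d = float(v @ inward) / (np.linalg.norm(v) + 1e-300)
            if d > best_dot:
                best, best_dot = j, d
        if best is not None:
            inward_of[i] = best
            starts.append(xy[best])
            ends.append(xy[i])
    degree = np.zeros(len(xy), dtype=int)
    for i, j in inward_of.items():
        degree[i] += 1
        degree[j] += 1
    interior = tri.interior()
    classes = {
        "Y": np.nonzero(interior & (degree == 3))[0],
        "reverseY": np.nonzero(interior & (degree == 1))[0],
        "regular": np.nonzero(interior & (degree == 2))[0],
    }
    field = RowBondField(np.asarray(starts), np.asarray(ends), center=c)
    return field, degree, classes


# --------------------------------------------------------------------------
# chain (linearity) detector
# --------------------------------------------------------------------------

@dataclass
class ChainGBCall:
    defect_index: int
    chain: list[int]
    score: float
    in_gb: bool


def chain_scores(
    positions: np.ndarray,
    wrap: tuple[str, float] | None = None,
    center=(0.0, 0.0),
    chain_length: int = 5,
) -> list[tuple[list[int], float]]:
    """Nearest-neighbor chains of five defects and their linearity score.

    From each defect a chain is grown greedily: repeatedly append the
    nearest defect not already in the chain (ties broken by smallest
    index).  The score is the mean projection of the four consecutive
    unit steps onto the unit end-to-end direction; 1 for a perfectly
    straight, monotonically ordered chain.
    """
    pts = np.asarray(positions, dtype=float)
    n = len(pts)
    if n < chain_length:
        return [([], float("nan"))] * n
    # ghost copies for periodic sectors
    if wrap is not None and wrap[0] == "angle":
        a = wrap[1]
        cx, cy = center
        ghosts = [pts]
        for sgn in (-1.0, 1.0):
            R = np.array([[math.cos(sgn * a), -math.sin(sgn * a)],
                          [math.sin(sgn * a), math.cos(sgn * a)]])
            ghosts.append((pts - (cx, cy)) @ R.T + (cx, cy))
        allp = np.vstack(ghosts)
    else:
        allp = pts
    tree = cKDTree(allp)

    out = []
    for i in range(n):
        chain = [i]
        chain_pts = [pts[i]]
        used = {i}
        while len(chain) < chain_length:
            k = min(4 * len(used) + 8, len(allp))
            d, idx = tree.query(chain_pts[-1], k=k)
            nxt = None
            for dd, jj in sorted(zip(d, idx), key=lambda t: (t[0], t[1] % n)):
                if (jj % n) not in used:
                    nxt = jj
                    break
            if nxt is None:
                break
            used.add(nxt % n)
            chain.append(nxt % n)
            chain_pts.append(allp[nxt])
        if len(chain) < chain_length:
            out.append((chain, float("nan")))
            continue
        p = np.asarray(chain_pts)
        e = p[0] - p[-1]
        e = e / (np.linalg.norm(e) + 1e-300)
        score = 0.0
        for j in range(chain_length - 1):
            step = p[j] - p[j + 1]
            score += float(e @ step) / (np.linalg.norm(step) + 1e-300)
        out.append((chain, score / (chain_length - 1)))
    return out


def call_gb_chain(
    scores: list[tuple[list[int], float]],
    a_gb: float = 7.0 / 8.0,
) -> tuple[list[ChainGBCall], float]:
    """Flag defects in grain boundaries by the chain-linearity score.

    Every member of a chain whose score exceeds ``a_gb`` is flagged, even
    if the chain grown from that member itself fails the cutoff.
    """
    n = len(scores)
    flagged = np.zeros(n, dtype=bool)
    for chain, a in scores:
        if not math.isnan(a) and a > a_gb:
            for m in chain:
                flagged[m] = True
    calls = [ChainGBCall(i, list(chain), a, bool(flagged[i]))
             for i, (chain, a) in enumerate(scores)]
    valid = [c for c in calls if not math.isnan(c.score) or c.in_gb]
    frac = float(np.mean([c.in_gb for c in calls])) if n else float("nan")
    return calls, frac


# --------------------------------------------------------------------------
# margin domain rotation
# --------------------------------------------------------------------------

def margin_domain_rotation(
    rows,
    group_polar: np.ndarray,
    margin_r: tuple[float, float],
    flank_width: float | None = None,
) -> float:
    """Rotation of the row direction across a group of defects, degrees.

    The row orientation is averaged in two flanking polar boxes within
    the radial margin window ``margin_r = (r_lo, r_hi)``, one on each
    angular side of the defect group; the returned value is the angle
    between the two flank orientations.
    """
    g = np.atleast_2d(np.asarray(group_polar, dtype=float))
    th_lo, th_hi = float(g[:, 1].min()), float(g[:, 1].max())
    r_mid = float(g[:, 0].mean())
    if flank_width is None:
        flank_width = max(3.0 * (th_hi - th_lo), 40.0 / r_mid)
    left = PolarBox(margin_r[0], margin_r[1], th_lo - flank_width, th_lo)
    right = PolarBox(margin_r[0], margin_r[1], th_hi, th_hi + flank_width)
    ul = box_row_orientation(rows, left)
    ur = box_row_orientation(rows, right)
    if ul is None or ur is None:
        return float("nan")
    return math.degrees(math.acos(min(1.0, max(-1.0, float(ul @ ur)))))
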