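"""Ground-truthed synthetic UV-cone mosaics on a growing cone frustum.

The generator reproduces the geometric structure of the growing retinal
mosaic: an anisotropic triangular lattice of UV cones whose rows radiate
from the retinal center, growing ring by ring at the rim, with row
insertions (Y-junctions) planted wherever the circumference demands them.

Construction
------------
Rows are represented as angular trajectories ``theta_i(k)`` over
circumferential rings ``k`` (slant radius ``s_k = s_top + k * a_row/2``).
Cones of adjacent rows sit on alternating rings, encoded by a continuous
per-row radial phase ``chi_i``: row ``i`` carries a cone wherever the
continuous ring coordinate ``kappa`` satisfies ``kappa - chi_i(kappa) = 2m``.

Planting a Y-junction at ``(ring k, angle beta)`` inserts a new row between
its angular neighbors and shifts the radial phase of *every* row at angle
greater than ``beta`` by one ring, ramped over ``ramp_rings`` rings.  This
phase jump across the cut line is precisely the displacement field of an
edge dislocation whose Burgers vector is the oblique lattice vector
``(a_row/2, a_col/2)``; the ramp keeps the strain small away from the core
so that the Delaunay triangulation shows exactly one five/seven-coordinated
pair per planted insertion.  Insertions are planted in pairs per ring (with
opposite ramp signs) so the phase field stays single valued around the
sector seam.  A reverse Y-junction (row deletion) is the same surgery with
the row removed instead of created.

Row angular positions are relaxed toward equal spacing by one global
smoothing pass per ring, plus a short burst of local passes around each
fresh insertion so that the crowding stays confined to the defect core.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from conemosaic.lattice import FrustumGeometry, LatticeSpec, frustum_for_rows

__all__ = [
    "GrainBoundaryMode",
    "CustomSchedule",
    "MosaicSample",
    "RowTraces",
    "TimepointPair",
    "build_frustum_mosaic",
    "trace_rows",
    "make_timepoint_pair",
    "decorate_full_mosaic",
]


# --------------------------------------------------------------------------
# insertion modes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GrainBoundaryMode:
    """Cluster insertions on ``n_lines`` fixed radial lines.

    ``jitter_rows`` is the angular scatter around each line, in units of the
    inter-row spacing at the insertion radius.
    """

    n_lines: int
    jitter_rows: float = 1.0


@dataclass(frozen=True)
class CustomSchedule:
    """Explicit defect schedule: list of ``(ring, angle_rad, type)``.

    ``type`` is ``"Y"`` (row insertion) or ``"reverseY"`` (row deletion).
    """

    events: Sequence[tuple[int, float, str]]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class RowTraces:
    """Oriented row polylines (center -> periphery) on the flattened plane."""

    polylines: list[np.ndarray]          # each (n_i, 2) float, x/y um
    center: tuple[float, float] = (0.0, 0.0)

    def __len__(self) -> int:
        return len(self.polylines)

    def to_json_dict(self) -> dict:
        return {
            "center": list(self.center),
            "rows": [p.tolist() for p in self.polylines],
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "RowTraces":
        return cls(
            polylines=[np.asarray(r, dtype=float) for r in d["rows"]],
            center=tuple(d.get("center", (0.0, 0.0))),
        )


@dataclass
class DefectTruth:
    ring: int
    s_um: float
    angle_rad: float
    kind: str                 # "Y" | "reverseY"
    gb_label: int | None = None
    row_id: int | None = None

    @property
    def xy(self) -> tuple[float, float]:
        return (self.s_um * math.cos(self.angle_rad),
                self.s_um * math.sin(self.angle_rad))


@dataclass
class MosaicSample:
    """Synthetic UV-cone point set with ground truth.

    ``points`` columns: id, x_um, y_um; polar coordinates and generator
    bookkeeping (row id, radial index) are kept alongside.
    """

    ids: np.ndarray            # (n,) int
    xy: np.ndarray             # (n, 2) float um
    s: np.ndarray              # (n,) slant radius um
    phi: np.ndarray            # (n,) sector angle rad
    row_id: np.ndarray         # (n,) int
    m_index: np.ndarray        # (n,) int
    defects_truth: list[DefectTruth]
    row_traces: "RowTraces"
    spec: LatticeSpec
    geometry: FrustumGeometry
    seed: int
    schedule: list[tuple] = field(default_factory=list)
    mode: object = "uniform"
    labels: np.ndarray | None = None   # optional subtype labels

    @property
    def n_points(self) -> int:
        return len(self.ids)

    @property
    def center(self) -> tuple[float, float]:
        return (0.0, 0.0)


@dataclass
class TimepointPair:
    """Two-timepoint observation of a growing mosaic patch.

    Shared cones keep their ids between ``points_t0`` and ``points_t1``;
    cones added by growth get fresh ids.  The rigid transform applied to the
    second timepoint and the positional jitter are stored so they can be
    recovered by registration.
    """

    sample_t0: MosaicSample
    ids_t1: np.ndarray
    xy_t1: np.ndarray
    truth_map: dict[int, int]          # t0 id -> t1 id (identity on shared)
    rotation_rad: float
    translation_um: tuple[float, float]
    jitter_um: float
    glide_events: list[tuple[int, int]]
    n_new_columns: int
    sample_t1: MosaicSample | None = None


# --------------------------------------------------------------------------
# growth engine
# --------------------------------------------------------------------------

class _Row:
    __slots__ = ("rid", "created", "ended", "theta", "chi", "chi0", "target",
                 "rate")

    def __init__(self, rid: int, created: int, theta0: float, chi0: float):
        self.rid = rid
        self.created = created
        self.ended: int | None = None
        self.theta: list[float] = []    # snapshots from ring `created`
        self.chi: list[float] = []
        self.chi0 = chi0                # radial phase at creation
        self.target = chi0              # phase the row is ramping toward
        self.rate = 0.0                 # current max phase step per ring


class _Grower:
    """Ring-by-ring growth of the row configuration."""

    def __init__(self, spec: LatticeSpec, geom: FrustumGeometry, rng: np.random.Generator,
                 mode, ramp_rings: int, smoothing: float,
                 core_relax_iters: int, core_relax_halfwidth: int,
                 tilt_max_deg: float = 12.0):
        self.spec = spec
        self.geom = geom
        self.rng = rng
        self.mode = mode
        self.w = ramp_rings
        self.lam = smoothing
        self.relax_iters = core_relax_iters
        self.relax_hw = core_relax_halfwidth
        self.tilt_max_deg = tilt_max_deg
        self.alpha = geom.sector_angle
        self.rows: list[_Row] = []
        self.order: list[int] = []       # row ids sorted by angle
        self.angle: dict[int, float] = {}
        self.chi_cur: dict[int, float] = {}
        self.truth: list[DefectTruth] = []
        self.windows: list[dict] = []
        self._placed: list[tuple[float, float]] = []
        self.min_separation_um = 3.0 * spec.a_col
        self.schedule: list[tuple] = []
        self._pending_deficit = 0.0
        self._gb_line_cycle = 0

        n0 = geom.n_initial_rows
        if n0 % 2 != 0:
            raise ValueError("n_initial_rows must be even (rings hold alternating rows)")
        alpha_eff = self.alpha if self.alpha > 0 else 2.0 * math.pi
        for i in range(n0):
            th = (i + 0.5) * alpha_eff / n0
            r = _Row(i, 0, th, float(i % 2))
            self.rows.append(r)
            self.order.append(i)
            self.angle[i] = th
            self.chi_cur[i] = float(i % 2)

    # -- geometry helpers --------------------------------------------------

    def s_at(self, k: float) -> float:
        return self.geom.s_top + k * self.spec.ring_spacing

    def _alpha_eff(self) -> float:
        return self.alpha if self.alpha > 0 else 2.0 * math.pi

    # -- insertion machinery ----------------------------------------------

    def _neighbors(self, beta: float) -> tuple[int, int, int]:
        """(index in order of left neighbor, left id, right id) for angle beta."""
        a = self._alpha_eff()
        angles = [self.angle[r] for r in self.order]
        beta = beta % a
        pos = bisect.bisect_left(angles, beta)
        left = (pos - 1) % len(self.order)
        right = pos % len(self.order)
        return left, self.order[left], self.order[right]

    def _register_flip(self, beta: float, sign: int | None, exclude: set[int]) -> int:
        """Flip every row beyond the cut; return the ramp sign used.

        When ``sign`` is None it is chosen to pull the affected rows'
        radial phase back toward its creation value, so that overlapping
        flips perform a bounded oscillation rather than a random walk.
        """
        a = self._alpha_eff()
        beta = beta % a
        affected = [rid for rid in self.order
                    if rid not in exclude and self.angle[rid] > beta]
        if sign is None:
            drift = sum(self.rows[rid].target - self.rows[rid].chi0
                        for rid in affected)
            sign = 1 if (not affected or drift <= 0.0) else -1
        # The displacement jump is sharp at the core and spreads with
        # angular distance from the cut anchor: nearby rows complete their
        # flip within ~2 rings, distant rows within ~w rings.
        pos = {r: i for i, r in enumerate(self.order)}
        n = len(self.order)
        for rid in affected:
            self.rows[rid].target += sign
        if affected:
            first = min(pos[r] for r in affected)
            for rid in affected:
                row = self.rows[rid]
                d = min(abs(pos[rid] - first), n - abs(pos[rid] - first))
                row.rate = max(row.rate, 1.0 / max(2.0, min(float(self.w), 1.0 + d)))
        return sign

    def _insert_row(self, k: int, beta: float, sign: int, gb_label: int | None) -> int:
        a = self._alpha_eff()
        beta = beta % a
        li, lid, rid_ = self._neighbors(beta)
        th_l, th_r = self.angle[lid], self.angle[rid_]
        span = (th_r - th_l) % a
        new_theta = (th_l + span / 2.0) % a
        new_id = len(self.rows)
        row = _Row(new_id, k, new_theta, self.chi_cur[lid] + 1.0)
        self.rows.append(row)
        self.chi_cur[new_id] = self.chi_cur[lid] + 1.0
        # inherit the left neighbor's pending phase motion so the pair
        # stays coherent through older cut lines
        row.target = row.chi0 + (self.rows[lid].target - self.chi_cur[lid])
        self.angle[new_id] = new_theta
        # keep order sorted
        angles = [self.angle[r] for r in self.order]
        pos = bisect.bisect_left(angles, new_theta)
        self.order.insert(pos, new_id)
        # flip every row beyond the cut (anchored at the new row's own angle,
        # so the left neighbor whose phase seeded the new row never flips)
        used = self._register_flip(new_theta, sign, exclude={new_id})
        self.truth.append(DefectTruth(k, self.s_at(k), new_theta, "Y", gb_label,
                                      row_id=new_id))
        self.schedule.append((k, beta, "Y", gb_label, used))
        return new_id

    def _delete_row(self, k: int, beta: float, sign: int) -> None:
        a = self._alpha_eff()
        beta = beta % a
        # remove the row nearest to beta
        best = min(self.order, key=lambda r: abs((self.angle[r] - beta + a / 2) % a - a / 2))
        self.rows[best].ended = k
        pos = self.order.index(best)
        self.order.pop(pos)
        del self.angle[best]
        used = self._register_flip(beta, sign, exclude=set())
        self.truth.append(DefectTruth(k, self.s_at(k), beta, "reverseY", None))
        self.schedule.append((k, beta, "reverseY", None, used))

    def _choose_angles(self, k: int, n_ins: int) -> list[tuple[float, int | None]]:
        a = self._alpha_eff()
        out: list[tuple[float, int | None]] = []
        if isinstance(self.mode, GrainBoundaryMode):
            nl = self.mode.n_lines
            if nl <= 0:
                raise ValueError("grain_boundaries mode needs n_lines >= 1 "
                                 "when insertions are required")
            lines = [(j + 0.5) * a / nl for j in range(nl)]
            s_k = self.s_at(k)
            sig = self.mode.jitter_rows * self.spec.inter_row / s_k
            for _ in range(n_ins):
                j = self._gb_line_cycle % nl
                self._gb_line_cycle += 1
                out.append(((lines[j] + sig * self.rng.standard_normal()) % a, j))
        else:  # uniform with a small hard core so planted cores never merge
            s_k = self.s_at(k)
            dmin = self.min_separation_um
            for _ in range(n_ins):
                best, best_d = None, -1.0
                for _attempt in range(60):
                    b = float(self.rng.uniform(0.0, a))
                    d = min(
                        (math.hypot(s_k - sp,
                                    ((b - bp + a / 2) % a - a / 2) * s_k)
                         for sp, bp in self._placed[-400:]),
                        default=math.inf,
                    )
                    if d >= dmin:
                        best = b
                        break
                    if d > best_d:
                        best, best_d = b, d
                self._placed.append((s_k, best))
                out.append((best, None))
        return out

    # -- relaxation --------------------------------------------------------

    def _smooth_global(self, k: int) -> None:
        """Relax row angles toward equal spacing, at a bounded tilt rate.

        The target is the fully equalized configuration (the long-ranged
        elastic response to an insertion: displacements decay with angular
        distance from the new row).  Tissue already laid down never moves,
        so each new ring only steps toward that target; the step is capped
        at an angular rate corresponding to a maximum row tilt of
        ``tilt_max_deg`` away from radial.  Near a fresh core the rows
        reach equal spacing within a few rings; far away the drift is
        gentle.  The residual tilt field is what the grain-boundary
        detectors measure.
        """
        a = self._alpha_eff()
        n = len(self.order)
        if n < 3:
            return
        base = a / n
        th = np.array([self.angle[r] for r in self.order])
        resid = th - base * np.arange(n)
        # global offset is defined modulo one row spacing; circular mean
        ang = 2.0 * math.pi * resid / base
        off = math.atan2(np.mean(np.sin(ang)),
                         np.mean(np.cos(ang))) * base / (2.0 * math.pi)
        eq = base * np.arange(n) + off
        delta = (eq - th + a / 2.0) % a - a / 2.0
        s_k = self.s_at(k)
        dmax = math.tan(math.radians(self.tilt_max_deg)) \
            * self.spec.ring_spacing / s_k
        th = np.mod(th + np.clip(self.lam * delta, -dmax, dmax), a)
        for rid, t in zip(self.order, th):
            self.angle[rid] = float(t)
        self.order.sort(key=lambda r: self.angle[r])

    def _smooth_local(self, centers: list[int]) -> None:
        """Queue a local re-spacing window around each fresh insertion.

        Dislocation far fields screen each other at the mean defect
        spacing, so the angular room for a new row is taken from its
        ``relax_hw`` neighbors on each side.  The window is re-spaced
        evenly between its (fixed) outer boundary rows *gradually*, over
        the same number of rings as the radial phase ramp, so the angular
        and radial parts of the defect displacement field stay in step.
        """
        if not centers or self.relax_hw <= 0:
            return
        for c in centers:
            if c not in self.angle:
                continue
            n = len(self.order)
            hw = min(self.relax_hw, (n - 2) // 2)
            ci = self.order.index(c)
            rows = [self.order[(ci + d) % n] for d in range(-hw, hw + 1)]
            self.windows.append({"rows": rows, "steps": self.w})

    def _advance_windows(self) -> None:
        a = self._alpha_eff()
        for win in self.windows:
            rows = [r for r in win["rows"] if r in self.angle]
            if len(rows) < 3:
                win["steps"] = 0
                continue
            th = np.unwrap(np.array([self.angle[r] for r in rows]), period=a)
            target = np.linspace(th[0], th[-1], len(th))
            frac = 1.0 / win["steps"]
            for r, cur, tgt in zip(rows[1:-1], th[1:-1], target[1:-1]):
                self.angle[r] = float(np.mod(cur + frac * (tgt - cur), a))
            win["steps"] -= 1
        self.windows = [w for w in self.windows if w["steps"] > 0]
        self.order.sort(key=lambda r: self.angle[r])

    # -- phase update ------------------------------------------------------

    def _advance_phases(self) -> None:
        """Advance each row's radial phase toward its flip target.

        The phase moves at a maximum rate of ``1/w`` per ring, so the
        radial strain carried by a ramp never exceeds ``1/w`` no matter how
        many flips are queued; opposite flips cancel through the target.
        """
        base = 1.0 / self.w
        for row in self.rows:
            if row.ended is not None:
                continue
            cur = self.chi_cur[row.rid]
            d = row.target - cur
            if d != 0.0:
                cap = max(base, row.rate)
                self.chi_cur[row.rid] = cur + max(-cap, min(cap, d))
            else:
                row.rate = 0.0

    # -- main loop ---------------------------------------------------------

    def run(self, custom: CustomSchedule | None = None) -> None:
        geom = self.geom
        self._snapshot(0)
        for k in range(1, geom.n_columns + 1):
            inserted_ids: list[int] = []
            # the leading ramp sign alternates per ring so the radial phase
            # of rows between the two per-ring cuts performs a bounded
            # oscillation instead of a systematic drift
            ring_sign = 1 if k % 2 == 0 else -1
            if custom is not None:
                events = [ev[1:] + (None,) * (4 - len(ev)) for ev in custom.events
                          if ev[0] == k]
                for ang, typ, sign in sorted(ev[:3] for ev in events):
                    if typ == "Y":
                        inserted_ids.append(self._insert_row(k, ang, sign, None))
                    elif typ == "reverseY":
                        self._delete_row(k, ang, sign)
                    else:
                        raise ValueError(f"unknown event type {typ!r}")
            elif self.alpha > 0:
                target = math.floor(self.alpha * self.s_at(k) / self.spec.inter_row + 0.5)
                deficit = target - len(self.order) + self._pending_deficit
                n_ins = int(deficit) - (int(deficit) % 2)
                self._pending_deficit = deficit - n_ins
                if n_ins > 0:
                    choices = self._choose_angles(k, n_ins)
                    for ang, lab in sorted(choices):
                        inserted_ids.append(self._insert_row(k, ang, None, lab))
            self._smooth_local(inserted_ids)
            self._advance_windows()
            self._smooth_global(k)
            self._advance_phases()
            self._snapshot(k)

    def _snapshot(self, k: int) -> None:
        for row in self.rows:
            if row.created <= k and (row.ended is None or k < row.ended):
                row.theta.append(self.angle[row.rid])
                row.chi.append(self.chi_cur[row.rid])


# --------------------------------------------------------------------------
# cone placement
# --------------------------------------------------------------------------

def _cones_for_row(row: _Row, spec: LatticeSpec, geom: FrustumGeometry,
                   n_rings: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (s, phi, m) of the cones on one row.

    Cones sit where the continuous ring coordinate kappa satisfies
    ``kappa - chi(kappa) = 2m``.  chi varies slowly (|dchi/dkappa| < 1), so
    ``g = kappa - chi`` is monotonic and each even integer is crossed once.
    """
    k0 = row.created
    kk = np.arange(k0, k0 + len(row.theta), dtype=float)
    if len(kk) < 2:
        return np.empty(0), np.empty(0), np.empty(0, dtype=int)
    chi = np.asarray(row.chi)
    theta = np.unwrap(np.asarray(row.theta), period=(geom.sector_angle or 2 * math.pi))
    g = kk - chi
    m_lo = math.ceil(g[0] / 2.0 - 1e-9)
    m_hi = math.floor(g[-1] / 2.0 + 1e-9)
    if m_hi < m_lo:
        return np.empty(0), np.empty(0), np.empty(0, dtype=int)
    targets = 2.0 * np.arange(m_lo, m_hi + 1)
    kap = np.interp(targets, g, kk)
    phi = np.interp(kap, kk, theta)
    s = geom.s_top + kap * spec.ring_spacing
    return s, phi, np.arange(m_lo, m_hi + 1)


def _anneal(s: np.ndarray, phi: np.ndarray, spec: LatticeSpec,
            geom: FrustumGeometry, sweeps: int = 8,
            eta: float = 0.3) -> tuple[np.ndarray, np.ndarray]:
    """Spring relaxation of cone positions in the isotropy-restoring metric.

    Every triangulation bond is a unit-rest-length spring in coordinates
    where the six lattice neighbors are equidistant (radial / a_row,
    tangential arc * sqrt(3) / a_col).  A few explicit-Euler sweeps let
    tight dislocation dipoles left by colliding insertion strain fields
    annihilate; planted dislocations carry topological charge and survive.
    The innermost and outermost two rings are held fixed.
    """
    from conemosaic.defects import triangulate

    alpha = geom.sector_angle
    s = s.copy()
    phi = phi.copy()
    scale_t = math.sqrt(3.0) / spec.a_col
    lo = s.min() + 2.0 * spec.ring_spacing
    hi = s.max() - 2.0 * spec.ring_spacing
    free = (s > lo) & (s < hi)
    for _ in range(sweeps):
        xy = np.column_stack([s * np.cos(phi), s * np.sin(phi)])
        tri = triangulate(xy, wrap=("angle", alpha), spec=spec,
                          center=(0.0, 0.0))
        if not tri.edges:
            break
        e = np.array(sorted(tri.edges))
        i, j = e[:, 0], e[:, 1]
        dphi = (phi[j] - phi[i] + alpha / 2.0) % alpha - alpha / 2.0
        sm = 0.5 * (s[i] + s[j])
        dx = dphi * sm * scale_t
        dy = (s[j] - s[i]) / spec.a_row
        ell = np.hypot(dx, dy)
        ell = np.where(ell < 1e-9, 1e-9, ell)
        # unit rest length springs
        fmag = (ell - 1.0) / ell
        fx = fmag * dx
        fy = fmag * dy
        gx = np.zeros_like(s)
        gy = np.zeros_like(s)
        np.add.at(gx, i, fx)
        np.add.at(gx, j, -fx)
        np.add.at(gy, i, fy)
        np.add.at(gy, j, -fy)
        deg = np.zeros_like(s)
        np.add.at(deg, i, 1.0)
        np.add.at(deg, j, 1.0)
        deg = np.where(deg < 1.0, 1.0, deg)
        step_x = eta * gx / deg
        step_y = eta * gy / deg
        phi[free] = phi[free] + (step_x[free] / (s[free] * scale_t))
        s[free] = s[free] + step_y[free] * spec.a_row
    return s, phi


# --------------------------------------------------------------------------
# public API
# --------------------------------------------------------------------------

def build_frustum_mosaic(
    spec: LatticeSpec,
    n_initial_rows: int,
    n_columns: int,
    insertion_mode: str | GrainBoundaryMode | CustomSchedule = "uniform",
    seed: int = 0,
    *,
    sector_angle: float | None = None,
    jitter_um: float = 0.0,
    ramp_rings: int = 4,
    smoothing: float = 0.15,
    core_relax_iters: int = 0,
    core_relax_halfwidth: int = 8,
    tilt_max_deg: float = 12.0,
    anneal_sweeps: int = 0,
) -> MosaicSample:
    """Grow a synthetic UV-cone mosaic on a flattened cone frustum.

    Parameters
    ----------
    spec
        Lattice spacings.
    n_initial_rows
        Rows at the innermost ring (must be even); the retina has ~200.
    n_columns
        Number of circumferential rings added during growth.
    insertion_mode
        ``"uniform"`` (default), a :class:`GrainBoundaryMode`, or a
        :class:`CustomSchedule`.  With the canonical opening angle
        ``2*a_col/a_row`` two rows are inserted per added ring.
    sector_angle
        Override the opening angle (``0`` gives a defect-free cylinder-like
        strip with constant row count).
    jitter_um
        Isotropic Gaussian positional noise added to every cone.
    anneal_sweeps
        Number of post-generation spring-relaxation sweeps in the
        isotropy-restoring metric.  Colliding insertion strain fields can
        leave tight dislocation dipoles (net Burgers content zero) in the
        raw kinematic construction; a few relaxation sweeps let them
        annihilate while the planted defects, which carry topological
        charge, are untouched.
    """
    rng = np.random.default_rng(seed)
    geom = frustum_for_rows(spec, n_initial_rows, n_columns, sector_angle)
    custom = insertion_mode if isinstance(insertion_mode, CustomSchedule) else None
    if isinstance(insertion_mode, GrainBoundaryMode) and insertion_mode.n_lines == 0:
        raise ValueError("grain_boundaries mode with n_lines=0 cannot place insertions")
    grower = _Grower(spec, geom, rng, insertion_mode, ramp_rings, smoothing,
                     core_relax_iters, core_relax_halfwidth, tilt_max_deg)
    grower.run(custom)

    cylinder = geom.sector_angle == 0.0
    ids, ss, phis, rids, ms = [], [], [], [], []
    next_id = 0
    for row in grower.rows:
        s, phi, m = _cones_for_row(row, spec, geom, geom.n_columns)
        if len(s) == 0:
            continue
        for j in range(len(s)):
            ids.append(next_id)
            next_id += 1
        ss.append(s); phis.append(phi)
        rids.append(np.full(len(s), row.rid)); ms.append(m)

    s_all = np.concatenate(ss)
    phi_all = np.concatenate(phis)
    row_all = np.concatenate(rids).astype(int)

    if anneal_sweeps > 0 and not cylinder and len(grower.truth) > 0:
        s_all, phi_all = _anneal(s_all, phi_all, spec, geom, sweeps=anneal_sweeps)

    if cylinder:
        # degenerate frustum: unroll onto a flat periodic strip
        # (s_top stores the circumference)
        x = phi_all * geom.s_top / (2.0 * math.pi)
        y = s_all - geom.s_top
    else:
        x = s_all * np.cos(phi_all)
        y = s_all * np.sin(phi_all)
    xy = np.column_stack([x, y])
    if jitter_um > 0:
        xy = xy + rng.normal(0.0, jitter_um, size=xy.shape)

    # snap insertion ground truth to the created row's innermost cone
    # (the core drifts with its row during relaxation)
    for d in grower.truth:
        if d.kind == "Y" and d.row_id is not None:
            sel = np.nonzero(row_all == d.row_id)[0]
            if len(sel):
                i0 = sel[np.argmin(s_all[sel])]
                d.s_um = float(s_all[i0])
                d.angle_rad = float(phi_all[i0])

    # row traces from the (annealed) cone positions, ordered center->rim
    polylines = []
    for row in grower.rows:
        sel = np.nonzero(row_all == row.rid)[0]
        if len(sel) < 2:
            continue
        sel = sel[np.argsort(s_all[sel])]
        polylines.append(xy[sel])
    traces = RowTraces(polylines, center=(0.0, 0.0))
    return MosaicSample(
        ids=np.asarray(ids, dtype=int),
        xy=xy,
        s=s_all,
        phi=np.mod(phi_all, grower._alpha_eff()),
        row_id=row_all,
        m_index=np.concatenate(ms).astype(int),
        defects_truth=grower.truth,
        row_traces=traces,
        spec=spec,
        geometry=geom,
        seed=seed,
        schedule=grower.schedule,
        mode=insertion_mode,
    )


def trace_rows(sample: MosaicSample) -> RowTraces:
    """Row polylines of a sample, one per row, oriented center -> periphery."""
    return sample.row_traces


def make_timepoint_pair(
    sample: MosaicSample,
    n_new_columns: int = 8,
    glide_events: Sequence[tuple[int, int]] = (),
    rigid_transform: tuple[float, tuple[float, float]] = (0.0, (0.0, 0.0)),
    jitter_um: float = 0.0,
    seed: int = 0,
) -> TimepointPair:
    """Grow a sample by ``n_new_columns`` rings into a second timepoint.

    ``glide_events`` is a list of ``(defect_index, signed_rows)``: planted
    insertion number ``defect_index`` (index into ``sample.defects_truth``)
    glides by the given number of rows between the timepoints.  The second
    timepoint is rotated/translated by ``rigid_transform = (rot_rad, (tx, ty))``
    and jittered with isotropic Gaussian noise of ``jitter_um``.
    """
    from scipy.spatial import cKDTree

    rng = np.random.default_rng(seed)
    spec, geom = sample.spec, sample.geometry

    # regrow with the same seed: the insertion stream is consumed per ring,
    # so the t0 schedule is reproduced exactly and extended
    grown = build_frustum_mosaic(
        spec, geom.n_initial_rows, geom.n_columns + n_new_columns,
        insertion_mode=_mode_like(sample), seed=sample.seed,
        sector_angle=geom.sector_angle if geom.sector_angle > 0 else 0.0,
    )

    if glide_events:
        # a glide step moves the insertion event one ring radially and one
        # row along the defect's own glide line; the angular sense depends
        # on the planted Burgers orientation, so both senses are built and
        # the one realizing a decisive bond flip at the core is kept
        sched = list(grown.schedule)
        for defect_index, rows_moved in glide_events:
            if rows_moved == 0:
                continue
            if rows_moved < 0:
                raise ValueError(
                    "only outward (positive) glide events are realizable "
                    "by the schedule surgery; see the methods note")
            k, beta, typ, lab, sign = sched[defect_index]
            s_k = geom.s_top + k * spec.ring_spacing
            truth_pos = np.array(grown.defects_truth[defect_index].xy)
            best = None
            for dphi_dir in (1.0, -1.0):
                cand = list(sched)
                beta2 = beta + dphi_dir * rows_moved * spec.inter_row / s_k
                cand[defect_index] = (k + rows_moved, beta2, typ, lab, sign)
                t1c = build_frustum_mosaic(
                    spec, geom.n_initial_rows, geom.n_columns + n_new_columns,
                    insertion_mode=CustomSchedule(
                        [(kk, bb, tt, sg) for kk, bb, tt, _, sg in cand]),
                    seed=sample.seed,
                    sector_angle=geom.sector_angle if geom.sector_angle > 0
                    else 0.0,
                )
                score = _glide_flip_margin(grown, t1c, truth_pos, spec,
                                           geom.sector_angle)
                if best is None or score > best[0]:
                    best = (score, cand)
            if best[0] < 20.0:
                raise ValueError(
                    f"defect {defect_index}: the local lattice registry "
                    "does not realize a clean single-bond-flip glide for "
                    "this insertion; plant the glide on a different defect")
            sched = best[1]
        t1 = build_frustum_mosaic(
            spec, geom.n_initial_rows, geom.n_columns + n_new_columns,
            insertion_mode=CustomSchedule(
                [(k, b, t, sg) for k, b, t, _, sg in sched]),
            seed=sample.seed,
            sector_angle=geom.sector_angle if geom.sector_angle > 0 else 0.0,
        )
    else:
        t1 = grown

    # positional correspondence t0 -> t1 (noiseless frames)
    tree = cKDTree(t1.xy)
    d, j = tree.query(sample.xy, k=1)
    ok = d < 0.45 * spec.oblique
    truth_map: dict[int, int] = {}
    # re-number t1 so shared points keep their t0 ids; ties (two t0 cones
    # nearest the same t1 cone, possible right at a relocated core) go to
    # the closer one
    remap = np.full(t1.n_points, -1, dtype=int)
    order = np.argsort(d)
    for i0 in order:
        if not ok[i0] or remap[j[i0]] >= 0:
            continue
        remap[j[i0]] = sample.ids[i0]
        truth_map[int(sample.ids[i0])] = int(sample.ids[i0])
    next_id = int(sample.ids.max()) + 1 if sample.n_points else 0
    for i1 in range(t1.n_points):
        if remap[i1] < 0:
            remap[i1] = next_id
            next_id += 1
    ids_t1 = remap

    rot, (tx, ty) = rigid_transform
    c, s_ = math.cos(rot), math.sin(rot)
    R = np.array([[c, -s_], [s_, c]])
    xy1 = t1.xy @ R.T + np.array([tx, ty])
    if jitter_um > 0:
        xy1 = xy1 + rng.normal(0.0, jitter_um, size=xy1.shape)

    return TimepointPair(
        sample_t0=sample,
        ids_t1=ids_t1,
        xy_t1=xy1,
        truth_map=truth_map,
        rotation_rad=rot,
        translation_um=(tx, ty),
        jitter_um=jitter_um,
        glide_events=list(glide_events),
        n_new_columns=n_new_columns,
        sample_t1=t1,
    )


def _glide_flip_margin(t0: MosaicSample, t1: MosaicSample, pos: np.ndarray,
                       spec: LatticeSpec, alpha: float) -> float:
    """Best decisive-flip margin near ``pos`` between two noiseless samples."""
    from scipy.spatial import cKDTree

    from conemosaic.defects import (_flip_margin_deg, _segments_cross,
                                    triangulate)

    tree = cKDTree(t1.xy)
    d, j = tree.query(t0.xy)
    ok = d < 0.45 * spec.oblique
    xy0 = t0.xy[ok]
    xy1 = t1.xy[j[ok]]
    keep = np.ones(len(xy1), dtype=bool)
    _u, first = np.unique(j[ok], return_index=True)
    mask = np.zeros(len(xy1), dtype=bool)
    mask[first] = True
    xy0, xy1 = xy0[mask], xy1[mask]
    wrap = ("angle", alpha) if alpha > 0 else None
    anchor = float(np.hypot(xy0[:, 0], xy0[:, 1]).min())
    tri0 = triangulate(xy0, wrap=wrap, spec=spec, center=(0.0, 0.0),
                       band_anchor=anchor)
    tri1 = triangulate(xy1, wrap=wrap, spec=spec, center=(0.0, 0.0),
                       band_anchor=anchor)
    rad = 3.0 * spec.a_col
    near = lambda e, xy: (  # noqa: E731
        np.linalg.norm(0.5 * (xy[e[0]] + xy[e[1]]) - pos) < rad)
    gone = [e for e in tri0.edges - tri1.edges if near(e, xy0)]
    new = [e for e in tri1.edges - tri0.edges if near(e, xy0)]
    best = -1e9
    for eg in gone:
        for en in new:
            if _segments_cross(xy0[eg[0]], xy0[eg[1]],
                               xy0[en[0]], xy0[en[1]]):
                best = max(best, _flip_margin_deg(xy1, eg, en, spec))
    return best


def _mode_like(sample: MosaicSample):
    """Insertion mode for deterministic regrowth.

    The per-ring rng stream makes the original events a prefix of the
    regrown schedule for the stochastic modes; custom schedules replay as is.
    """
    return sample.mode


# --------------------------------------------------------------------------
# full-mosaic decoration
# --------------------------------------------------------------------------

def decorate_full_mosaic(sample: MosaicSample, core_style: str = "shuffle") -> dict[str, np.ndarray]:
    """Decorate a UV sample with the full cone-mosaic unit cell.

    Each unit cell holds one UV, one Blue, two Green and two Red cones.
    The Blue sublattice is the UV sublattice translated by half a row
    spacing along the local row (radial) direction; the Red and Green
    sublattices are anisotropic honeycombs with two sites per unit cell.

    The arrangement of the honeycomb sublattices in a dislocation core is
    variable in real retinae; ``core_style`` selects which of the two
    canonical core structures the decoration realizes:

    * ``"shuffle"`` places the honeycomb sites a quarter column spacing on
      either side of the anchor sublattice, which turns a dislocation core
      into a single octagon enclosing two anchor cones;
    * ``"glide"`` builds the honeycombs as the duals (triangle centers) of
      the anchor triangulations, which turns the five/seven-coordinated
      pair into a pentagon-heptagon face pair.

    Returns a dict with keys ``UV``, ``B``, ``G``, ``R`` of (n, 2) arrays.
    """
    if core_style not in ("glide", "shuffle"):
        raise ValueError("core_style must be 'glide' or 'shuffle'")
    spec = sample.spec
    phi = sample.phi
    rhat = np.column_stack([np.cos(phi), np.sin(phi)])
    that = np.column_stack([-np.sin(phi), np.cos(phi)])
    uv = sample.xy
    blue = uv + 0.5 * spec.a_row * rhat
    if core_style == "shuffle":
        green = np.vstack([uv + 0.25 * spec.a_col * that,
                           uv - 0.25 * spec.a_col * that])
        red = np.vstack([blue + 0.25 * spec.a_col * that,
                         blue - 0.25 * spec.a_col * that])
    else:
        alpha = sample.geometry.sector_angle
        wrap = ("angle", alpha) if alpha > 0 else None
        green = _dual_centroids(uv, wrap)
        red = _dual_centroids(blue, wrap)
    return {"UV": uv, "B": blue, "G": green, "R": red}


def _dual_centroids(pts: np.ndarray, wrap) -> np.ndarray:
    """Triangle centers of the Delaunay triangulation (honeycomb dual)."""
    from scipy.spatial import Delaunay

    n = len(pts)
    if wrap is not None:
        a = wrap[1]
        ghosts = [pts]
        for sgn in (-1.0, 1.0):
            R = np.array([[math.cos(sgn * a), -math.sin(sgn * a)],
                          [math.sin(sgn * a), math.cos(sgn * a)]])
            ghosts.append(pts @ R.T)
        allp = np.vstack(ghosts)
    else:
        allp = pts
    dt = Delaunay(allp)
    cents = []
    for simp in dt.simplices:
        if np.any(simp < n):
            cents.append(allp[simp].mean(axis=0))
    cents = np.asarray(cents)
    # deduplicate centroids contributed twice through ghost copies
    key = np.round(cents / 0.5).astype(int)
    _uniq, idx = np.unique(key, axis=0, return_index=True)
    return cents[np.sort(idx)]
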