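"""Anisotropic phase-field-crystal (PFC) model of cone mosaic growth.

The density-modulation field ``psi`` evolves by conserved relaxation of

    F = integral( psi [R + (1 + L_s)^2] psi / 2 + psi^4 / 4 ),
    dpsi/dt = Lap( [R + (1 + L_s)^2] psi + psi^3 ),

where ``R < 0`` is the undercooling parameter and ``L_s`` the stretched
Laplacian, ``b^2 d_rr``-like along the radial (growth) direction and
``1/b^2`` along the transverse one.  With stretch
``b = sqrt(sqrt(3) a_row / a_col)`` the triangular peak lattice has the
measured column-to-row spacing ratio of about six fifths.

Geometry: a rectangle (axis 0 = x, no-flux; axis 1 = y, periodic) or a
flattened cone frustum (axis 0 = slant radius, no-flux; axis 1 = sector
angle, periodic), both isometric to the plane.  The transverse direction
is handled spectrally, the radial one by conservative finite differences;
time stepping is first-order implicit-explicit (linear part implicit,
``psi^3`` explicit) with fixed ``dt = 0.075``.

Intrinsic lattice scales (wavenumber ~ 1): row spacing along the radial
direction ``a_row_sim = 4 pi b / sqrt(3)``, same-column spacing
``a_col_sim = 4 pi / b``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import ndimage

from conemosaic.lattice import LatticeSpec, make_lattice_spec

__all__ = [
    "PFCParams",
    "PFCGeometry",
    "PFCField",
    "psi0_on_cut",
    "one_mode_phases",
    "dispersion_growth_rate",
    "free_energy",
    "init_field",
    "run_growth",
    "extract_peaks",
    "frustum_geometry",
    "rectangle_geometry",
]

DT_DEFAULT = 0.075


def lattice_scales(b: float) -> tuple[float, float]:
    """(a_row_sim, a_col_sim) of the stretched one-mode triangular lattice."""
    return 4.0 * math.pi * b / math.sqrt(3.0), 4.0 * math.pi / b


# --------------------------------------------------------------------------
# parameters and one-mode theory
# --------------------------------------------------------------------------

def psi0_on_cut(R: float) -> float:
    """Mean field on the scan cut, ``psi0 = -sqrt(-R)/2``.

    The cut runs through the triangular-only region of the phase diagram;
    :func:`one_mode_phases` verifies that for each scanned ``R``.
    """
    if R >= 0:
        raise ValueError("the ordering regime needs R < 0")
    return -math.sqrt(-R) / 2.0


@dataclass(frozen=True)
class PFCParams:
    """Model and discretization parameters.

    ``R`` undercooling (< 0 orders), ``psi0`` conserved mean, ``b``
    anisotropy stretch, ``dt`` time step, ``noise_sigma`` the standard
    deviation of the white-noise mask in the initial condition,
    ``pts_per_col`` / ``pts_per_row`` grid densities per circumferential /
    radial lattice spacing.
    """

    R: float
    psi0: float
    b: float = 1.2038550586559453          # sqrt(sqrt(3) * 10.25 / 12.25)
    dt: float = DT_DEFAULT
    noise_sigma: float = 0.75
    pts_per_col: float = 25.0
    pts_per_row: float = 10.0
    seed: int = 0

    @classmethod
    def on_cut(cls, R: float, **kw) -> "PFCParams":
        return cls(R=R, psi0=psi0_on_cut(R), **kw)


def _f_liquid(R, psi0):
    return 0.5 * (R + 1.0) * psi0 ** 2 + 0.25 * psi0 ** 4


def _f_stripe(R, psi0):
    arg = R + 3.0 * psi0 ** 2
    if arg >= 0:
        return _f_liquid(R, psi0), 0.0
    A2 = -4.0 * arg / 3.0
    f = _f_liquid(R, psi0) + 0.25 * arg * A2 + (3.0 / 32.0) * A2 ** 2
    return f, math.sqrt(A2)


def _f_triangular(R, psi0):
    # minimize f(A) = f_liq + (3/4) c A^2 + (3/2) psi0 A^3 + (45/32) A^4
    c = R + 3.0 * psi0 ** 2
    coeffs = [45.0 / 8.0, 4.5 * psi0, 1.5 * c]   # derivative/A: quadratic
    disc = coeffs[1] ** 2 - 4.0 * coeffs[0] * coeffs[2]
    best = (_f_liquid(R, psi0), 0.0)
    if disc >= 0:
        for sgn in (+1.0, -1.0):
            A = (-coeffs[1] + sgn * math.sqrt(disc)) / (2.0 * coeffs[0])
            f = (_f_liquid(R, psi0) + 0.75 * c * A ** 2
                 + 1.5 * psi0 * A ** 3 + (45.0 / 32.0) * A ** 4)
            if f < best[0]:
                best = (f, A)
    return best


def one_mode_phases(R: float, psi0: float) -> tuple[str, dict]:
    """Lowest-energy one-mode phase: constant, stripe or triangular.

    Returns the label and a dict of the three free-energy densities and
    the optimal amplitudes.
    """
    f_liq = _f_liquid(R, psi0)
    f_str, A_str = _f_stripe(R, psi0)
    f_tri, A_tri = _f_triangular(R, psi0)
    info = {"constant": f_liq, "stripe": f_str, "triangular": f_tri,
            "A_stripe": A_str, "A_triangular": A_tri}
    label = min(("constant", "stripe", "triangular"), key=lambda k: info[k])
    # amplitude zero means the phase degenerates to the constant one
    if label == "stripe" and A_str == 0.0:
        label = "constant"
    if label == "triangular" and A_tri == 0.0:
        label = "constant"
    return label, info


def dispersion_growth_rate(q, R: float, psi0: float, b: float = 1.0,
                           stretched_axis: str = "x") -> float:
    """Linear growth rate of a perturbation ``exp(i q . r)`` about psi0.

    ``omega(q) = -|q|^2 [ R + (1 - q_s^2)^2 + 3 psi0^2 ]`` with the
    stretched wavenumber ``q_s^2 = b^2 qx^2 + qy^2 / b^2`` (x stretched).
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if q.size == 1:
        qx, qy = float(q[0]), 0.0
    else:
        qx, qy = float(q[0]), float(q[1])
    if stretched_axis == "y":
        qx, qy = qy, qx
    q2 = qx * qx + qy * qy
    qs2 = (b * b) * qx * qx + qy * qy / (b * b)
    return -q2 * (R + (1.0 - qs2) ** 2 + 3.0 * psi0 ** 2)


# --------------------------------------------------------------------------
# geometry and discrete operators
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PFCGeometry:
    """Discretized solution domain.

    ``kind`` is "frustum" (polar, axis 0 = slant radius) or "rectangle"
    (axis 0 = x).  Axis 1 is periodic with period ``period`` (sector angle
    or Ly); axis 0 runs from ``r0`` with ``n_r`` points spaced ``dr`` and
    no-flux boundaries.
    """

    kind: str
    r0: float
    dr: float
    n_r: int
    n_t: int
    period: float

    @property
    def r(self) -> np.ndarray:
        return self.r0 + self.dr * np.arange(self.n_r)

    @property
    def weights(self) -> np.ndarray:
        """Area weight of each radial node (per unit angle / length)."""
        if self.kind == "frustum":
            return self.r * self.dr
        return np.full(self.n_r, self.dr)

    @property
    def dt_axis1(self) -> float:
        return self.period / self.n_t


def frustum_geometry(n_initial_rows: int, n_columns: int, b: float,
                     insertions_per_column: float = 2.0,
                     pts_per_col: float = 25.0,
                     pts_per_row: float = 10.0,
                     pad_rings: int = 2) -> PFCGeometry:
    """Cone frustum holding ``n_initial_rows`` rows at the top ring.

    The opening angle is ``insertions_per_column * a_col_sim / a_row_sim``
    so that the stated number of row insertions per added column keeps the
    lattice spacing constant.
    """
    a_row, a_col = lattice_scales(b)
    m0 = n_initial_rows / 2.0             # cones in the first column
    alpha = insertions_per_column * a_col / a_row
    s_top = m0 * a_col / alpha
    n_t = int(round(pts_per_col * m0 / 2.0)) * 2
    dr = a_row / pts_per_row
    span = (n_columns + pad_rings) * (a_row / 2.0) + a_row
    n_r = int(math.ceil(span / dr))
    return PFCGeometry("frustum", s_top - a_row / 2.0, dr, n_r, n_t, alpha)


def rectangle_geometry(n_rows: int, n_columns: int, b: float,
                       pts_per_col: float = 25.0,
                       pts_per_row: float = 10.0) -> PFCGeometry:
    """Flat strip: x grows by columns (no flux), y periodic over the rows."""
    a_row, a_col = lattice_scales(b)
    Ly = (n_rows / 2.0) * a_col
    n_t = int(round(pts_per_col * n_rows / 2.0)) * 2
    dr = a_row / pts_per_row
    span = n_columns * (a_row / 2.0) + 2.0 * a_row
    n_r = int(math.ceil(span / dr))
    return PFCGeometry("rectangle", 0.0, dr, n_r, n_t, Ly)


def _radial_flux_laplacian(geom: PFCGeometry, stretch2: float = 1.0) -> sp.csr_matrix:
    """Conservative radial part ``stretch2 * (1/r) d_r (r d_r)`` (or d_xx).

    Flux form with zero flux at both ends: the discrete r-weighted sum of
    the operator output vanishes identically, which is what conserves the
    mean of the field to solver precision.
    """
    n, dr = geom.n_r, geom.dr
    r = geom.r
    if geom.kind == "frustum":
        r_half_p = r + dr / 2.0
        r_half_m = r - dr / 2.0
    else:
        r_half_p = np.ones(n)
        r_half_m = np.ones(n)
    lo = np.zeros(n - 1)
    di = np.zeros(n)
    up = np.zeros(n - 1)
    denom = (r if geom.kind == "frustum" else np.ones(n)) * dr * dr
    for i in range(n):
        fp = r_half_p[i] if i < n - 1 else 0.0     # no flux out the far end
        fm = r_half_m[i] if i > 0 else 0.0         # no flux at the near end
        di[i] = -(fp + fm) / denom[i]
        if i < n - 1:
            up[i] = fp / denom[i]
        if i > 0:
            lo[i - 1] = fm / denom[i]
    return stretch2 * sp.diags([lo, di, up], [-1, 0, 1], format="csr")


class _Operators:
    """Per-mode banded operators and the implicit-step factorization."""

    def __init__(self, params: PFCParams, geom: PFCGeometry):
        self.params = params
        self.geom = geom
        n_r, n_t = geom.n_r, geom.n_t
        b = params.b
        # transverse wavenumbers of rfft modes
        k = np.arange(n_t // 2 + 1)
        m = 2.0 * math.pi * k / geom.period        # angular mode factor
        if geom.kind == "frustum":
            inv_r2 = 1.0 / geom.r ** 2
        else:
            inv_r2 = np.ones(n_r)
        lap_r = _radial_flux_laplacian(geom, 1.0)
        lap_r_s = _radial_flux_laplacian(geom, b * b)
        eye = sp.identity(n_r, format="csr")

        lap_blocks = []
        lin_blocks = []
        for mk in m:
            ang = sp.diags(-(mk ** 2) * inv_r2)
            D2 = (lap_r + ang).tocsr()                       # plain Laplacian
            S = (lap_r_s + sp.diags(-(mk ** 2) * inv_r2 / (b * b))).tocsr()
            one_plus = (eye + S)
            lin = (D2 @ (params.R * eye + one_plus @ one_plus)).tocsr()
            lap_blocks.append(D2)
            lin_blocks.append(lin)
        self.D2 = sp.block_diag(lap_blocks, format="csr")
        A = sp.block_diag(lin_blocks, format="csc")
        self.n_modes = len(m)
        self.m = m
        ident = sp.identity(A.shape[0], format="csc")
        self.lu = spla.splu((ident - params.dt * A).tocsc())
        self.A = A

    def apply_linear_energy(self, psi: np.ndarray) -> np.ndarray:
        """(1 + L_s)^2 psi + R psi, for the free-energy quadrature."""
        geom = self.geom
        F = np.fft.rfft(psi, axis=1)           # (n_r, n_modes)
        out = np.empty_like(F)
        b = self.params.b
        lap_r_s = _radial_flux_laplacian(geom, b * b)
        eye = sp.identity(geom.n_r, format="csr")
        inv_r2 = 1.0 / geom.r ** 2 if geom.kind == "frustum" else np.ones(geom.n_r)
        for j, mk in enumerate(self.m):
            S = (lap_r_s + sp.diags(-(mk ** 2) * inv_r2 / (b * b))).tocsr()
            one_plus = eye + S
            out[:, j] = one_plus @ (one_plus @ F[:, j]) + self.params.R * F[:, j]
        return np.fft.irfft(out, n=geom.n_t, axis=1)


@dataclass
class PFCField:
    """The density-modulation field and its evolution machinery."""

    psi: np.ndarray                    # (n_r, n_t)
    params: PFCParams
    geometry: PFCGeometry
    step_count: int = 0
    _ops: _Operators | None = field(default=None, repr=False)

    @property
    def ops(self) -> _Operators:
        if self._ops is None:
            self._ops = _Operators(self.params, self.geometry)
        return self._ops

    def mean(self) -> float:
        w = self.geometry.weights
        return float((self.psi.mean(axis=1) * w).sum() / w.sum())

    def step(self, n: int = 1) -> "PFCField":
        """Advance ``n`` implicit-explicit steps (in place)."""
        ops = self.ops
        geom = self.geometry
        dt = self.params.dt
        n_r, n_t, n_m = geom.n_r, geom.n_t, ops.n_modes
        for _ in range(n):
            F = np.fft.rfft(self.psi, axis=1)        # (n_r, n_modes)
            psi3 = self.psi * self.psi * self.psi
            G = np.fft.rfft(psi3, axis=1)
            Ff = np.ascontiguousarray(F.T).ravel()   # mode-major flat
            Gf = np.ascontiguousarray(G.T).ravel()
            rhs = Ff + dt * (ops.D2 @ Gf)
            sol = ops.lu.solve(np.column_stack([rhs.real, rhs.imag]))
            x = sol[:, 0] + 1j * sol[:, 1]
            self.psi = np.fft.irfft(x.reshape(n_m, n_r).T, n=n_t, axis=1)
            self.step_count += 1
        if not np.isfinite(self.psi).all():
            raise FloatingPointError(
                f"PFC field diverged at step {self.step_count}")
        return self

    # -- diagnostics -------------------------------------------------------

    def amplitude_profile(self) -> np.ndarray:
        """Max - min of psi over the transverse direction, per radius."""
        return self.psi.max(axis=1) - self.psi.min(axis=1)

    def front_radius(self, rel_threshold: float = 0.5) -> float:
        """Outermost radius where the modulation exceeds the threshold.

        The threshold is ``rel_threshold`` times the one-mode triangular
        peak-to-trough amplitude for the run's parameters.
        """
        _lab, info = one_mode_phases(self.params.R, self.params.psi0)
        ref = 4.5 * abs(info["A_triangular"])     # ~ peak-to-trough of 3 modes
        amp = self.amplitude_profile()
        above = np.nonzero(amp > rel_threshold * ref)[0]
        if len(above) == 0:
            return self.geometry.r0
        return float(self.geometry.r[above[-1]])


# --------------------------------------------------------------------------
# free energy
# --------------------------------------------------------------------------

def free_energy(fld: PFCField) -> float:
    """Discrete quadrature of the free-energy functional.

    Midpoint rule: the radial nodes are cell centers, with the no-flux
    walls half a step outside the first and last node.
    """
    psi = fld.psi
    lin = fld.ops.apply_linear_energy(psi)
    psi2 = psi * psi
    dens = 0.5 * psi * lin + 0.25 * psi2 * psi2
    w = fld.geometry.weights
    return float((dens.mean(axis=1) * w).sum() * fld.geometry.period)


# --------------------------------------------------------------------------
# initial conditions and growth
# --------------------------------------------------------------------------

def init_field(params: PFCParams, geom: PFCGeometry,
               mode: str = "column_seed", seed: int | None = None) -> PFCField:
    """Uniform ``psi0`` plus the seed column and the white-noise mask.

    ``column_seed`` lays one column of density peaks (the one-mode
    amplitude) along the innermost ring; white noise of standard deviation
    ``noise_sigma`` covers the first two column widths.  ``noise_only``
    skips the seed.  The global mean is re-pinned to ``psi0`` afterwards.
    """
    if mode not in ("column_seed", "noise_only"):
        raise ValueError("mode must be 'column_seed' or 'noise_only'")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n_r, n_t = geom.n_r, geom.n_t
    psi = np.full((n_r, n_t), params.psi0)
    a_row, a_col = lattice_scales(params.b)
    r = geom.r
    label, info = one_mode_phases(params.R, params.psi0)
    if label != "triangular":
        raise ValueError(
            f"(R={params.R}, psi0={params.psi0}) lies outside the "
            f"triangular-only region (one-mode prediction: {label}); "
            "choose parameters on the psi0 = -sqrt(-R)/2 cut")
    A = info["A_triangular"]

    if mode == "column_seed":
        # one ring of peaks: transverse cosine at the cone spacing, radial
        # Gaussian envelope of one ring width
        if geom.kind == "frustum":
            circumference = geom.period * (geom.r0 + a_row / 2.0)
        else:
            circumference = geom.period
        n_peaks = max(int(round(circumference / a_col)), 1)
        th = np.arange(n_t) * (2.0 * math.pi / n_t)
        s_seed = geom.r0 + a_row / 2.0
        envelope = np.exp(-0.5 * ((r - s_seed) / (a_row / 4.0)) ** 2)
        psi += 3.0 * A * envelope[:, None] * np.cos(n_peaks * th)[None, :]

    if params.noise_sigma > 0:
        band = r < geom.r0 + a_row / 2.0 + 2.0 * (a_row / 2.0)
        noise = rng.normal(0.0, params.noise_sigma, size=(band.sum(), n_t))
        psi[band] += noise

    fld = PFCField(psi, params, geom)
    # re-pin the conserved mean
    fld.psi += params.psi0 - fld.mean()
    return fld


def run_growth(params: PFCParams, geom: PFCGeometry,
               mode: str = "column_seed",
               max_steps: int = 200_000,
               check_every: int = 250,
               stop_margin_rings: float = 2.0,
               callback=None) -> PFCField:
    """Grow the crystal until the front reaches the outer boundary.

    The front position is tracked through the modulation envelope; the
    run stops when it comes within ``stop_margin_rings`` rings of the
    outer edge, or at ``max_steps``.
    """
    fld = init_field(params, geom, mode=mode)
    a_row, _ = lattice_scales(params.b)
    target = geom.r[-1] - stop_margin_rings * (a_row / 2.0)
    while fld.step_count < max_steps:
        fld.step(check_every)
        if callback is not None:
            callback(fld)
        if fld.front_radius() >= target:
            break
    return fld


# --------------------------------------------------------------------------
# peak extraction
# --------------------------------------------------------------------------

def extract_peaks(fld: PFCField, rel_threshold: float = 0.3,
                  spec: LatticeSpec | None = None) -> np.ndarray:
    """Density-peak positions, sub-grid refined, in um on the flattened plane.

    Local maxima above ``psi0 + rel_threshold * (max - psi0)`` are found
    with a periodic maximum filter and refined by a one-dimensional
    quadratic fit along each axis.  With ``spec`` given (default: the
    measured retinal spacings) positions are calibrated so that the
    simulated row spacing equals ``spec.a_row``.
    """
    spec = spec or make_lattice_spec()
    psi = fld.psi
    geom = fld.geometry
    a_row_sim, _ = lattice_scales(fld.params.b)
    scale = spec.a_row / a_row_sim

    size_r = max(int(0.25 * a_row_sim / geom.dr), 2)
    size_t = max(int(0.25 * (4.0 * math.pi / fld.params.b)
                     / (geom.period / geom.n_t)
                     / (geom.r.mean() if geom.kind == "frustum" else 1.0)), 2)
    foot = ndimage.maximum_filter(
        psi, size=(2 * size_r + 1, 2 * size_t + 1), mode=("nearest", "wrap"))
    thr = fld.params.psi0 + rel_threshold * (psi.max() - fld.params.psi0)
    is_peak = (psi >= foot - 1e-12) & (psi > thr)
    ri, ti = np.nonzero(is_peak)
    pts = []
    for i, j in zip(ri, ti):
        # quadratic sub-grid refinement
        dr_off = dt_off = 0.0
        if 0 < i < geom.n_r - 1:
            y0, y1, y2 = psi[i - 1, j], psi[i, j], psi[i + 1, j]
            den = y0 - 2 * y1 + y2
            if den < 0:
                dr_off = 0.5 * (y0 - y2) / den
        jm, jp = (j - 1) % geom.n_t, (j + 1) % geom.n_t
        y0, y1, y2 = psi[i, jm], psi[i, j], psi[i, jp]
        den = y0 - 2 * y1 + y2
        if den < 0:
            dt_off = 0.5 * (y0 - y2) / den
        rr = geom.r0 + (i + dr_off) * geom.dr
        tt = (j + dt_off) * (geom.period / geom.n_t)
        if geom.kind == "frustum":
            pts.append((rr * math.cos(tt) * scale, rr * math.sin(tt) * scale))
        else:
            pts.append((rr * scale, tt * scale))
    return np.asarray(pts) if pts else np.empty((0, 2))
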