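import math

import numpy as np
import pytest

from conemosaic import pfc
from conemosaic.lattice import make_lattice_spec


B = make_lattice_spec().pfc_stretch


# -- one-mode theory --------------------------------------------------------

@pytest.mark.parametrize("R,psi0,expected", [
    (-0.25, 0.0, "stripe"),
    (-0.25, -0.25, "triangular"),
    (-0.01, -0.4, "constant"),
])
def test_one_mode_phase_selection(R, psi0, expected):
    label, _info = pfc.one_mode_phases(R, psi0)
    assert label == expected


def test_scan_cut_lies_in_triangular_region():
    for R in (-0.1, -0.15, -0.2, -0.25, -0.3):
        psi0 = pfc.psi0_on_cut(R)
        label, info = pfc.one_mode_phases(R, psi0)
        assert label == "triangular"
        assert info["triangular"] < info["stripe"] - 1e-12
        assert info["triangular"] < info["constant"] - 1e-12


def test_dispersion_neutral_at_zero_and_unstable_on_shell():
    assert pfc.dispersion_growth_rate([0.0, 0.0], -0.25, -0.25) == 0.0
    # on the stretched shell the rate reduces to -q^2 (R + 3 psi0^2)
    q = np.array([1.0 / B, 0.0])
    w = pfc.dispersion_growth_rate(q, -0.25, -0.25, b=B)
    assert w == pytest.approx(-(1 / B ** 2) * (-0.25 + 3 * 0.0625), rel=1e-12)
    assert w > 0
    # stable when R + 3 psi0^2 > 0
    assert pfc.dispersion_growth_rate(q, -0.01, -0.4, b=B) < 0


def test_solver_reproduces_linear_growth_rate():
    """A seeded transverse mode grows at the dispersion-relation rate."""
    R, psi0 = -0.25, -0.25
    # a reduced step isolates the spatial dynamics from the first-order
    # time-splitting error
    params = pfc.PFCParams(R=R, psi0=psi0, b=B, noise_sigma=0.0, dt=0.02)
    geom = pfc.rectangle_geometry(8, 6, B)
    # transverse mode on the periodic axis near the unstable shell
    m = int(round(geom.period * B / (2 * math.pi)))
    qy = 2 * math.pi * m / geom.period
    omega = pfc.dispersion_growth_rate([0.0, qy], R, psi0, b=B)
    assert omega > 0
    psi = np.full((geom.n_r, geom.n_t), psi0)
    th = np.arange(geom.n_t) * 2 * math.pi / geom.n_t
    psi += 1e-5 * np.cos(m * th)[None, :]
    fld = pfc.PFCField(psi, params, geom)
    def amp(f):
        F = np.fft.rfft(f.psi, axis=1)
        return np.abs(F[:, m]).mean()
    a0 = amp(fld)
    n = 1500
    fld.step(n)
    rate = math.log(amp(fld) / a0) / (n * params.dt)
    assert rate == pytest.approx(omega, rel=0.02)


# -- free energy ------------------------------------------------------------

def test_free_energy_of_uniform_state():
    R, psi0 = -0.2, -0.3
    params = pfc.PFCParams(R=R, psi0=psi0, b=B, noise_sigma=0.0)
    geom = pfc.rectangle_geometry(6, 4, B)
    fld = pfc.PFCField(np.full((geom.n_r, geom.n_t), psi0), params, geom)
    area = geom.n_r * geom.dr * geom.period           # midpoint quadrature
    expected = (0.5 * psi0 ** 2 * (R + 1) + 0.25 * psi0 ** 4) * area
    assert pfc.free_energy(fld) == pytest.approx(expected, rel=1e-6)


def _stripe_field(params, geom, m):
    _lab, info = pfc.one_mode_phases(params.R, params.psi0)
    A = info["A_stripe"]
    th = np.arange(geom.n_t) * 2 * math.pi / geom.n_t
    return pfc.PFCField(params.psi0 + A * np.cos(m * th)[None, :].repeat(geom.n_r, 0),
                        params, geom)


def test_one_mode_stripe_energy_matches_analytic():
    R, psi0 = -0.25, 0.0
    params = pfc.PFCParams(R=R, psi0=psi0, b=B, noise_sigma=0.0)
    geom = pfc.rectangle_geometry(6, 4, B)
    # stripe along the periodic axis at the nearest admissible wavenumber
    m = int(round(geom.period * B / (2 * math.pi)))
    fld = _stripe_field(params, geom, m)
    _lab, info = pfc.one_mode_phases(R, psi0)
    area = geom.n_r * geom.dr * geom.period
    assert pfc.free_energy(fld) == pytest.approx(info["stripe"] * area, rel=0.01)


def test_free_energy_quadrature_converges_quadratically():
    # radial stripe commensurate with the no-flux boundaries, energy
    # compared with the closed-form one-mode value at the same wavenumber
    R, psi0 = -0.25, 0.0
    Lx = 30.0
    n_wave = round((1.0 / B) * Lx / math.pi)
    qx = n_wave * math.pi / Lx
    qs2 = (B * qx) ** 2
    c = R + (1.0 - qs2) ** 2
    A2 = -4.0 * c / 3.0
    f_ref = 0.25 * c * A2 + (3.0 / 32.0) * A2 ** 2

    def err(n_r):
        # nodes at cell centers: walls at x = 0 and x = Lx
        dr = Lx / n_r
        geom = pfc.PFCGeometry("rectangle", dr / 2.0, dr, n_r, 64, 40.0)
        params = pfc.PFCParams(R=R, psi0=psi0, b=B, noise_sigma=0.0)
        psi = psi0 + math.sqrt(A2) * np.cos(qx * geom.r)[:, None] \
            .repeat(geom.n_t, 1)
        fld = pfc.PFCField(psi, params, geom)
        area = geom.n_r * geom.dr * geom.period
        return abs(pfc.free_energy(fld) / area - f_ref)

    e1, e2 = err(28), err(56)
    assert e2 < e1 / 3.0


# -- dynamics ---------------------------------------------------------------

def test_uniform_stable_state_is_fixed_point():
    params = pfc.PFCParams(R=-0.01, psi0=-0.4, b=B, noise_sigma=0.0)
    geom = pfc.rectangle_geometry(6, 4, B)
    fld = pfc.PFCField(np.full((geom.n_r, geom.n_t), params.psi0), params, geom)
    fld.step(50)
    assert np.allclose(fld.psi, params.psi0, atol=1e-12)


def test_mean_conserved_to_1e8_over_1000_steps():
    params = pfc.PFCParams.on_cut(-0.25, b=B, seed=3)
    geom = pfc.frustum_geometry(30, 8, B)
    fld = pfc.init_field(params, geom)
    m0 = fld.mean()
    fld.step(1000)
    assert abs(fld.mean() - m0) < 1e-8


def test_relaxed_stripe_amplitude_matches_one_mode():
    R, psi0 = -0.25, 0.0
    params = pfc.PFCParams(R=R, psi0=psi0, b=B, noise_sigma=0.0)
    geom = pfc.rectangle_geometry(8, 5, B)
    m = int(round(geom.period * B / (2 * math.pi)))
    fld = _stripe_field(params, geom, m)
    fld.psi *= 0.5                      # start away from the minimum
    fld.psi += psi0 - fld.mean()
    fld.step(4000)
    amp = 0.5 * (fld.psi.max() - fld.psi.min())
    _lab, info = pfc.one_mode_phases(R, psi0)
    assert amp == pytest.approx(info["A_stripe"], rel=0.05)


def test_free_energy_non_increasing_during_growth():
    params = pfc.PFCParams.on_cut(-0.25, b=B, seed=5)
    geom = pfc.frustum_geometry(30, 10, B)
    fld = pfc.init_field(params, geom)
    energies = []
    for _ in range(6):
        fld.step(150)
        energies.append(pfc.free_energy(fld))
    diffs = np.diff(energies)
    assert np.all(diffs < 1e-6 * np.abs(energies[0]))


def test_invalid_parameters_refused_by_init():
    params = pfc.PFCParams(R=-0.01, psi0=-0.4, b=B)   # constant-only region
    geom = pfc.frustum_geometry(30, 8, B)
    with pytest.raises(ValueError):
        pfc.init_field(params, geom)


# -- peaks ------------------------------------------------------------------

def test_extract_peaks_recovers_analytic_triangular_lattice():
    R, psi0 = -0.25, -0.25
    params = pfc.PFCParams(R=R, psi0=psi0, b=B, noise_sigma=0.0)
    geom = pfc.rectangle_geometry(8, 8, B)
    _lab, info = pfc.one_mode_phases(R, psi0)
    A = info["A_triangular"]
    a_row, a_col = pfc.lattice_scales(B)
    x = geom.r[:, None]
    y = (np.arange(geom.n_t) * geom.period / geom.n_t)[None, :]
    # triad with one wavevector along the periodic axis
    qy = 2 * math.pi / (a_col / 2.0)
    ky = round(qy * geom.period / (2 * math.pi)) * 2 * math.pi / geom.period
    qx = 2 * math.pi / a_row
    psi = psi0 + A * (np.cos(ky * y)
                      + 2.0 * np.cos(qx * x) * np.cos(ky * y / 2.0))
    fld = pfc.PFCField(psi, params, geom)
    spec = make_lattice_spec()
    peaks = pfc.extract_peaks(fld, spec=spec)
    assert len(peaks) > 0
    # peaks sit on the analytic lattice: row spacing equals a_row in um
    xs = np.unique(np.round(peaks[:, 0] / (spec.a_row / 2)))
    from scipy.spatial import cKDTree
    d, _ = cKDTree(peaks).query(peaks, k=2)
    assert np.median(d[:, 1]) == pytest.approx(spec.oblique, rel=0.03)


def test_uniform_field_has_no_peaks():
    params = pfc.PFCParams(R=-0.25, psi0=-0.25, b=B, noise_sigma=0.0)
    geom = pfc.rectangle_geometry(6, 4, B)
    fld = pfc.PFCField(np.full((geom.n_r, geom.n_t), params.psi0), params, geom)
    assert len(pfc.extract_peaks(fld)) == 0


def test_grown_rectangle_has_measured_anisotropy():
    """Column-to-row peak spacing ratio ~ sqrt(3)/b^2 after growth."""
    params = pfc.PFCParams.on_cut(-0.25, b=B, seed=2)
    geom = pfc.rectangle_geometry(16, 14, B)
    fld = pfc.run_growth(params, geom, max_steps=30000)
    spec = make_lattice_spec()
    peaks = pfc.extract_peaks(fld, spec=spec)
    assert len(peaks) > 50
    # row spacing: nearest peak along x; column spacing: nearest along y
    from scipy.spatial import cKDTree
    tree = cKDTree(peaks)
    d, j = tree.query(peaks, k=9)
    drow, dcol = [], []
    for i in range(len(peaks)):
        for dd, jj in zip(d[i, 1:], j[i, 1:]):
            v = peaks[jj] - peaks[i]
            if abs(v[1]) < 0.25 * abs(v[0]):
                drow.append(abs(v[0]))
            if abs(v[0]) < 0.25 * abs(v[1]):
                dcol.append(abs(v[1]))
    ratio = np.median(dcol) / np.median(drow)
    assert ratio == pytest.approx(math.sqrt(3.0) / B ** 2, rel=0.05)


# -- growth phenomenology ---------------------------------------------------

def _row_bond_alignment(b, seed):
    """Mean |cos| between row bonds and the radial direction after a
    noise-only growth run."""
    from conemosaic import grain_boundary as gbm
    from conemosaic.defects import triangulate
    from conemosaic.lattice import LatticeSpec

    spec = make_lattice_spec()
    params = pfc.PFCParams.on_cut(-0.25, b=b, noise_sigma=1.0, seed=seed)
    geom = pfc.frustum_geometry(40, 14, b)
    fld = pfc.run_growth(params, geom, mode="noise_only", max_steps=30000)
    peaks = pfc.extract_peaks(fld)
    ar, ac = pfc.lattice_scales(b)
    sp_eff = LatticeSpec(spec.a_row, ac * spec.a_row / ar)
    tri = triangulate(peaks, wrap=("angle", geom.period), spec=sp_eff,
                      center=(0.0, 0.0))
    field, _deg, _cls = gbm.extract_row_bonds(tri, center=(0.0, 0.0))
    vals = []
    for s0, e0 in zip(field.starts, field.ends):
        v = e0 - s0
        v = v / np.linalg.norm(v)
        mid = 0.5 * (s0 + e0)
        r = mid / np.linalg.norm(mid)
        vals.append(abs(float(v @ r)))
    return float(np.mean(vals))


def test_anisotropy_selects_radial_row_orientation():
    """From pure noise, the stretched free energy locks rows onto the
    radial direction; the isotropic model grows misoriented domains."""
    a_ani = _row_bond_alignment(B, 3)
    a_iso = _row_bond_alignment(1.0, 3)
    assert a_ani > 0.85
    assert a_ani > a_iso + 0.05


def test_growth_front_lags_at_grain_boundaries():
    """The density field near defect-bearing sectors resolves later than
    in neighboring domains (V-shaped growth front)."""
    from conemosaic import grain_boundary as gbm
    from conemosaic.defects import triangulate

    spec = make_lattice_spec()
    params = pfc.PFCParams.on_cut(-0.25, b=B, noise_sigma=1.0, seed=4)
    geom = pfc.frustum_geometry(40, 16, B)
    snaps = []
    fld = pfc.run_growth(params, geom, mode="column_seed", max_steps=30000,
                         callback=lambda f: snaps.append(f.psi.copy()))
    peaks = pfc.extract_peaks(fld)
    tri = triangulate(peaks, wrap=("angle", geom.period), spec=spec,
                      center=(0.0, 0.0))
    _field, _deg, classes = gbm.extract_row_bonds(tri, center=(0.0, 0.0))
    ys = classes["Y"]
    th_y = np.mod(np.arctan2(peaks[ys, 1], peaks[ys, 0]), geom.period)

    mid_psi = snaps[len(snaps) // 2]
    _lab, info = pfc.one_mode_phases(params.R, params.psi0)
    ref = 4.5 * abs(info["A_triangular"])
    nb = 24
    edges = np.linspace(0, geom.period, nb + 1)
    th_grid = (np.arange(geom.n_t) + 0.5) * geom.period / geom.n_t
    fronts = []
    for b0, b1 in zip(edges[:-1], edges[1:]):
        cols = (th_grid >= b0) & (th_grid < b1)
        a = mid_psi[:, cols].max(axis=1) - mid_psi[:, cols].min(axis=1)
        above = np.nonzero(a > 0.5 * ref)[0]
        fronts.append(geom.r[above[-1]] if len(above) else geom.r0)
    fronts = np.array(fronts)
    has_y = np.array([np.any((th_y >= b0) & (th_y < b1))
                      for b0, b1 in zip(edges[:-1], edges[1:])])
    assert 0 < has_y.sum() < nb
    assert fronts[has_y].mean() < fronts[~has_y].mean()
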