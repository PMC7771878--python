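"""End-to-end analysis pipelines shared by the CLI, tests and scripts."""

from __future__ import annotations

import math

import numpy as np

from conemosaic import grain_boundary as gb
from conemosaic import pfc
from conemosaic.defects import triangulate
from conemosaic.lattice import make_lattice_spec

__all__ = ["pfc_gb_fraction", "pfc_grow_and_analyze"]


def pfc_grow_and_analyze(R: float, rows: int, columns: int, seed: int,
                         noise_sigma: float = 0.75,
                         cutoff_deg: float = 12.0,
                         delta_r: float = 35.0,
                         init_mode: str = "column_seed"):
    """Grow one anisotropic PFC crystal and run the primary GB detector.

    Returns ``(fraction, n_y, peaks, calls)``: the in-grain-boundary
    fraction of Y-junction peaks at the given cutoff, the Y count, the
    extracted peak positions (um) and the per-defect calls.
    """
    spec = make_lattice_spec()
    params = pfc.PFCParams.on_cut(R, noise_sigma=noise_sigma, seed=seed)
    geom = pfc.frustum_geometry(rows, columns, params.b)
    fld = pfc.run_growth(params, geom, mode=init_mode)
    peaks = pfc.extract_peaks(fld)
    tri = triangulate(peaks, wrap=("angle", geom.period), spec=spec,
                      center=(0.0, 0.0))
    field, _degree, classes = gb.extract_row_bonds(tri, center=(0.0, 0.0))
    ys = classes["Y"]
    s_pk = np.hypot(peaks[:, 0], peaks[:, 1])
    th = np.mod(np.arctan2(peaks[:, 1], peaks[:, 0]), geom.period)
    dp = np.column_stack([s_pk[ys], th[ys]])
    calls, frac = gb.call_gb_primary(field, dp, delta_r=delta_r,
                                     cutoff_deg=cutoff_deg)
    return frac, len(ys), peaks, calls


def pfc_gb_fraction(R: float, rows: int, columns: int, seed: int,
                    **kw) -> tuple[float, int]:
    frac, n_y, _pk, _calls = pfc_grow_and_analyze(R, rows, columns, seed, **kw)
    return frac, n_y
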