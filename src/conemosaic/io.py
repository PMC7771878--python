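"""File formats: point-set CSV, row-trace / defect / result JSON, field dumps.

Point sets travel as CSV with header ``id,x_um,y_um[,z_um][,label]``;
row traces and analysis results as JSON; gridded PFC fields as a raw
binary array next to a JSON header carrying geometry, parameters, seed
and step count.  Writers embed the lattice spec, geometry and seed so
every artifact can be regenerated.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from conemosaic.lattice import FrustumGeometry, LatticeSpec
from conemosaic.synthetic import DefectTruth, MosaicSample, RowTraces

__all__ = [
    "write_points_csv", "read_points_csv",
    "write_sample", "read_sample",
    "write_traces_json", "read_traces_json",
    "write_defects_json", "read_defects_json",
    "write_field", "read_field",
    "write_json", "read_json",
]


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_coerce))


def read_json(path):
    return json.loads(Path(path).read_text())


def _coerce(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"cannot serialize {type(o)}")


# -- point sets -------------------------------------------------------------

def write_points_csv(path, ids, xy, labels=None, z=None) -> None:
    cols = {"id": np.asarray(ids, dtype=int),
            "x_um": np.asarray(xy)[:, 0], "y_um": np.asarray(xy)[:, 1]}
    if z is not None:
        cols["z_um"] = np.asarray(z)
    if labels is not None:
        cols["label"] = labels
    pd.DataFrame(cols).to_csv(path, index=False)


def read_points_csv(path):
    df = pd.read_csv(path)
    ids = df["id"].to_numpy(dtype=int)
    if "z_um" in df.columns:
        xyz = df[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    else:
        xyz = df[["x_um", "y_um"]].to_numpy(dtype=float)
    labels = df["label"].to_numpy() if "label" in df.columns else None
    return ids, xyz, labels


# -- samples ----------------------------------------------------------------

def write_sample(outdir, sample: MosaicSample, stem: str = "mosaic") -> None:
    """Point CSV + ground-truth / trace JSON sidecars for a sample."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_points_csv(outdir / f"{stem}_points.csv", sample.ids, sample.xy,
                     labels=None)
    write_traces_json(outdir / f"{stem}_rows.json", sample.row_traces)
    meta = {
        "spec": sample.spec.to_dict(),
        "geometry": sample.geometry.to_dict(),
        "seed": sample.seed,
        "defects_truth": [
            {"ring": d.ring, "s_um": d.s_um, "angle_rad": d.angle_rad,
             "kind": d.kind, "gb_label": d.gb_label}
            for d in sample.defects_truth
        ],
    }
    write_json(outdir / f"{stem}_truth.json", meta)


def read_sample(outdir, stem: str = "mosaic"):
    """Round-trip companion of :func:`write_sample` (points + sidecars)."""
    outdir = Path(outdir)
    ids, xyz, _ = read_points_csv(outdir / f"{stem}_points.csv")
    traces = read_traces_json(outdir / f"{stem}_rows.json")
    meta = read_json(outdir / f"{stem}_truth.json")
    spec = LatticeSpec(**meta["spec"])
    geom = FrustumGeometry(**meta["geometry"])
    defects = [DefectTruth(**d) for d in meta["defects_truth"]]
    return ids, xyz, traces, spec, geom, defects, meta["seed"]


# -- traces and defects -----------------------------------------------------

def write_traces_json(path, traces: RowTraces) -> None:
    write_json(path, traces.to_json_dict())


def read_traces_json(path) -> RowTraces:
    return RowTraces.from_json_dict(read_json(path))


def write_defects_json(path, cores, extra=None) -> None:
    """Dislocation list: id5, id7, core position, Burgers vector, class."""
    rows = [{
        "id5": c.id5, "id7": c.id7,
        "x_um": float(c.position[0]), "y_um": float(c.position[1]),
        "burgers_x_um": float(c.burgers[0]), "burgers_y_um": float(c.burgers[1]),
        "class": c.kind,
    } for c in cores]
    write_json(path, {"defects": rows, **(extra or {})})


def read_defects_json(path):
    return read_json(path)


# -- field dumps ------------------------------------------------------------

def write_field(outdir, fld, stem: str = "pfc") -> None:
    """Raw float64 array plus a JSON header with geometry/params/step."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.asarray(fld.psi, dtype=np.float64).tofile(outdir / f"{stem}_psi.bin")
    hdr = {
        "shape": list(fld.psi.shape),
        "dtype": "float64",
        "order": "C",
        "geometry": {"kind": fld.geometry.kind, "r0": fld.geometry.r0,
                     "dr": fld.geometry.dr, "n_r": fld.geometry.n_r,
                     "n_t": fld.geometry.n_t, "period": fld.geometry.period},
        "params": {"R": fld.params.R, "psi0": fld.params.psi0,
                   "b": fld.params.b, "dt": fld.params.dt,
                   "noise_sigma": fld.params.noise_sigma,
                   "seed": fld.params.seed},
        "step_count": fld.step_count,
    }
    write_json(outdir / f"{stem}_header.json", hdr)


def read_field(outdir, stem: str = "pfc"):
    from conemosaic.pfc import PFCField, PFCGeometry, PFCParams

    outdir = Path(outdir)
    hdr = read_json(outdir / f"{stem}_header.json")
    psi = np.fromfile(outdir / f"{stem}_psi.bin",
                      dtype=hdr["dtype"]).reshape(hdr["shape"])
    geom = PFCGeometry(**hdr["geometry"])
    params = PFCParams(**hdr["params"])
    return PFCField(psi, params, geom, step_count=hdr["step_count"])
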