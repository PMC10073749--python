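"""Serialization of pullback containers and calibration results.

Primary container: one HDF5 file with datasets ``/nirf``,
``/geometry/{ds,d_out,label}``, ``/positions`` and optional ``/truth/*``
arrays, kinematics and provenance stored as root attributes.  Fallback: a
directory of CSV files (one per array) plus a YAML metadata file,
value-equivalent to the HDF5 layout.  Calibration results round-trip through
JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .calibration import CalibrationResult
from .containers import Kinematics, Pullback, Truth
from .errors import SchemaError

_CSV_FMT = "%.17g"  # round-trips float64 exactly


def _is_hdf5_path(path: Path) -> bool:
    return path.suffix.lower() in {".h5", ".hdf5"}


def write_pullback(pullback: Pullback, path, scene_yaml: str | None = None) -> Path:
    """Write a pullback container.

    ``path`` ending in ``.h5``/``.hdf5`` selects the HDF5 layout; anything
    else is treated as a directory for the CSV fallback.  ``scene_yaml`` is
    embedded verbatim for provenance.
    """
    pullback.validate()
    path = Path(path)
    if _is_hdf5_path(path):
        _write_hdf5(pullback, path, scene_yaml)
    else:
        _write_csv(pullback, path, scene_yaml)
    return path


def read_pullback(path) -> Pullback:
    """Read and validate a pullback container (HDF5 file or CSV directory)."""
    path = Path(path)
    if path.is_dir():
        pullback = _read_csv(path)
    elif _is_hdf5_path(path):
        pullback = _read_hdf5(path)
    else:
        raise SchemaError(f"not a pullback container: {path}")
    return pullback.validate()


def _write_hdf5(pullback: Pullback, path: Path, scene_yaml: str | None) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("nirf", data=pullback.nirf)
        geo = h5.create_group("geometry")
        geo.create_dataset("ds", data=pullback.ds)
        geo.create_dataset("d_out", data=pullback.d_out)
        geo.create_dataset("label", data=pullback.labels.astype(np.int8))
        h5.create_dataset("positions", data=pullback.positions)
        if pullback.truth is not None:
            tr = h5.create_group("truth")
            tr.create_dataset("source", data=pullback.truth.source)
            tr.create_dataset("concentration", data=pullback.truth.concentration)
            tr.create_dataset("cb", data=pullback.truth.cb)
        h5.attrs["medium"] = pullback.medium
        h5.attrs["n_frames"] = pullback.n_frames
        for key, value in pullback.kinematics.to_dict().items():
            h5.attrs[key] = value
        h5.attrs["meta_json"] = json.dumps(pullback.meta, default=float)
        if scene_yaml is not None:
            h5.attrs["scene_yaml"] = scene_yaml


def _read_hdf5(path: Path) -> Pullback:
    with h5py.File(path, "r") as h5:
        for name in ("nirf", "geometry", "positions"):
            if name not in h5:
                raise SchemaError(f"missing dataset or group '{name}' in {path}")
        for name in ("ds", "d_out", "label"):
            if name not in h5["geometry"]:
                raise SchemaError(f"missing dataset 'geometry/{name}' in {path}")
        kin = Kinematics(
            length_mm=float(h5.attrs["length_mm"]),
            pullback_speed_mm_s=float(h5.attrs["pullback_speed_mm_s"]),
            rpm=float(h5.attrs["rpm"]),
        )
        nirf = np.asarray(h5["nirf"], dtype=float)
        if int(h5.attrs.get("n_frames", nirf.shape[0])) != nirf.shape[0]:
            raise SchemaError("frame count attribute inconsistent with array extent")
        truth = None
        if "truth" in h5:
            truth = Truth(
                source=np.asarray(h5["truth/source"], dtype=float),
                concentration=np.asarray(h5["truth/concentration"], dtype=float),
                cb=np.asarray(h5["truth/cb"], dtype=float),
            )
        meta = json.loads(h5.attrs.get("meta_json", "{}"))
        if "scene_yaml" in h5.attrs:
            meta["scene_yaml"] = str(h5.attrs["scene_yaml"])
        return Pullback(
            nirf=nirf,
            ds=np.asarray(h5["geometry/ds"], dtype=float),
            d_out=np.asarray(h5["geometry/d_out"], dtype=float),
            labels=np.asarray(h5["geometry/label"], dtype=np.int8),
            positions=np.asarray(h5["positions"], dtype=float),
            kinematics=kin,
            medium=str(h5.attrs.get("medium", "water")),
            meta=meta,
            truth=truth,
        )


def _write_csv(pullback: Pullback, path: Path, scene_yaml: str | None) -> None:
    path.mkdir(parents=True, exist_ok=True)
    np.savetxt(path / "nirf.csv", pullback.nirf, delimiter=",", fmt=_CSV_FMT)
    np.savetxt(path / "ds.csv", pullback.ds, delimiter=",", fmt=_CSV_FMT)
    np.savetxt(path / "d_out.csv", pullback.d_out, delimiter=",", fmt=_CSV_FMT)
    np.savetxt(path / "label.csv", pullback.labels, delimiter=",", fmt="%d")
    np.savetxt(path / "positions.csv", pullback.positions, delimiter=",", fmt=_CSV_FMT)
    if pullback.truth is not None:
        np.savetxt(path / "truth_source.csv", pullback.truth.source,
                   delimiter=",", fmt=_CSV_FMT)
        np.savetxt(path / "truth_concentration.csv", pullback.truth.concentration,
                   delimiter=",", fmt=_CSV_FMT)
        np.savetxt(path / "truth_cb.csv", pullback.truth.cb,
                   delimiter=",", fmt=_CSV_FMT)
    meta = {
        "kinematics": pullback.kinematics.to_dict(),
        "medium": pullback.medium,
        "n_frames": pullback.n_frames,
        "meta": pullback.meta,
    }
    if scene_yaml is not None:
        meta["scene_yaml"] = scene_yaml
    (path / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))


def _read_csv(path: Path) -> Pullback:
    meta_path = path / "meta.yaml"
    if not meta_path.exists():
        raise SchemaError(f"missing meta.yaml in {path}")
    meta = yaml.safe_load(meta_path.read_text())
    for name in ("nirf", "ds", "d_out", "label", "positions"):
        if not (path / f"{name}.csv").exists():
            raise SchemaError(f"missing {name}.csv in {path}")

    def load(name: str) -> np.ndarray:
        return np.atleast_2d(np.loadtxt(path / f"{name}.csv", delimiter=","))

    kin = Kinematics(**meta["kinematics"])
    truth = None
    if (path / "truth_source.csv").exists():
        truth = Truth(
            source=load("truth_source"),
            concentration=load("truth_concentration"),
            cb=np.atleast_1d(np.loadtxt(path / "truth_cb.csv", delimiter=",")),
        )
    nirf = load("nirf")
    if int(meta.get("n_frames", nirf.shape[0])) != nirf.shape[0]:
        raise SchemaError("frame count attribute inconsistent with array extent")
    extra = dict(meta.get("meta") or {})
    if "scene_yaml" in meta:
        extra["scene_yaml"] = meta["scene_yaml"]
    return Pullback(
        nirf=nirf,
        ds=load("ds"),
        d_out=load("d_out"),
        labels=load("label").astype(np.int8),
        positions=np.atleast_1d(np.loadtxt(path / "positions.csv", delimiter=",")),
        kinematics=kin,
        medium=str(meta.get("medium", "water")),
        meta=extra,
        truth=truth,
    )


def save_calibration(calib: CalibrationResult, path) -> Path:
    path = Path(path)
    doc = {
        "i0": calib.i0,
        "cw": calib.cw,
        "r2": calib.r2,
        "table": np.asarray(calib.table, dtype=float).tolist(),
    }
    path.write_text(json.dumps(doc, indent=2))
    return path


def load_calibration(path) -> CalibrationResult:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise SchemaError(f"cannot read calibration file {path}: {exc}") from exc
    for key in ("i0", "cw", "r2"):
        if key not in doc:
            raise SchemaError(f"calibration file {path} lacks '{key}'")
    return CalibrationResult(
        i0=float(doc["i0"]),
        cw=float(doc["cw"]),
        r2=float(doc["r2"]),
        table=np.asarray(doc.get("table", []), dtype=float).reshape(-1, 2),
    )
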