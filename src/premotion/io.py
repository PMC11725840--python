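"""Readers and writers: CSV spike tables, JSON stimulus logs and geometry,
report bundles and run manifests.

CSV is the interchange format for spike events (no domain standard exists
at this granularity); stimulus logs, geometry and ground truth travel as
JSON.  Every output directory gets a manifest (config + seeds + package
version) sufficient to reproduce the run.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .geometry import RetinaGeometry
from .simulate import (FullFieldProtocol, GratingProtocol, MovingBarProtocol,
                       SimCellParams, SimRecording, StaticBarProtocol,
                       TRIAL_COLUMNS, WhiteNoiseProtocol)

SCHEMA_VERSION = "premotion-1"
SPIKE_COLUMNS = ["cell_id", "protocol_id", "trial_id", "t_s"]

_PROTOCOL_TYPES = {
    "moving_bar": MovingBarProtocol,
    "static_bar": StaticBarProtocol,
    "full_field": FullFieldProtocol,
    "grating": GratingProtocol,
    "white_noise": WhiteNoiseProtocol,
}


class ValidationError(ValueError):
    """Malformed input file; message lists the offending rows."""


def _package_version() -> str:
    try:
        from importlib.metadata import version
        return version("premotion")
    except Exception:
        return "unknown"


# ---------------------------------------------------------------------------
# Spike tables
# ---------------------------------------------------------------------------

def write_spike_table(spikes: pd.DataFrame, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# schema: {SCHEMA_VERSION} spike_table\n")
        spikes[SPIKE_COLUMNS].to_csv(fh, index=False)


def read_spike_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = set(SPIKE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    for col in ("protocol_id", "trial_id", "t_s"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()].tolist()
        if bad or df[col].isna().any():
            bad = sorted(set(bad) | set(df.index[df[col].isna()]))
            raise ValidationError(
                f"{path}: malformed values in column {col!r}, rows "
                f"{[b + 2 for b in bad[:10]]} (1-based, incl. header)")
        df[col] = coerced
    df["protocol_id"] = df["protocol_id"].astype(np.int64)
    df["trial_id"] = df["trial_id"].astype(np.int64)
    return df[SPIKE_COLUMNS]


# ---------------------------------------------------------------------------
# Stimulus logs / geometry / ground truth
# ---------------------------------------------------------------------------

def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, (tuple, list, np.ndarray)):
        return [_jsonable(x) for x in v]
    if isinstance(v, float) and not np.isfinite(v):
        return None
    return v


def write_stimulus_log(trials: pd.DataFrame, protocols: dict, path) -> None:
    doc = {
        "schema": SCHEMA_VERSION,
        "protocols": {
            str(pid): {"kind": proto.kind,
                       **{k: _jsonable(v) for k, v in
                          dataclasses.asdict(proto).items() if k != "kind"}}
            for pid, proto in protocols.items()},
        "trials": json.loads(
            trials[TRIAL_COLUMNS].to_json(orient="records")),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_stimulus_log(path):
    doc = json.loads(Path(path).read_text())
    protocols = {}
    for pid, spec in doc["protocols"].items():
        kind = spec.pop("kind")
        cls = _PROTOCOL_TYPES.get(kind)
        if cls is None:
            raise ValidationError(f"{path}: unknown protocol kind {kind!r}")
        for key in ("directions", "bars", "extent", "sequence"):
            if key in spec and spec[key] is not None:
                spec[key] = tuple(tuple(x) if isinstance(x, list) else x
                                  for x in spec[key])
        protocols[int(pid)] = cls(**spec)
    trials = pd.DataFrame(doc["trials"], columns=TRIAL_COLUMNS)
    return trials, protocols


def write_geometry(geometry: RetinaGeometry, path) -> None:
    Path(path).write_text(json.dumps({
        "schema": SCHEMA_VERSION,
        "edge_polygon": [list(map(float, v)) for v in geometry.edge_polygon],
        "optic_disc": list(map(float, geometry.optic_disc)),
        "units": geometry.units,
        "central_radius": geometry.central_radius,
        "distance_min_required": geometry.distance_min_required,
    }, indent=1))


def read_geometry(path, expected_units: str | None = None) -> RetinaGeometry:
    doc = json.loads(Path(path).read_text())
    geom = RetinaGeometry(
        edge_polygon=tuple(tuple(v) for v in doc["edge_polygon"]),
        optic_disc=tuple(doc.get("optic_disc", (0.0, 0.0))),
        units=doc.get("units", "um"),
        central_radius=doc.get("central_radius", 350.0),
        distance_min_required=doc.get("distance_min_required", 450.0))
    if expected_units is not None and geom.units != expected_units:
        raise ValidationError(
            f"{path}: geometry units {geom.units!r} do not match the "
            f"configured units {expected_units!r}")
    return geom


def write_ground_truth(cells, path) -> None:
    Path(path).write_text(json.dumps({
        "schema": SCHEMA_VERSION,
        "cells": [{k: _jsonable(v) for k, v in dataclasses.asdict(c).items()}
                  for c in cells]}, indent=1))


def read_ground_truth(path):
    doc = json.loads(Path(path).read_text())
    cells = []
    for spec in doc["cells"]:
        spec["rf_center"] = tuple(spec["rf_center"])
        cells.append(SimCellParams(**spec))
    return tuple(cells)


# ---------------------------------------------------------------------------
# Single-file binary container (HDF5) — an optional faster alternative to
# the CSV/JSON bundle for large simulated sessions
# ---------------------------------------------------------------------------

def write_recording_hdf5(rec: SimRecording, path) -> None:
    import h5py
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = SCHEMA_VERSION
        g = f.create_group("spikes")
        g.create_dataset("cell_id",
                         data=rec.spikes["cell_id"].astype(str).to_numpy(
                             dtype=object),
                         dtype=h5py.string_dtype())
        for col in ("protocol_id", "trial_id", "t_s"):
            g.create_dataset(col, data=rec.spikes[col].to_numpy())
        t = f.create_group("trials")
        for col in TRIAL_COLUMNS:
            vals = rec.trials[col]
            if vals.dtype == object or col == "kind":
                t.create_dataset(col, data=vals.astype(str).to_numpy(
                    dtype=object), dtype=h5py.string_dtype())
            else:
                t.create_dataset(col, data=vals.to_numpy())
        f.attrs["protocols"] = json.dumps({
            str(pid): {"kind": proto.kind,
                       **{k: _jsonable(v) for k, v in
                          dataclasses.asdict(proto).items() if k != "kind"}}
            for pid, proto in rec.protocols.items()})
        f.attrs["geometry"] = json.dumps({
            "edge_polygon": [list(map(float, v))
                             for v in rec.geometry.edge_polygon],
            "optic_disc": list(map(float, rec.geometry.optic_disc)),
            "units": rec.geometry.units,
            "central_radius": rec.geometry.central_radius,
            "distance_min_required": rec.geometry.distance_min_required})
        if rec.ground_truth is not None:
            f.attrs["ground_truth"] = json.dumps(
                [{k: _jsonable(v) for k, v in dataclasses.asdict(c).items()}
                 for c in rec.ground_truth])


def read_recording_hdf5(path) -> SimRecording:
    import h5py
    with h5py.File(path, "r") as f:
        spikes = pd.DataFrame({
            "cell_id": [s.decode() if isinstance(s, bytes) else s
                        for s in f["spikes/cell_id"][()]],
            "protocol_id": f["spikes/protocol_id"][()],
            "trial_id": f["spikes/trial_id"][()],
            "t_s": f["spikes/t_s"][()],
        })
        trials = {}
        for col in TRIAL_COLUMNS:
            v = f["trials"][col][()]
            if v.dtype.kind in "SO":
                v = [s.decode() if isinstance(s, bytes) else s for s in v]
            trials[col] = v
        trials = pd.DataFrame(trials, columns=TRIAL_COLUMNS)
        protocols = {}
        for pid, spec in json.loads(f.attrs["protocols"]).items():
            kind = spec.pop("kind")
            for key in ("directions", "bars", "extent", "sequence"):
                if key in spec and spec[key] is not None:
                    spec[key] = tuple(tuple(x) if isinstance(x, list) else x
                                      for x in spec[key])
            protocols[int(pid)] = _PROTOCOL_TYPES[kind](**spec)
        gdoc = json.loads(f.attrs["geometry"])
        geometry = RetinaGeometry(
            edge_polygon=tuple(tuple(v) for v in gdoc["edge_polygon"]),
            optic_disc=tuple(gdoc["optic_disc"]), units=gdoc["units"],
            central_radius=gdoc["central_radius"],
            distance_min_required=gdoc["distance_min_required"])
        gt = None
        if "ground_truth" in f.attrs:
            cells = []
            for spec in json.loads(f.attrs["ground_truth"]):
                spec["rf_center"] = tuple(spec["rf_center"])
                cells.append(SimCellParams(**spec))
            gt = tuple(cells)
    return SimRecording(spikes=spikes, trials=trials, protocols=protocols,
                        geometry=geometry, ground_truth=gt).validate()


# ---------------------------------------------------------------------------
# Whole recordings and report bundles
# ---------------------------------------------------------------------------

def write_recording(rec: SimRecording, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_spike_table(rec.spikes, out / "spikes.csv")
    write_stimulus_log(rec.trials, rec.protocols, out / "stimulus_log.json")
    write_geometry(rec.geometry, out / "geometry.json")
    if rec.ground_truth is not None:
        write_ground_truth(rec.ground_truth, out / "ground_truth.json")


def read_recording(in_dir) -> SimRecording:
    p = Path(in_dir)
    spikes = read_spike_table(p / "spikes.csv")
    trials, protocols = read_stimulus_log(p / "stimulus_log.json")
    geometry = read_geometry(p / "geometry.json")
    gt = None
    if (p / "ground_truth.json").exists():
        gt = read_ground_truth(p / "ground_truth.json")
    return SimRecording(spikes=spikes, trials=trials, protocols=protocols,
                        geometry=geometry, ground_truth=gt).validate()


def write_manifest(path, cfg: RunConfig, seed, extra: dict | None = None
                   ) -> None:
    doc = {"schema": SCHEMA_VERSION, "package_version": _package_version(),
           "config": cfg.to_dict(), "seed": seed}
    doc.update(extra or {})
    Path(path).write_text(json.dumps(doc, indent=1))


def write_reports(result, out_dir, cfg: RunConfig, seed) -> None:
    """Write cell_report.csv, exclusions.csv, population_summary.json and
    the run manifest for a ScreenResult."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.reports.to_csv(out / "cell_report.csv", index=False)
    result.exclusions.to_csv(out / "exclusions.csv", index=False)
    rep = result.reports
    summary = {
        "n_included": int(len(rep)),
        "n_excluded": int(len(result.exclusions)),
        "pre_fraction": _jsonable(result.pre_fraction),
        "n_pre": int(rep["pre_asymmetric"].sum()) if len(rep) else 0,
        "n_pre_and_post": int(rep["pre_and_post"].sum()) if len(rep) else 0,
    }
    (out / "population_summary.json").write_text(json.dumps(summary,
                                                            indent=1))
    write_manifest(out / "manifest.json", cfg, seed)
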