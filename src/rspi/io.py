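"""Reading and writing the cohort trace schema (JSON nested, CSV long form).

No standard bioinformatics container fits segmental strain traces, so the
package defines a small versioned schema.  The JSON document is::

    {"schema_version": "1.0",
     "units": {"time": "ms", "strain": "%", "volume": "mL"},
     "patients": [
        {"id": "...",
         "timing": {"avc": ..., "aortic_preejection": ...,
                    "pulmonary_preejection": ..., "lv_filling_time": ...,
                    "rr": ..., "qrs_onset": 0.0},
         "lvesv_base": ..., "lvesv_fu": ..., "lvedv_base": ..., "lvedv_fu": ...,
         "lvef_base": ..., "lvef_fu": ..., "nyha_base": ..., "nyha_fu": ...,
         "septal_flash": false, "qrs_ms": ..., "lbbb": true, "upgrade": false,
         "strain_traces": [
            {"view": "4CH", "wall": "septal", "level": "basal",
             "segment_id": "...", "times": [...], "values": [...]}, ...],
         "velocity_traces": [...]}]}

Times are ms from QRS onset; strain is % with negative meaning shortening.
The CSV alternative uses two files: a long-format trace table
(patient_id, trace_type, view, wall, level, segment_id, time_ms, value) and
a patient table with the clinical and timing columns.  Both directions
validate against the domain types and fail loudly, naming the offending
patient/segment/field.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .model import (
    CardiacTiming,
    EARLY_WALL,
    InputError,
    LATE_WALL,
    PatientRecord,
    StrainTrace,
    VelocityTrace,
    ViewStrainSet,
    VIEWS,
)

SCHEMA_VERSION = "1.0"

_TIMING_FIELDS = ("avc", "aortic_preejection", "pulmonary_preejection",
                  "lv_filling_time", "rr", "qrs_onset")
_CLINICAL_FIELDS = ("lvesv_base", "lvesv_fu", "lvedv_base", "lvedv_fu",
                    "lvef_base", "lvef_fu", "nyha_base", "nyha_fu",
                    "septal_flash", "qrs_ms", "lbbb", "upgrade")


def views_from_traces(traces: Iterable[StrainTrace],
                      timing: CardiacTiming) -> dict:
    """Group strain traces into per-view sets using the anatomic wall roles."""
    views: dict = {v: None for v in VIEWS}
    by_view: dict = {}
    for tr in traces:
        by_view.setdefault(tr.view, []).append(tr)
    for view, trs in by_view.items():
        early = [t for t in trs if t.wall == EARLY_WALL[view]]
        late = [t for t in trs if t.wall == LATE_WALL[view]]
        stray = [t.wall for t in trs
                 if t.wall not in (EARLY_WALL[view], LATE_WALL[view])]
        if stray:
            raise InputError(
                f"view {view}: unexpected wall(s) {sorted(set(stray))}; "
                f"expected {EARLY_WALL[view]} or {LATE_WALL[view]}")
        views[view] = ViewStrainSet(view=view, early_wall=tuple(early),
                                    late_wall=tuple(late), timing=timing)
    return views


def _strain_traces_of(patient: PatientRecord) -> list[StrainTrace]:
    out = []
    for view in VIEWS:
        vs = patient.views.get(view)
        if vs is not None:
            out.extend(vs.early_wall)
            out.extend(vs.late_wall)
    return out


# --------------------------------------------------------------------- JSON

def patients_to_json_obj(patients: Iterable[PatientRecord]) -> dict:
    doc = {"schema_version": SCHEMA_VERSION,
           "units": {"time": "ms", "strain": "%", "volume": "mL"},
           "patients": []}
    for p in patients:
        rec = {"id": p.id,
               "timing": {f: getattr(p.timing, f) for f in _TIMING_FIELDS}}
        for f in _CLINICAL_FIELDS:
            value = getattr(p, f)
            rec[f] = bool(value) if isinstance(value, (bool, np.bool_)) \
                else value
        rec["strain_traces"] = [_trace_obj(t) for t in _strain_traces_of(p)]
        rec["velocity_traces"] = [_trace_obj(t) for t in p.velocity_traces]
        doc["patients"].append(rec)
    return doc


def _trace_obj(tr) -> dict:
    return {"view": tr.view, "wall": tr.wall, "level": tr.level,
            "segment_id": tr.segment_id,
            "times": [float(x) for x in tr.times],
            "values": [float(x) for x in tr.values]}


def save_patients_json(patients: Iterable[PatientRecord],
                       path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(patients_to_json_obj(patients)))


def _require(obj: dict, key: str, where: str):
    if key not in obj:
        raise InputError(f"{where}: missing required field {key!r}")
    return obj[key]


def patients_from_json_obj(doc: dict) -> list[PatientRecord]:
    version = _require(doc, "schema_version", "document")
    if str(version) != SCHEMA_VERSION:
        raise InputError(f"unsupported schema_version {version!r}")
    patients = []
    for rec in _require(doc, "patients", "document"):
        pid = str(_require(rec, "id", "patient"))
        where = f"patient {pid!r}"
        timing_obj = _require(rec, "timing", where)
        for f in _TIMING_FIELDS[:-1]:
            _require(timing_obj, f, f"{where} timing")
        timing = CardiacTiming(**{f: float(timing_obj.get(f, 0.0))
                                  for f in _TIMING_FIELDS})
        strain = [_trace_from_obj(o, StrainTrace, where)
                  for o in rec.get("strain_traces", [])]
        velocity = [_trace_from_obj(o, VelocityTrace, where)
                    for o in rec.get("velocity_traces", [])]
        kwargs = {f: _require(rec, f, where) for f in _CLINICAL_FIELDS}
        kwargs["septal_flash"] = bool(kwargs["septal_flash"])
        kwargs["lbbb"] = bool(kwargs["lbbb"])
        kwargs["upgrade"] = bool(kwargs["upgrade"])
        kwargs["nyha_base"] = int(kwargs["nyha_base"])
        kwargs["nyha_fu"] = int(kwargs["nyha_fu"])
        patients.append(PatientRecord(
            id=pid, views=views_from_traces(strain, timing), timing=timing,
            velocity_traces=tuple(velocity), **kwargs))
    return patients


def _trace_from_obj(obj: dict, cls, where: str):
    for key in ("view", "wall", "level", "segment_id", "times", "values"):
        _require(obj, key, f"{where} trace")
    try:
        return cls(times=np.asarray(obj["times"], float),
                   values=np.asarray(obj["values"], float),
                   view=obj["view"], wall=obj["wall"], level=obj["level"],
                   segment_id=str(obj["segment_id"]))
    except InputError as exc:
        raise InputError(f"{where}: {exc}") from exc


def load_patients_json(path: Union[str, Path]) -> list[PatientRecord]:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise InputError(f"{path}: not valid JSON ({exc})") from exc
    return patients_from_json_obj(doc)


# ---------------------------------------------------------------------- CSV

def save_patients_csv(patients: Iterable[PatientRecord],
                      traces_path: Union[str, Path],
                      patients_path: Union[str, Path]) -> None:
    """Long-format trace table plus a clinical/timing patient table."""
    patients = list(patients)
    rows = []
    for p in patients:
        for kind, trs in (("strain", _strain_traces_of(p)),
                          ("velocity", list(p.velocity_traces))):
            for tr in trs:
                for t, v in zip(tr.times, tr.values):
                    rows.append((p.id, kind, tr.view, tr.wall, tr.level,
                                 tr.segment_id, t, v))
    pd.DataFrame(rows, columns=["patient_id", "trace_type", "view", "wall",
                                "level", "segment_id", "time_ms", "value"]
                 ).to_csv(traces_path, index=False)

    prows = []
    for p in patients:
        row = {"patient_id": p.id}
        row.update({f: getattr(p.timing, f) for f in _TIMING_FIELDS})
        row.update({f: getattr(p, f) for f in _CLINICAL_FIELDS})
        prows.append(row)
    pd.DataFrame(prows).to_csv(patients_path, index=False)


def load_patients_csv(traces_path: Union[str, Path],
                      patients_path: Union[str, Path]) -> list[PatientRecord]:
    traces = pd.read_csv(traces_path)
    ptab = pd.read_csv(patients_path, dtype={"patient_id": str})
    needed = {"patient_id", "trace_type", "view", "wall", "level",
              "segment_id", "time_ms", "value"}
    if not needed <= set(traces.columns):
        raise InputError(
            f"trace CSV missing columns {sorted(needed - set(traces.columns))}")
    for f in ("patient_id",) + _TIMING_FIELDS[:-1] + _CLINICAL_FIELDS:
        if f not in ptab.columns:
            raise InputError(f"patient CSV missing column {f!r}")

    patients = []
    traces["patient_id"] = traces["patient_id"].astype(str)
    grouped = dict(tuple(traces.groupby("patient_id", sort=False)))
    for _, prow in ptab.iterrows():
        pid = str(prow["patient_id"])
        where = f"patient {pid!r}"
        timing = CardiacTiming(**{f: float(prow.get(f, 0.0))
                                  for f in _TIMING_FIELDS})
        strain, velocity = [], []
        sub = grouped.get(pid)
        if sub is not None:
            for (kind, view, wall, level, seg), g in sub.groupby(
                    ["trace_type", "view", "wall", "level", "segment_id"],
                    sort=False):
                g = g.sort_values("time_ms", kind="stable")
                cls = StrainTrace if kind == "strain" else VelocityTrace
                tr = _trace_from_obj(
                    {"view": view, "wall": wall, "level": level,
                     "segment_id": seg, "times": g["time_ms"].tolist(),
                     "values": g["value"].tolist()}, cls, where)
                (strain if kind == "strain" else velocity).append(tr)
        patients.append(PatientRecord(
            id=pid, views=views_from_traces(strain, timing), timing=timing,
            velocity_traces=tuple(velocity),
            **{f: _coerce_clinical(f, prow[f]) for f in _CLINICAL_FIELDS}))
    return patients


def _coerce_clinical(name: str, value):
    if name in ("septal_flash", "lbbb", "upgrade"):
        return bool(value) if isinstance(value, (bool, np.bool_)) \
            else str(value).strip().lower() in ("1", "true", "yes")
    if name.startswith("nyha"):
        return int(value)
    return float(value)
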