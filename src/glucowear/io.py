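"""Readers and writers for device-style on-disk formats.

Supported dialects:

* Empatica-E4-style per-channel CSV export: line 1 = session start (UNIX
  seconds), line 2 = sampling rate (Hz), then one sample value per line.
* Libre-style CGM CSV: delimited text with a timestamp column and a glucose
  column (mg/dL by default, mmol/L convertible at parse time).
* Feature matrices as CSV with a JSON sidecar carrying the registry.
* Cohort manifest (YAML) tying participant files, demographics and phases
  together.

All readers raise :class:`~glucowear.types.FormatError` on malformed input;
nothing is silently truncated.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import (
    META_COLS, PID_COL, TARGET_COL, TIME_COL, FeatureMatrix, FeatureSpec,
)
from .types import (
    Demographics, FormatError, GlucoseTrace, ParticipantRecord, Phase,
    SensorStream,
)

MMOL_TO_MGDL = 18.016


def read_e4_export(path, modality: str) -> SensorStream:
    """Read one modality from an E4-style export file.

    Timestamps are reconstructed as ``start + k/rate``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 2:
        raise FormatError(f"{path}: expected start-time and rate header lines")
    try:
        start = float(lines[0].split(",")[0])
    except ValueError as exc:
        raise FormatError(f"{path}: line 1 is not a UNIX start time: "
                          f"{lines[0]!r}") from exc
    try:
        rate = float(lines[1].split(",")[0])
    except ValueError as exc:
        raise FormatError(f"{path}: line 2 is not a sampling rate: "
                          f"{lines[1]!r}") from exc
    if rate <= 0:
        raise FormatError(f"{path}: line 2 declares non-positive rate {rate}")
    values = []
    for i, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        try:
            values.append(float(line.split(",")[0]))
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric value at row {i}: "
                              f"{line!r}") from exc
    values = np.asarray(values, dtype=float)
    timestamps = start + np.arange(values.size) / rate
    return SensorStream(modality=modality, native_rate=rate,
                        timestamps=timestamps, values=values)


def write_e4_export(stream: SensorStream, path) -> None:
    """Write a stream in the E4 export dialect (resampled to its own rate grid)."""
    path = Path(path)
    start = stream.timestamps[0] if len(stream) else 0.0
    with path.open("w") as fh:
        fh.write(f"{start:.6f}\n{stream.native_rate:g}\n")
        for v in stream.values:
            fh.write(f"{v:.9g}\n")


def read_cgm_trace(
    path,
    time_col: str = "timestamp",
    glucose_col: str = "glucose_mgdl",
    unit: str = "mgdl",
) -> GlucoseTrace:
    """Read a Libre-style CGM CSV.

    Rows are sorted by time and duplicate timestamps collapsed by mean;
    ``unit='mmol'`` converts to mg/dL at parse time.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"{path}: unreadable CSV: {exc}") from exc
    for col in (time_col, glucose_col):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r} "
                              f"(have {list(df.columns)})")
    t = pd.to_numeric(df[time_col], errors="coerce")
    if t.isna().any():
        parsed = pd.to_datetime(df[time_col], errors="coerce", utc=True)
        t = parsed.astype("int64") / 1e9
    g = pd.to_numeric(df[glucose_col], errors="coerce")
    ok = ~(np.isnan(t) | np.isnan(g))
    if not ok.any():
        raise FormatError(f"{path}: no parseable rows")
    sub = pd.DataFrame({"t": t[ok], "g": g[ok]})
    sub = sub.groupby("t", as_index=False).mean().sort_values("t")
    values = sub["g"].to_numpy(dtype=float)
    if unit == "mmol":
        values = values * MMOL_TO_MGDL
    elif unit != "mgdl":
        raise FormatError(f"unknown glucose unit {unit!r}")
    return GlucoseTrace(timestamps=sub["t"].to_numpy(dtype=float), values=values)


def write_cgm_trace(trace: GlucoseTrace, path,
                    time_col: str = "timestamp",
                    glucose_col: str = "glucose_mgdl") -> None:
    pd.DataFrame({time_col: trace.timestamps,
                  glucose_col: trace.values}).to_csv(Path(path), index=False)


# ------------------------------------------------------------ feature matrix

def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_feature_matrix(matrix: FeatureMatrix, path) -> None:
    """CSV + JSON sidecar; floating-point round-trip within 1e-9 relative."""
    path = Path(path)
    matrix.frame.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "feature_names": matrix.feature_names,
        "specs": [
            {"name": s.name, "category": s.category, "subcategory": s.subcategory,
             "channel": s.channel, "extractor": s.extractor,
             "is_zscore": s.is_zscore}
            for s in matrix.specs
        ],
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_feature_matrix(path) -> FeatureMatrix:
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise FormatError(f"{side}: sidecar metadata not found")
    meta = json.loads(side.read_text())
    feature_names = list(meta["feature_names"])
    try:
        frame = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"{path}: unreadable CSV: {exc}") from exc
    expected = set(META_COLS) | set(feature_names)
    unknown = [c for c in frame.columns if c not in expected]
    if unknown:
        raise FormatError(f"{path}: unknown columns {unknown}")
    missing = [c for c in (*META_COLS, *feature_names) if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    specs = [FeatureSpec(**s) for s in meta.get("specs", [])]
    return FeatureMatrix(frame=frame, feature_names=feature_names, specs=specs)


# ------------------------------------------------------------------- cohorts

MANIFEST_NAME = "manifest.yaml"


def write_cohort(records: list[ParticipantRecord], outdir,
                 extra: dict | None = None) -> Path:
    """Write a cohort as per-participant E4-style channel files + CGM CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"cohort": {"n_participants": len(records), **(extra or {})},
                "participants": []}
    for rec in records:
        pdir = outdir / rec.id
        pdir.mkdir(exist_ok=True)
        channels = {}
        for name, stream in rec.streams.items():
            fname = f"{rec.id}/{name}.csv"
            write_e4_export(stream, outdir / fname)
            channels[name] = {"file": fname, "rate": float(stream.native_rate)}
        gname = f"{rec.id}/glucose.csv"
        write_cgm_trace(rec.glucose, outdir / gname)
        d = rec.demographics
        entry = {
            "id": rec.id,
            "study_arm": rec.study_arm,
            "demographics": {
                "age": float(d.age), "sex": d.sex,
                "height_cm": None if d.height_cm is None else float(d.height_cm),
                "weight_kg": None if d.weight_kg is None else float(d.weight_kg),
                "bmi": float(d.bmi),
            },
            "channels": channels,
            "glucose_file": gname,
        }
        if rec.phases is not None:
            entry["phases"] = [
                {"start": float(ph.start), "end": float(ph.end), "label": ph.label}
                for ph in rec.phases
            ]
        manifest["participants"].append(entry)
    (outdir / MANIFEST_NAME).write_text(
        yaml.safe_dump(manifest, sort_keys=False))
    return outdir


def read_cohort(indir) -> list[ParticipantRecord]:
    indir = Path(indir)
    mpath = indir / MANIFEST_NAME
    if not mpath.exists():
        raise FormatError(f"{mpath}: cohort manifest not found")
    manifest = yaml.safe_load(mpath.read_text())
    records = []
    for entry in manifest.get("participants", []):
        streams = {
            name: read_e4_export(indir / ch["file"], modality=name)
            for name, ch in entry["channels"].items()
        }
        glucose = read_cgm_trace(indir / entry["glucose_file"])
        phases = None
        if "phases" in entry:
            phases = [Phase(**ph) for ph in entry["phases"]]
        records.append(ParticipantRecord(
            id=entry["id"],
            demographics=Demographics(**entry["demographics"]),
            streams=streams,
            glucose=glucose,
            phases=phases,
            study_arm=entry.get("study_arm", "main"),
        ))
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate participant ids in cohort manifest")
    return records
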