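"""Trace CSV files and the dataset manifest.

A trace file is a plain CSV with a commented metadata header::

    # participant: c01
    # group: concurrent_vf
    # session: simple
    # phase: pre_test
    # sampling_rate_hz: 80.3
    # units: mm
    # role: recording
    time_s,displacement_mm
    0,0
    0.012453300124533,0.1234567890123456

Time starts at 0 and must be uniform to within 1e-6 s. Displacement is
written with 17 significant digits so write-then-read is the identity on
the data. The manifest is one CSV row per trace: participant, group,
session, phase, file (path relative to the manifest).
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import List

import numpy as np
import pandas as pd

from .simulate import StudyDataset, TraceRecord
from .trace import MotionTrace

MANIFEST_NAME = "manifest.csv"
_HEADER_KEYS = ("participant", "group", "session", "phase", "sampling_rate_hz", "units", "role")


class TraceFormatError(ValueError):
    """A trace or manifest file violates the format contract."""


def write_trace(path: str | Path, trace: MotionTrace) -> None:
    path = Path(path)
    meta = dict(trace.meta)
    meta.setdefault("units", "mm")
    meta.setdefault("role", "recording")
    meta["sampling_rate_hz"] = repr(float(trace.sampling_rate_hz))
    lines = [f"# {k}: {meta[k]}" for k in _HEADER_KEYS if k in meta]
    extra = sorted(set(meta) - set(_HEADER_KEYS))
    lines += [f"# {k}: {meta[k]}" for k in extra]
    lines.append("time_s,displacement_mm")
    t = trace.time_s
    x = trace.displacement_mm
    lines += [f"{t[i]:.17g},{x[i]:.17g}" for i in range(len(trace))]
    path.write_text("\n".join(lines) + "\n")


def read_trace(path: str | Path) -> MotionTrace:
    path = Path(path)
    meta: dict = {}
    rows: List[tuple] = []
    header_seen = False
    try:
        text = path.read_text()
    except OSError as exc:
        raise TraceFormatError(f"{path}: cannot read trace file ({exc})") from exc
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if ":" not in line:
                raise TraceFormatError(f"{path}:{lineno}: malformed metadata line {line!r}")
            key, val = line[1:].split(":", 1)
            meta[key.strip()] = val.strip()
            continue
        if not header_seen:
            if line != "time_s,displacement_mm":
                raise TraceFormatError(
                    f"{path}:{lineno}: expected column header "
                    f"'time_s,displacement_mm', got {line!r}"
                )
            header_seen = True
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise TraceFormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError:
            raise TraceFormatError(f"{path}:{lineno}: non-numeric value in {line!r}") from None
    if "sampling_rate_hz" not in meta:
        raise TraceFormatError(f"{path}: missing 'sampling_rate_hz' metadata")
    if len(rows) < 2:
        raise TraceFormatError(f"{path}: trace needs at least 2 samples")
    fs = float(meta.pop("sampling_rate_hz"))
    t = np.array([r[0] for r in rows])
    x = np.array([r[1] for r in rows])
    expected_t = np.arange(len(t)) / fs
    if abs(t[0]) > 1e-9:
        raise TraceFormatError(f"{path}: time must start at 0, starts at {t[0]}")
    if np.max(np.abs(t - expected_t)) > 1e-6:
        i = int(np.argmax(np.abs(t - expected_t)))
        raise TraceFormatError(
            f"{path}: time not uniform at the stated rate (sample {i}: "
            f"{t[i]} vs expected {expected_t[i]})"
        )
    return MotionTrace(x, fs, meta)


def write_dataset(dataset: StudyDataset, out_dir: str | Path) -> Path:
    """Write the trace CSV tree plus the manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in dataset:
        rel = Path(rec.group) / rec.participant / f"{rec.session}_{rec.phase}.csv"
        fpath = out_dir / rel
        fpath.parent.mkdir(parents=True, exist_ok=True)
        write_trace(fpath, rec.trace)
        rows.append(
            {
                "participant": rec.participant,
                "group": rec.group,
                "session": rec.session,
                "phase": rec.phase,
                "file": rel.as_posix(),
            }
        )
    manifest = out_dir / MANIFEST_NAME
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_dataset(data_dir: str | Path) -> StudyDataset:
    """Load a dataset from its manifest; errors name the offending file."""
    data_dir = Path(data_dir)
    manifest = data_dir / MANIFEST_NAME
    if not manifest.exists():
        raise TraceFormatError(f"{manifest}: manifest not found")
    df = pd.read_csv(manifest)
    required = {"participant", "group", "session", "phase", "file"}
    missing = required - set(df.columns)
    if missing:
        raise TraceFormatError(f"{manifest}: missing columns {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        fpath = data_dir / str(row["file"])
        if not fpath.exists():
            raise TraceFormatError(
                f"{manifest}: row {i + 1} references missing file {os.fspath(fpath)}"
            )
        trace = read_trace(fpath)
        records.append(
            TraceRecord(
                participant=str(row["participant"]),
                group=str(row["group"]),
                session=str(row["session"]),
                phase=str(row["phase"]),
                trace=trace,
            )
        )
    return StudyDataset(records)
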