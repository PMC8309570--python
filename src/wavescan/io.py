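"""Readers and writers for the interchange formats.

Signals travel as single-column CSV (header ``value_uv``, UTF-8, '.'
decimal) with a JSON sidecar carrying the sampling rate and metadata; EDF
is supported read-only through :mod:`mne` when installed. Event tables,
manifests and diagram exports are plain CSV. Every artifact written here
carries enough sidecar metadata to re-run its producing command.
"""
from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .detect import EVENT_COLUMNS
from .preprocess import SignalRecord

log = logging.getLogger("wavescan")

MANIFEST_COLUMNS = ["subject_id", "group", "path", "fs_hz", "arm", "muscle",
                    "tremor_side"]

_META_FIELDS = ("subject_id", "group", "arm", "muscle", "stage")


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def write_signal(rec: SignalRecord, path) -> None:
    path = Path(path)
    pd.DataFrame({"value_uv": rec.samples}).to_csv(path, index=False,
                                                   float_format="%.17g")
    meta = {"fs_hz": rec.fs, "history": list(rec.history)}
    meta.update({k: getattr(rec, k) for k in _META_FIELDS})
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def _read_signal_csv(path, fs, meta) -> SignalRecord:
    frame = pd.read_csv(path, float_precision="round_trip")
    col = "value_uv" if "value_uv" in frame.columns else frame.columns[0]
    values = pd.to_numeric(frame[col], errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(values))
    if bad.size:
        raise ValueError(f"{path}: non-numeric or missing sample at row {bad[0] + 2}")
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        stored = json.loads(sidecar.read_text())
        fs = fs if fs is not None else stored.get("fs_hz")
        for k in _META_FIELDS:
            meta.setdefault(k, stored.get(k))
        meta.setdefault("history", tuple(stored.get("history", ())))
    if fs is None:
        raise ValueError(f"{path}: sampling rate not given and no sidecar found")
    meta = {k: v for k, v in meta.items() if v is not None}
    history = tuple(meta.pop("history", ()))
    return SignalRecord(values, float(fs), history=history, **meta)


def _read_signal_edf(path, fs, meta, channel) -> SignalRecord:
    try:
        import mne
    except ImportError as exc:   # pragma: no cover - depends on extras
        raise ImportError("EDF support requires the 'mne' package "
                          "(install wavescan[edf])") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data()[channel] * 1e6   # volts -> microvolts
    meta = {k: v for k, v in meta.items() if v is not None}
    return SignalRecord(data, float(fs if fs is not None else raw.info["sfreq"]),
                        **meta)


def read_signal(path, format: str | None = None, fs: float | None = None,
                channel: int = 0, **meta) -> SignalRecord:
    """Load one channel as a SignalRecord (samples in uV).

    ``format`` is inferred from the suffix when omitted; for CSV the
    sampling rate comes from the JSON sidecar unless given explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "csv":
        return _read_signal_csv(path, fs, meta)
    if fmt == "edf":
        return _read_signal_edf(path, fs, meta, channel)
    raise ValueError(f"unknown signal format {fmt!r}")


def write_event_table(events: pd.DataFrame, path) -> None:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns {missing}")
    extra = [c for c in events.columns if c not in EVENT_COLUMNS]
    events[EVENT_COLUMNS + extra].to_csv(path, index=False)


def read_event_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, keep_default_na=False, dtype={"rejected_code": str},
                        float_precision="round_trip")
    missing = [c for c in EVENT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: event table missing columns {missing}")
    extra = [c for c in frame.columns if c not in EVENT_COLUMNS]
    if extra:
        warnings.warn(f"event table has unknown columns {extra}; preserved")
    for col in EVENT_COLUMNS[4:-1]:
        frame[col] = pd.to_numeric(frame[col])
    return frame


def write_manifest(manifest: pd.DataFrame, path) -> None:
    cols = [c for c in MANIFEST_COLUMNS if c in manifest.columns]
    cols += [c for c in manifest.columns if c not in cols]
    manifest[cols].to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    for col in ("subject_id", "group", "path"):
        if col not in frame.columns:
            raise ValueError(f"{path}: manifest missing column {col!r}")
    key = [c for c in ("subject_id", "arm", "muscle") if c in frame.columns]
    if frame.duplicated(key).any():
        raise ValueError(f"{path}: duplicate {tuple(key)} rows in manifest")
    return frame


def write_cohort(cohort, outdir) -> Path:
    """Write a synthetic cohort: per-subject signal CSVs plus manifest.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort.records:
        fname = f"{rec.subject_id}.csv"
        write_signal(rec, outdir / fname)
        rows.append({"subject_id": rec.subject_id, "group": rec.group,
                     "path": fname, "fs_hz": rec.fs, "arm": rec.arm,
                     "muscle": rec.muscle,
                     "tremor_side": "left" if rec.group == "patient" else "none"})
    manifest = pd.DataFrame(rows)
    write_manifest(manifest, outdir / "manifest.csv")
    meta = {"seed": cohort.spec.seed, "n_controls": cohort.spec.n_controls,
            "n_patients": cohort.spec.n_patients,
            "duration_s": cohort.spec.duration_s, "fs": cohort.spec.fs}
    (outdir / "cohort.json").write_text(json.dumps(meta, indent=1))
    return outdir / "manifest.csv"
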