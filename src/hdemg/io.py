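"""Portable readers/writers for sessions, heatmaps and sidecar metadata.

A session bundle is a directory containing ``metadata.json`` and
``signals.f32`` — the raw signal matrix as little-endian 32-bit floats in
row-major (channels x samples) order.  The format is deliberately
language-neutral: any environment that can read JSON and a flat float32
array can consume it.  Delimited text import/export is provided as the
ingestion path for externally exported recordings (one column per channel,
in channel-index order, values in microvolts).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .grid import Anthropometrics
from .session import ContractionProtocol, RecordingSession

_SIGNALS_NAME = "signals.f32"
_META_NAME = "metadata.json"

_REQUIRED_META = (
    "fs",
    "n_channels",
    "n_samples",
    "gesture_label",
    "participant_id",
    "protocol",
    "anthropometrics",
)


def write_session(session: RecordingSession, path: str | Path) -> Path:
    """Write a session bundle; returns the bundle directory path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "fs": session.fs,
        "n_channels": session.n_channels,
        "n_samples": session.n_samples,
        "gesture_label": session.gesture_label,
        "participant_id": session.participant_id,
        "group": session.group,
        "protocol": {
            "n_repetitions": session.protocol.n_repetitions,
            "contraction_s": session.protocol.contraction_s,
            "rest_s": session.protocol.rest_s,
            "fs": session.protocol.fs,
            "ramp_s": session.protocol.ramp_s,
            "lead_in_s": session.protocol.lead_in_s,
        },
        "anthropometrics": {
            "forearm_length_cm": session.anthropometrics.forearm_length_cm,
            "circumference_cm": session.anthropometrics.circumference_cm,
            "start_offset_fraction": session.anthropometrics.start_offset_fraction,
            "handedness": session.anthropometrics.handedness,
        },
        "extra": session.extra,
        "dtype": "<f4",
        "order": "channels_x_samples_row_major",
    }
    (path / _META_NAME).write_text(json.dumps(meta, indent=2))
    sig = np.ascontiguousarray(session.signals, dtype="<f4")
    sig.tofile(path / _SIGNALS_NAME)
    return path


def read_session(path: str | Path) -> RecordingSession:
    """Read a session bundle written by :func:`write_session`.

    Raises :class:`FormatError` naming the offending field on any mismatch.
    """
    path = Path(path)
    meta_path = path / _META_NAME
    sig_path = path / _SIGNALS_NAME
    if not meta_path.is_file():
        raise FormatError(f"bundle {path} is missing {_META_NAME}")
    if not sig_path.is_file():
        raise FormatError(f"bundle {path} is missing {_SIGNALS_NAME}")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed {_META_NAME}: {exc}") from exc
    for key in _REQUIRED_META:
        if key not in meta:
            raise FormatError(f"bundle metadata missing required field: {key}")
    n_ch, n_s = int(meta["n_channels"]), int(meta["n_samples"])
    raw = np.fromfile(sig_path, dtype="<f4")
    if raw.size != n_ch * n_s:
        raise FormatError(
            f"signals.f32 holds {raw.size} values but metadata declares "
            f"n_channels={n_ch} x n_samples={n_s}"
        )
    proto = meta["protocol"]
    anth = meta["anthropometrics"]
    try:
        protocol = ContractionProtocol(**proto)
        anthropometrics = Anthropometrics(**anth)
    except TypeError as exc:
        raise FormatError(f"bad protocol/anthropometrics block: {exc}") from exc
    return RecordingSession(
        signals=raw.reshape(n_ch, n_s),
        fs=float(meta["fs"]),
        gesture_label=meta["gesture_label"],
        participant_id=meta["participant_id"],
        protocol=protocol,
        anthropometrics=anthropometrics,
        group=meta.get("group", "unknown"),
        extra=meta.get("extra", {}),
    )


def export_delimited(session: RecordingSession, path: str | Path, fmt: str = "%.6f") -> Path:
    """Write signals as delimited text: one row per sample, one column per channel."""
    path = Path(path)
    np.savetxt(path, session.signals.T, fmt=fmt, delimiter=",")
    return path


def import_delimited(
    path: str | Path,
    fs: float,
    gesture_label: str,
    participant_id: str,
    protocol: ContractionProtocol,
    anthropometrics: Anthropometrics,
    group: str = "unknown",
) -> RecordingSession:
    """Read a delimited signal matrix (columns = channels, values in microvolts).

    Ragged rows or non-numeric cells raise :class:`FormatError` naming the
    first offending row (0-based data row index).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, header=None, sep=",")
    except pd.errors.ParserError as exc:
        raise FormatError(f"ragged or unparseable delimited file {path}: {exc}") from exc
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=np.float64)
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        row, col = bad[0]
        raise FormatError(
            f"non-numeric or missing cell at row {row}, column {col} of {path}"
        )
    return RecordingSession(
        signals=values.T,
        fs=fs,
        gesture_label=gesture_label,
        participant_id=participant_id,
        protocol=protocol,
        anthropometrics=anthropometrics,
        group=group,
    )


def write_heatmap_csv(values: np.ndarray, path: str | Path, **metadata) -> Path:
    """Write an 8x8 heatmap as CSV with ``# key: value`` metadata header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, val in metadata.items():
            fh.write(f"# {key}: {val}\n")
        np.savetxt(fh, np.asarray(values), fmt="%.8g", delimiter=",")
    return path


def read_heatmap_csv(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    meta = {}
    rows = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
        elif line.strip():
            rows.append([float(x) for x in line.split(",")])
    return np.asarray(rows), meta


def write_ground_truth(truth: dict, path: str | Path) -> Path:
    """Write a synthetic-cohort ground-truth sidecar as JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    path.write_text(json.dumps(truth, indent=2, default=_default))
    return path


def read_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
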