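"""Recording and result I/O.

Two recording formats are supported:

* delimited numeric text (one row per channel, tab-separated) with a JSON
  sidecar (``<path>.json``) holding the sampling rate, channel labels and
  metadata — lossless, the default;
* EDF (European Data Format, 16-bit integer, 1-second data records) —
  implemented natively here because no EDF library is available in the
  runtime image.  EDF quantizes to the 16-bit physical range and requires
  an integer sampling rate and a whole number of seconds.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .types import FeatureVector, InputError, MultichannelRecording

__all__ = [
    "write_recording_text",
    "read_recording_text",
    "write_recording_edf",
    "read_recording_edf",
    "read_recording",
    "write_recording",
    "write_feature_table",
    "read_feature_table",
]


# --------------------------------------------------------------------------
# delimited text + JSON sidecar
# --------------------------------------------------------------------------

def _sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def write_recording_text(rec: MultichannelRecording, path) -> Path:
    """One tab-separated row per channel; metadata in ``<path>.json``."""
    path = Path(path)
    np.savetxt(path, rec.data, delimiter="\t", fmt="%.10g")
    meta = {
        "sampling_rate": rec.sampling_rate,
        "channel_labels": list(rec.channel_labels),
        "subject_id": rec.subject_id,
        "group_label": rec.group_label,
        "units": "uV",
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)
    return path


def read_recording_text(path, sidecar: Optional[dict] = None) -> MultichannelRecording:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if sidecar is None:
        sc = _sidecar_path(path)
        if not sc.exists():
            raise InputError(
                f"missing metadata: {path} has no sidecar {sc.name} and no "
                "sidecar dict was supplied (need sampling_rate, channel_labels)"
            )
        with open(sc) as fh:
            sidecar = json.load(fh)
    for key in ("sampling_rate", "channel_labels"):
        if key not in sidecar:
            raise InputError(f"sidecar for {path} is missing field {key!r}")
    data = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
    if data.shape[0] != len(sidecar["channel_labels"]):
        raise InputError(
            f"{path}: {data.shape[0]} data rows but "
            f"{len(sidecar['channel_labels'])} channel labels"
        )
    return MultichannelRecording(
        data=data,
        sampling_rate=float(sidecar["sampling_rate"]),
        channel_labels=list(sidecar["channel_labels"]),
        subject_id=sidecar.get("subject_id", ""),
        group_label=sidecar.get("group_label"),
    )


# --------------------------------------------------------------------------
# minimal EDF (16-bit, 1-second records)
# --------------------------------------------------------------------------

def _ascii(value, width: int) -> bytes:
    out = str(value)[:width]
    return out.ljust(width).encode("ascii")


def write_recording_edf(rec: MultichannelRecording, path) -> Path:
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9 or fs < 1:
        raise InputError(f"EDF export needs an integer sampling rate, got {fs}")
    fs = int(round(fs))
    n_records = rec.n_samples // fs
    if n_records < 1:
        raise InputError("EDF export needs at least 1 second of data")
    ns = rec.n_channels
    data = rec.data[:, : n_records * fs]

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    flat = phys_max == phys_min
    phys_max = np.where(flat, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((data - phys_min[:, None]) * scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    header_bytes = 256 + 256 * ns
    with open(path, "wb") as fh:
        fh.write(_ascii("0", 8))
        fh.write(_ascii(rec.subject_id or "X", 80))
        fh.write(_ascii(rec.group_label or "", 80))
        fh.write(_ascii("01.01.20", 8))
        fh.write(_ascii("00.00.00", 8))
        fh.write(_ascii(header_bytes, 8))
        fh.write(_ascii("", 44))
        fh.write(_ascii(n_records, 8))
        fh.write(_ascii(1, 8))
        fh.write(_ascii(ns, 4))
        for lab in rec.channel_labels:
            fh.write(_ascii(lab, 16))
        for _ in range(ns):
            fh.write(_ascii("", 80))       # transducer
        for _ in range(ns):
            fh.write(_ascii("uV", 8))
        for v in phys_min:
            fh.write(_ascii(f"{v:.8g}"[:8], 8))
        for v in phys_max:
            fh.write(_ascii(f"{v:.8g}"[:8], 8))
        fh.write(_ascii(dig_min, 8) * ns)
        fh.write(_ascii(dig_max, 8) * ns)
        for _ in range(ns):
            fh.write(_ascii("", 80))       # prefiltering
        fh.write(_ascii(fs, 8) * ns)
        fh.write(_ascii("", 32) * ns)
        for r in range(n_records):
            block = digital[:, r * fs:(r + 1) * fs]
            fh.write(block.tobytes())
    return Path(path)


def _read_field(fh, width: int) -> str:
    return fh.read(width).decode("ascii", errors="replace").strip()


def read_recording_edf(path) -> MultichannelRecording:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    with open(path, "rb") as fh:
        try:
            _read_field(fh, 8)                      # version
            subject = _read_field(fh, 80)
            group = _read_field(fh, 80) or None
            _read_field(fh, 8)
            _read_field(fh, 8)
            header_bytes = int(_read_field(fh, 8))
            _read_field(fh, 44)
            n_records = int(_read_field(fh, 8))
            record_dur = float(_read_field(fh, 8))
            ns = int(_read_field(fh, 4))
            labels = [_read_field(fh, 16) for _ in range(ns)]
            fh.read(80 * ns)                        # transducer
            fh.read(8 * ns)                         # physical dimension
            phys_min = np.array([float(_read_field(fh, 8)) for _ in range(ns)])
            phys_max = np.array([float(_read_field(fh, 8)) for _ in range(ns)])
            dig_min = np.array([float(_read_field(fh, 8)) for _ in range(ns)])
            dig_max = np.array([float(_read_field(fh, 8)) for _ in range(ns)])
            fh.read(80 * ns)                        # prefiltering
            spr = [int(_read_field(fh, 8)) for _ in range(ns)]
            fh.read(32 * ns)
        except (ValueError, struct.error) as exc:
            raise InputError(f"{path}: malformed EDF header ({exc})") from exc
        if header_bytes != 256 + 256 * ns:
            raise InputError(f"{path}: EDF header size field inconsistent")
        if len(set(spr)) != 1:
            raise InputError(f"{path}: per-channel sampling rates differ")
        if record_dur <= 0:
            raise InputError(f"{path}: non-positive record duration")
        fs = spr[0] / record_dur
        raw = fh.read()
    expected = n_records * ns * spr[0] * 2
    if len(raw) < expected:
        raise InputError(
            f"{path}: truncated EDF (expected {expected} data bytes, "
            f"got {len(raw)})"
        )
    digital = np.frombuffer(raw[:expected], dtype="<i2")
    digital = digital.reshape(n_records, ns, spr[0])
    data = digital.transpose(1, 0, 2).reshape(ns, -1).astype(float)
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    data = (data - dig_min[:, None]) * scale[:, None] + phys_min[:, None]
    return MultichannelRecording(
        data=data, sampling_rate=fs, channel_labels=labels,
        subject_id=subject, group_label=group,
    )


# --------------------------------------------------------------------------
# dispatch
# --------------------------------------------------------------------------

def read_recording(path, sidecar: Optional[dict] = None) -> MultichannelRecording:
    """Auto-detect format from the extension (.edf vs delimited text)."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_recording_edf(path)
    return read_recording_text(path, sidecar=sidecar)


def write_recording(rec: MultichannelRecording, path) -> Path:
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return write_recording_edf(rec, path)
    return write_recording_text(rec, path)


# --------------------------------------------------------------------------
# feature tables
# --------------------------------------------------------------------------

def write_feature_table(feature_vectors, path) -> Path:
    """CSV with one row per epoch; the header names the layout scheme and
    the per-column feature identity."""
    if not feature_vectors:
        raise InputError("no feature vectors to write")
    layouts = {fv.layout for fv in feature_vectors}
    if len(layouts) != 1:
        raise InputError(f"mixed layouts: {sorted(layouts)}")
    first = feature_vectors[0]
    cols = first.names or [f"f{i}" for i in range(len(first))]
    df = pd.DataFrame(
        np.vstack([fv.values for fv in feature_vectors]), columns=cols
    )
    df.insert(0, "epoch_id", [fv.epoch_id for fv in feature_vectors])
    df.insert(1, "label", [fv.label for fv in feature_vectors])
    df.insert(2, "layout", first.layout)
    df.to_csv(path, index=False, float_format="%.12g")
    return Path(path)


def read_feature_table(path):
    """Inverse of :func:`write_feature_table`; returns FeatureVectors."""
    df = pd.read_csv(path)
    for col in ("epoch_id", "label", "layout"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    value_cols = [c for c in df.columns if c not in ("epoch_id", "label", "layout")]
    out = []
    for _, row in df.iterrows():
        out.append(
            FeatureVector(
                values=row[value_cols].to_numpy(dtype=float),
                layout=row["layout"],
                label=None if pd.isna(row["label"]) else str(row["label"]),
                epoch_id=None if pd.isna(row["epoch_id"]) else str(row["epoch_id"]),
                names=list(value_cols),
            )
        )
    return out
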