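"""Recording and model I/O.

Recordings travel either as EDF (the clinical interchange format) or as
plain CSV with a ``time_s`` column and one column per channel.  Event
markers live in a two-column sidecar text file ``(sample_index, code)`` in
both cases, since EDF annotations are not needed for fixed-code markers.

EDF files are read through :func:`mne.io.read_raw_edf`.  Writing uses a
small built-in EDF writer (16-bit samples, one data record per second,
zero-padded tail record trimmed on read via the stored sample count is not
attempted -- instead a single data record holds the whole signal, which
EDF permits and mne reads back exactly).
"""

from __future__ import annotations

import json
import pathlib

import numpy as np
import pandas as pd

from .signals import EEGRecording

__all__ = [
    "ParseError", "read_recording", "write_recording",
    "read_events", "write_events", "save_models", "load_models",
]


class ParseError(ValueError):
    """Malformed recording or event file."""


def _events_path(path) -> pathlib.Path:
    p = pathlib.Path(path)
    return p.with_suffix(p.suffix + ".events.csv")


def write_events(events, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_index,code\n")
        for idx, code in events:
            fh.write(f"{idx},{code}\n")


def read_events(path) -> list:
    events = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != "sample_index,code":
            raise ParseError(f"{path}: bad event-file header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.strip().split(",")
            if len(parts) != 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 fields")
            events.append((int(parts[0]), _coerce_code(parts[1])))
    return events


def _coerce_code(text: str):
    try:
        return int(text)
    except ValueError:
        return text


# ---------------------------------------------------------------- CSV

def _write_csv(rec: EEGRecording, path) -> None:
    t = np.arange(rec.n_samples) / rec.rate
    df = pd.DataFrame({"time_s": t})
    for name, row in zip(rec.channel_names, rec.data):
        df[name] = row
    df.to_csv(path, index=False, float_format="%.6f")


def _read_csv(path) -> EEGRecording:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if "time_s" not in df.columns:
        raise ParseError(f"{path}: missing required column 'time_s'")
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax()) + 2  # +header +1-based
        raise ParseError(f"{path}: missing value at line {row}")
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ParseError(f"{path}: need at least two samples")
    rate = 1.0 / np.median(np.diff(t))
    if abs(rate - round(rate)) < 0.005 * rate:  # undo time-column rounding
        rate = round(rate)
    names = [c for c in df.columns if c != "time_s"]
    data = df[names].to_numpy().T
    return EEGRecording(data, rate=float(rate), channel_names=tuple(names))


# ---------------------------------------------------------------- EDF

def _edf_field(value, width) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(rec: EEGRecording, path) -> None:
    """Minimal EDF writer: one data record containing the whole signal."""
    n_ch = rec.n_channels
    n_samp = rec.n_samples
    phys_min = rec.data.min(axis=1)
    phys_max = rec.data.max(axis=1)
    # avoid a zero physical range on constant channels
    flat = phys_max - phys_min < 1e-12
    phys_max = np.where(flat, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767

    header = b"0".ljust(8)
    header += _edf_field("hybridbci", 80)           # patient id
    header += _edf_field("synthetic", 80)           # recording id
    header += _edf_field("01.01.00", 8)             # start date
    header += _edf_field("00.00.00", 8)             # start time
    header += _edf_field(256 + 256 * n_ch, 8)       # header bytes
    header += _edf_field("", 44)                    # reserved
    header += _edf_field(1, 8)                      # number of data records
    header += _edf_field(repr(n_samp / rec.rate)[:8], 8)  # record duration s
    header += _edf_field(n_ch, 4)

    def per_signal(values, width):
        return b"".join(_edf_field(v, width) for v in values)

    header += per_signal(rec.channel_names, 16)     # labels
    header += per_signal([""] * n_ch, 80)           # transducer
    header += per_signal(["uV"] * n_ch, 8)          # physical dimension
    header += per_signal([f"{v:.6g}"[:8] for v in phys_min], 8)
    header += per_signal([f"{v:.6g}"[:8] for v in phys_max], 8)
    header += per_signal([dig_min] * n_ch, 8)
    header += per_signal([dig_max] * n_ch, 8)
    header += per_signal([""] * n_ch, 80)           # prefiltering
    header += per_signal([n_samp] * n_ch, 8)        # samples per record
    header += per_signal([""] * n_ch, 32)           # reserved

    # re-read the physical ranges as the truncated ASCII the file carries,
    # so quantization is computed against what a reader will see
    pmin = np.array([float(f"{v:.6g}"[:8]) for v in phys_min])
    pmax = np.array([float(f"{v:.6g}"[:8]) for v in phys_max])
    gain = (dig_max - dig_min) / (pmax - pmin)
    dig = np.rint((rec.data - pmin[:, None]) * gain[:, None] + dig_min)
    dig = np.clip(dig, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(dig.tobytes())            # signal-major within the record


def _read_edf(path) -> EEGRecording:
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises various types on malformed files
        raise ParseError(f"{path}: {exc}") from exc
    data = raw.get_data() * 1e6  # mne converts uV channels to volts
    return EEGRecording(data, rate=float(raw.info["sfreq"]),
                        channel_names=tuple(raw.ch_names))


# ---------------------------------------------------------------- public

def write_recording(rec: EEGRecording, path, format: str = None) -> None:
    """Write a recording as EDF or CSV, plus an event sidecar file."""
    fmt = (format or pathlib.Path(path).suffix.lstrip(".")).upper()
    if fmt == "EDF":
        _write_edf(rec, path)
    elif fmt == "CSV":
        _write_csv(rec, path)
    else:
        raise ValueError(f"unknown recording format {fmt!r}")
    write_events(rec.events, _events_path(path))


def read_recording(path, format: str = None) -> EEGRecording:
    """Read an EDF or CSV recording; events are loaded from the sidecar
    file if present."""
    fmt = (format or pathlib.Path(path).suffix.lstrip(".")).upper()
    if fmt == "EDF":
        rec = _read_edf(path)
    elif fmt == "CSV":
        rec = _read_csv(path)
    else:
        raise ValueError(f"unknown recording format {fmt!r}")
    ev_path = _events_path(path)
    if ev_path.exists():
        rec.events = read_events(ev_path)
    return rec


# ------------------------------------------------------- model container

def save_models(path, **models) -> None:
    """Serialize fitted decoder models to a single JSON container.

    Every keyword argument must expose ``to_dict()``; the container keys
    are the argument names.
    """
    payload = {name: m.to_dict() for name, m in models.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_models(path, **loaders) -> dict:
    """Inverse of :func:`save_models`; ``loaders`` maps container keys to
    ``from_dict`` callables."""
    with open(path) as fh:
        payload = json.load(fh)
    return {name: loaders[name](d) for name, d in payload.items()
            if name in loaders}
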