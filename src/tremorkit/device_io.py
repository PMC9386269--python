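"""Reading and writing wrist-accelerometer CSV exports.

Consumer/research accelerometer wristwatches (e.g. GENEActiv) export
recordings as delimited tables with a triaxial acceleration channel in units
of g, a light channel from the built-in photodiode, and optionally button and
temperature channels.  This module parses those tables together with the
filename convention that encodes session metadata::

    <subject>_<wrist side>_<watch id>_YYYY-MM-DD HH-MM-SS.csv

e.g. ``patient X_right wrist_watchnumber_2018-07-13 17-27-44.csv``.

The pipeline operates on sample indices; the timestamp column is used only to
infer the sampling rate and to check monotonicity, while ``start_datetime``
from the filename anchors absolute time.
"""

from __future__ import annotations

import io
import os
import re
from dataclasses import dataclass, replace
from datetime import datetime
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import MetadataError, ParseError, UnitError

#: Standard gravity, m/s² per g (CODATA conventional value).
STANDARD_GRAVITY = 9.80665

#: Default device ceiling on the sampling rate, Hz.
DEFAULT_MAX_SAMPLE_RATE = 100.0

#: Device acceleration sensing range, g.
DEVICE_RANGE_G = 8.0

_TIMESTAMP_FMT = "%Y-%m-%d %H-%M-%S"

_DEFAULT_COLUMNS = ("timestamp", "x", "y", "z", "light", "button", "temperature")


@dataclass(frozen=True)
class DeviceMeta:
    """Session metadata parsed from a recording filename."""

    subject_id: str
    wrist_side: str  # "left" or "right"
    watch_id: str
    start_datetime: datetime

    def __post_init__(self) -> None:
        if self.wrist_side not in ("left", "right"):
            raise MetadataError(
                f"wrist_side must be 'left' or 'right', got {self.wrist_side!r}"
            )
        for name in ("subject_id", "watch_id"):
            if not getattr(self, name):
                raise MetadataError(f"{name} must be non-empty")


@dataclass
class RawRecording:
    """A uniformly sampled triaxial recording plus auxiliary channels.

    ``acceleration`` is an (N, 3) array either in g (``units == "g"``) or in
    m/s² (``units == "m/s2"``); :func:`to_si` converts between them.
    """

    sample_rate: float
    acceleration: np.ndarray  # (N, 3)
    light: np.ndarray  # (N,)
    meta: DeviceMeta
    units: str = "g"
    temperature: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.acceleration = np.asarray(self.acceleration, dtype=float)
        self.light = np.asarray(self.light, dtype=float)
        if self.acceleration.ndim != 2 or self.acceleration.shape[1] != 3:
            raise ParseError(
                f"acceleration must be (N, 3), got shape {self.acceleration.shape}"
            )
        n = self.acceleration.shape[0]
        if n < 1:
            raise ParseError("recording has zero samples")
        if self.light.shape != (n,):
            raise ParseError(
                f"light channel length {self.light.shape[0]} != {n} samples"
            )
        if self.temperature is not None:
            self.temperature = np.asarray(self.temperature, dtype=float)
            if self.temperature.shape != (n,):
                raise ParseError("temperature channel length mismatch")
        if not self.sample_rate > 0:
            raise ParseError(f"sample_rate must be positive, got {self.sample_rate}")
        if np.any(self.light < 0):
            raise ParseError("light channel must be nonnegative")

    @property
    def n_samples(self) -> int:
        return self.acceleration.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate


def parse_filename(name: str | os.PathLike) -> DeviceMeta:
    """Parse session metadata from a recording filename.

    The base name (extension stripped) must split on underscores into at
    least four fields: subject id, a wrist phrase containing "left" or
    "right", watch id, and a ``YYYY-MM-DD HH-MM-SS`` timestamp.  A subject id
    may itself contain underscores; fields are taken as (first, ..., last-2,
    last-1, last) with everything before the wrist phrase joined back into
    the subject id.
    """
    stem = Path(name).stem
    parts = stem.split("_")
    if len(parts) < 4:
        raise MetadataError(
            f"filename {stem!r} splits into {len(parts)} underscore fields; "
            "expected at least 4 (subject, wrist, watch, timestamp)"
        )
    ts_field = parts[-1]
    watch_id = parts[-2]
    wrist_field = parts[-3]
    subject_id = "_".join(parts[:-3])

    try:
        start = datetime.strptime(ts_field, _TIMESTAMP_FMT)
    except ValueError as exc:
        raise MetadataError(
            f"timestamp field {ts_field!r} does not parse as "
            f"'YYYY-MM-DD HH-MM-SS': {exc}"
        ) from exc

    low = wrist_field.lower()
    has_left = "left" in low
    has_right = "right" in low
    if has_left == has_right:
        raise MetadataError(
            f"wrist field {wrist_field!r} must contain exactly one of "
            "'left'/'right'"
        )
    side = "left" if has_left else "right"
    return DeviceMeta(
        subject_id=subject_id,
        wrist_side=side,
        watch_id=watch_id,
        start_datetime=start,
    )


def _parse_timestamps(values: pd.Series) -> np.ndarray:
    """Return timestamps as seconds (float), accepting numbers or datetimes."""
    numeric = pd.to_numeric(values, errors="coerce")
    if numeric.notna().all():
        return numeric.to_numpy(dtype=float)
    parsed = pd.to_datetime(values, errors="coerce", format="mixed")
    if parsed.isna().any():
        bad = int(np.argmax(parsed.isna().to_numpy()))
        raise ParseError(f"unparseable timestamp at data row {bad}")
    t = parsed.astype("int64").to_numpy()
    return (t - t[0]) / 1e9


def read_recording(
    path: str | os.PathLike,
    column_map: Mapping[str, str] | None = None,
    max_sample_rate: float = DEFAULT_MAX_SAMPLE_RATE,
) -> RawRecording:
    """Read a delimited accelerometer export into a :class:`RawRecording`.

    The default dialect is: optional ``#``-prefixed header lines (which may
    declare ``# sample_rate: <Hz>``), then a header row naming at least
    ``timestamp,x,y,z,light`` with acceleration in g.  ``column_map`` maps
    file column names onto those roles for other vendor exports.
    """
    path = Path(path)
    header_rate: float | None = None
    header_lines = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            m = re.match(r"#\s*sample_rate\s*[:=]\s*([0-9.]+)", line)
            if m:
                header_rate = float(m.group(1))

    try:
        df = pd.read_csv(path, skiprows=header_lines)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path.name}: {exc}") from exc
    if df.shape[0] == 0:
        raise ParseError(f"{path.name}: no data rows")
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).to_numpy().argmax())
        raise ParseError(f"{path.name}: ragged/missing values at data row {row}")

    if column_map:
        df = df.rename(columns=dict(column_map))
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in ("timestamp", "x", "y", "z", "light") if c not in df.columns]
    if missing:
        raise ParseError(f"{path.name}: missing required columns {missing}")

    t = _parse_timestamps(df["timestamp"])
    if len(t) > 1:
        gaps = np.diff(t)
        if np.any(gaps <= 0):
            bad = int(np.argmax(gaps <= 0)) + 1
            raise ParseError(
                f"{path.name}: non-monotone timestamp at data row {bad}"
            )
        inferred = 1.0 / float(np.median(gaps))
    else:
        inferred = None

    rate = header_rate if header_rate is not None else inferred
    if rate is None:
        raise ParseError(f"{path.name}: cannot determine sample rate from one row")

    acc = df[["x", "y", "z"]].to_numpy(dtype=float)
    if np.any(np.abs(acc) > DEVICE_RANGE_G + 1e-9):
        raise ParseError(
            f"{path.name}: acceleration exceeds device range ±{DEVICE_RANGE_G} g"
        )
    temp = (
        df["temperature"].to_numpy(dtype=float)
        if "temperature" in df.columns
        else None
    )
    if rate > max_sample_rate * (1 + 1e-6):
        raise ParseError(
            f"{path.name}: inferred sample rate {rate:.3f} Hz exceeds the "
            f"device ceiling {max_sample_rate} Hz (override max_sample_rate "
            "for other hardware)"
        )
    return RawRecording(
        sample_rate=rate,
        acceleration=acc,
        light=df["light"].to_numpy(dtype=float),
        meta=parse_filename(path),
        units="g",
        temperature=temp,
    )


def write_recording(rec: RawRecording, directory: str | os.PathLike) -> Path:
    """Write a recording as a CSV under the filename convention.

    The inverse of :func:`read_recording` on the default dialect; channels
    round-trip to better than 1e-9 relative error (full float precision is
    written) and metadata exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    m = rec.meta
    fname = (
        f"{m.subject_id}_{m.wrist_side} wrist_{m.watch_id}_"
        f"{m.start_datetime.strftime(_TIMESTAMP_FMT)}.csv"
    )
    out = directory / fname
    if rec.units != "g":
        raise UnitError("write_recording expects device units (g)")
    n = rec.n_samples
    t = np.arange(n) / rec.sample_rate
    cols = {
        "timestamp": t,
        "x": rec.acceleration[:, 0],
        "y": rec.acceleration[:, 1],
        "z": rec.acceleration[:, 2],
        "light": rec.light,
    }
    if rec.temperature is not None:
        cols["temperature"] = rec.temperature
    buf = io.StringIO()
    buf.write(f"# sample_rate: {rec.sample_rate:.10g}\n")
    pd.DataFrame(cols).to_csv(buf, index=False, float_format="%.17g")
    out.write_text(buf.getvalue(), encoding="utf-8")
    return out


def to_si(raw: RawRecording) -> RawRecording:
    """Convert acceleration from g to m/s² (idempotent on SI input)."""
    if raw.units == "m/s2":
        return raw
    if raw.units != "g":
        raise UnitError(f"unknown acceleration unit flag {raw.units!r}")
    return replace(
        raw,
        acceleration=raw.acceleration * STANDARD_GRAVITY,
        units="m/s2",
    )
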