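"""Reading and writing of multi-overtone QCM-D trace exports.

The canonical in-memory representation keeps frequency shifts as *raw* Hz at
each overtone (not divided by the overtone number), dissipation shifts in
ppm, and time in hours.  Instrument exports that store overtone-normalized
frequencies (Delta f / n) are converted on read/write via
:class:`TraceFileDialect`.

File layout (delimited text)::

    # qcmd-trace v1
    # surface_label: C8
    # frequency_convention: raw_hz
    # f0_hz: 5000000.0
    # Zq: 8800000.0
    # overtones: 3,5,7,9,11,13
    # baseline_start_h: 0.0
    # injection_h: 1.0
    # rinse_h: 47.5
    time_h,f3,D3,f5,D5,...,f13,D13
    0.0,0.0,0.0,...

Metadata lines are '#'-prefixed; event times are required either in the
header or through an explicit ``events`` argument / sidecar config.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, FormatError

__all__ = [
    "SensorParams",
    "QcmTrace",
    "TraceFileDialect",
    "read_trace",
    "write_trace",
    "load_experiment_config",
    "DEFAULT_OVERTONES",
]

DEFAULT_OVERTONES = (3, 5, 7, 9, 11, 13)

EVENT_NAMES = ("baseline_start", "injection", "rinse")


@dataclass(frozen=True)
class SensorParams:
    """Physical constants of the shear-mode quartz sensor.

    Parameters
    ----------
    f0:
        Fundamental resonance frequency in Hz.  AT-cut sensors used for
        bioadhesion work typically resonate at 5 MHz.
    Zq:
        Shear-wave acoustic impedance of AT-cut quartz, kg m^-2 s^-1.
    overtones:
        Ordered list of measured odd overtone numbers.
    """

    f0: float = 5.0e6
    Zq: float = 8.8e6
    overtones: tuple[int, ...] = DEFAULT_OVERTONES

    def __post_init__(self):
        if not self.f0 > 0:
            raise ValueError("f0 must be positive")
        if not self.Zq > 0:
            raise ValueError("Zq must be positive")
        ots = tuple(int(n) for n in self.overtones)
        if len(ots) == 0:
            raise ValueError("at least one overtone is required")
        if any(n < 1 or n % 2 == 0 for n in ots):
            raise ValueError("overtones must be odd integers >= 1")
        if any(b <= a for a, b in zip(ots, ots[1:])):
            raise ValueError("overtones must be strictly increasing")
        object.__setattr__(self, "overtones", ots)

    def angular_frequency(self, n: int) -> float:
        """Angular measurement frequency 2*pi*n*f0 of overtone ``n``."""
        return 2.0 * np.pi * n * self.f0


@dataclass(frozen=True)
class TraceFileDialect:
    """How a delimited trace export encodes its numbers.

    ``frequency_convention`` is either ``"raw_hz"`` (file stores Delta f at
    the overtone) or ``"normalized_hz"`` (file stores Delta f / n; values are
    multiplied by n on read and divided by n on write).
    """

    delimiter: str = ","
    frequency_convention: str = "raw_hz"

    def __post_init__(self):
        if self.frequency_convention not in ("raw_hz", "normalized_hz"):
            raise ValueError(
                f"unknown frequency convention {self.frequency_convention!r}"
            )

    def f_column(self, n: int) -> str:
        return f"f{n}"

    def d_column(self, n: int) -> str:
        return f"D{n}"


@dataclass
class QcmTrace:
    """A time-indexed multi-overtone QCM-D experiment.

    ``df`` and ``dd`` are (time x overtone) matrices of raw frequency shift
    (Hz) and dissipation shift (ppm); columns follow ``sensor.overtones``.
    ``events`` maps ``baseline_start`` < ``injection`` < ``rinse`` to hours.
    """

    time: np.ndarray
    df: np.ndarray
    dd: np.ndarray
    events: dict[str, float]
    sensor: SensorParams = field(default_factory=SensorParams)
    surface_label: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.df = np.asarray(self.df, dtype=float)
        self.dd = np.asarray(self.dd, dtype=float)
        if self.time.ndim != 1 or len(self.time) < 2:
            raise DataError("time must be a 1-D vector with >= 2 samples")
        if np.any(np.diff(self.time) <= 0):
            raise DataError("time must be strictly increasing")
        n_ot = len(self.sensor.overtones)
        if self.df.shape != (len(self.time), n_ot):
            raise DataError(
                f"df has shape {self.df.shape}, expected "
                f"({len(self.time)}, {n_ot})"
            )
        if self.dd.shape != self.df.shape:
            raise DataError("df and dd must share the same shape")
        missing = [k for k in EVENT_NAMES if k not in self.events]
        if missing:
            raise DataError(f"missing event annotations: {missing}")
        b, i, r = (self.events[k] for k in EVENT_NAMES)
        if not (b < i < r):
            raise DataError(
                "events must be ordered baseline_start < injection < rinse"
            )
        t0, t1 = self.time[0], self.time[-1]
        for k in EVENT_NAMES:
            if not (t0 <= self.events[k] <= t1):
                raise DataError(f"event {k!r} lies outside the time range")

    def overtone_index(self, n: int) -> int:
        try:
            return self.sensor.overtones.index(n)
        except ValueError:
            raise DataError(f"overtone {n} not measured in this trace") from None

    def column(self, channel: str, n: int) -> np.ndarray:
        """Return the df ('f') or dd ('D') series of overtone ``n``."""
        j = self.overtone_index(n)
        if channel == "f":
            return self.df[:, j]
        if channel == "D":
            return self.dd[:, j]
        raise ValueError("channel must be 'f' or 'D'")


def _format_float(x: float) -> str:
    # repr gives the shortest decimal string that round-trips binary64
    return repr(float(x))


def write_trace(trace: QcmTrace, path, dialect: TraceFileDialect | None = None) -> None:
    """Write ``trace`` as delimited text parseable by :func:`read_trace`.

    Floats are written with round-trip precision, so a raw-dialect
    write/read cycle is bit-identical.
    """
    dialect = dialect or TraceFileDialect()
    sep = dialect.delimiter
    cols = ["time_h"]
    for n in trace.sensor.overtones:
        cols += [dialect.f_column(n), dialect.d_column(n)]
    lines = [
        "# qcmd-trace v1",
        f"# surface_label: {trace.surface_label}",
        f"# frequency_convention: {dialect.frequency_convention}",
        f"# f0_hz: {_format_float(trace.sensor.f0)}",
        f"# Zq: {_format_float(trace.sensor.Zq)}",
        "# overtones: " + ",".join(str(n) for n in trace.sensor.overtones),
    ]
    for k in EVENT_NAMES:
        lines.append(f"# {k}_h: {_format_float(trace.events[k])}")
    lines.append(sep.join(cols))

    df_out = trace.df
    if dialect.frequency_convention == "normalized_hz":
        df_out = trace.df / np.asarray(trace.sensor.overtones, dtype=float)
    for i in range(len(trace.time)):
        row = [_format_float(trace.time[i])]
        for j in range(len(trace.sensor.overtones)):
            row.append(_format_float(df_out[i, j]))
            row.append(_format_float(trace.dd[i, j]))
        lines.append(sep.join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_header(text: str) -> dict[str, str]:
    meta = {}
    for line in text.splitlines():
        if not line.startswith("#"):
            continue
        body = line.lstrip("#").strip()
        if ":" in body:
            key, _, value = body.partition(":")
            meta[key.strip()] = value.strip()
    return meta


def read_trace(
    path,
    dialect: TraceFileDialect | None = None,
    sensor: SensorParams | None = None,
    events: Mapping[str, float] | None = None,
) -> QcmTrace:
    """Read a delimited trace export into canonical units.

    Units on return are raw Hz at the overtone, ppm and hours regardless of
    the stored convention.  ``dialect``, ``sensor`` and ``events`` override
    whatever the file header declares.
    """
    path = Path(path)
    text = path.read_text()
    meta = _parse_header(text)

    if dialect is None:
        conv = meta.get("frequency_convention", "raw_hz")
        dialect = TraceFileDialect(frequency_convention=conv)
    if sensor is None:
        kwargs = {}
        if "f0_hz" in meta:
            kwargs["f0"] = float(meta["f0_hz"])
        if "Zq" in meta:
            kwargs["Zq"] = float(meta["Zq"])
        if "overtones" in meta:
            kwargs["overtones"] = tuple(
                int(s) for s in meta["overtones"].split(",") if s.strip()
            )
        sensor = SensorParams(**kwargs)
    if events is None:
        events = {}
        for k in EVENT_NAMES:
            if f"{k}_h" in meta:
                events[k] = float(meta[f"{k}_h"])
        missing = [k for k in EVENT_NAMES if k not in events]
        if missing:
            raise FormatError(
                f"{path.name}: event annotations {missing} missing from "
                "header; pass events= or a sidecar config"
            )

    table = pd.read_csv(
        _stdio.StringIO(text),
        sep=dialect.delimiter,
        comment="#",
        float_precision="round_trip",
    )
    required = ["time_h"]
    for n in sensor.overtones:
        required += [dialect.f_column(n), dialect.d_column(n)]
    for col in required:
        if col not in table.columns:
            raise FormatError(f"{path.name}: missing required column {col!r}")

    time = table["time_h"].to_numpy(dtype=float)
    if np.any(np.diff(time) <= 0):
        raise DataError(f"{path.name}: time_h is not strictly increasing")
    df = np.column_stack(
        [table[dialect.f_column(n)].to_numpy(dtype=float) for n in sensor.overtones]
    )
    dd = np.column_stack(
        [table[dialect.d_column(n)].to_numpy(dtype=float) for n in sensor.overtones]
    )
    if dialect.frequency_convention == "normalized_hz":
        df = df * np.asarray(sensor.overtones, dtype=float)
    return QcmTrace(
        time=time,
        df=df,
        dd=dd,
        events=dict(events),
        sensor=sensor,
        surface_label=meta.get("surface_label", ""),
    )


def load_experiment_config(path) -> dict:
    """Load a YAML/JSON sidecar config.

    Recognized keys: ``sensor`` (f0, Zq, overtones), ``dialect`` (delimiter,
    frequency_convention) and ``events`` (baseline_start, injection, rinse,
    hours).  Returns ``{"sensor": SensorParams, "dialect": TraceFileDialect,
    "events": dict}`` with defaults filled in.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sensor_kwargs = dict(raw.get("sensor", {}))
    if "overtones" in sensor_kwargs:
        sensor_kwargs["overtones"] = tuple(sensor_kwargs["overtones"])
    sensor = SensorParams(**sensor_kwargs)
    dialect = TraceFileDialect(**raw.get("dialect", {}))
    events = {k: float(v) for k, v in raw.get("events", {}).items()}
    return {"sensor": sensor, "dialect": dialect, "events": events}
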