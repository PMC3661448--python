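"""Signal container and delimited-text I/O for EPG recordings.

A :class:`Trace` holds a uniformly sampled single-channel voltage signal in
millivolts together with its sampling rate, start time, a free-text label and
an optional :class:`ConditionSchedule` describing stimulation/drug epochs.

Traces are stored on disk in the ``csv_2col`` dialect: ``#``-prefixed
metadata comment lines, then a ``time_s,signal_mV`` header and one row per
sample.  Values are written with shortest round-trip float formatting so that
``read_trace(write_trace(t)) == t`` bit-exactly for the samples.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_CONDITIONS",
    "ConditionSchedule",
    "Trace",
    "read_trace",
    "write_trace",
]

#: Condition labels with built-in schedule-effect semantics.  Custom labels
#: are allowed anywhere a label is accepted.
CANONICAL_CONDITIONS = frozenset(
    {"baseline", "5HT", "ethanol", "light_on", "light_off", "custom"}
)

#: Relative tolerance on the sampling grid used by :func:`read_trace`.
UNIFORMITY_RTOL = 1e-6


@dataclass
class ConditionSchedule:
    """Sorted, non-overlapping ``(start_s, end_s, condition_label)`` intervals."""

    intervals: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        norm = []
        for iv in self.intervals:
            start, end, label = iv
            start, end, label = float(start), float(end), str(label)
            if not (math.isfinite(start) and math.isfinite(end)):
                raise ValueError(f"non-finite schedule interval {iv!r}")
            if end <= start:
                raise ValueError(f"schedule interval has end <= start: {iv!r}")
            norm.append((start, end, label))
        for a, b in zip(norm, norm[1:]):
            if b[0] < a[1]:
                raise ValueError(
                    f"schedule intervals overlap or are unsorted: {a!r} then {b!r}"
                )
        self.intervals = norm

    def validate_within(self, t0: float, duration: float) -> None:
        for start, end, label in self.intervals:
            if start < t0 - 1e-9 or end > t0 + duration + 1e-9:
                raise ValueError(
                    f"schedule interval ({start}, {end}, {label!r}) outside "
                    f"trace span [{t0}, {t0 + duration}]"
                )

    def condition_at(self, t: float) -> Optional[str]:
        for start, end, label in self.intervals:
            if start <= t < end:
                return label
        return None

    def boundaries(self) -> list[float]:
        """All interval edges, sorted (used to exclude boundary-spanning gaps)."""
        edges: set[float] = set()
        for start, end, _ in self.intervals:
            edges.add(start)
            edges.add(end)
        return sorted(edges)

    def to_json(self) -> str:
        return json.dumps([[s, e, lbl] for s, e, lbl in self.intervals])

    @classmethod
    def from_json(cls, text: str) -> "ConditionSchedule":
        raw = json.loads(text)
        return cls([(float(s), float(e), str(lbl)) for s, e, lbl in raw])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConditionSchedule):
            return NotImplemented
        return self.intervals == other.intervals


@dataclass
class Trace:
    """Uniformly sampled voltage signal (mV) with metadata.

    Parameters
    ----------
    samples:
        Voltage samples in millivolts; all finite, length >= 2.
    sampling_rate:
        Samples per second, > 0.
    t0:
        Time of the first sample in seconds.
    label:
        Free-text strain/condition label.
    schedule:
        Optional condition schedule; must lie within the trace span.
    """

    samples: np.ndarray
    sampling_rate: float
    t0: float = 0.0
    label: str = ""
    schedule: Optional[ConditionSchedule] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size < 2:
            raise ValueError("trace needs at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")
        self.sampling_rate = float(self.sampling_rate)
        if not (self.sampling_rate > 0 and math.isfinite(self.sampling_rate)):
            raise ValueError("sampling_rate must be positive and finite")
        self.t0 = float(self.t0)
        if self.schedule is not None:
            self.schedule.validate_within(self.t0, self.duration)

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Trace length in seconds (n / rate)."""
        return self.n / self.sampling_rate

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.sampling_rate

    def time_to_index(self, t: float) -> int:
        """Nearest sample index for time ``t``, clipped to the trace."""
        i = int(round((t - self.t0) * self.sampling_rate))
        return min(max(i, 0), self.n - 1)

    def replace_samples(self, samples: np.ndarray) -> "Trace":
        return Trace(
            samples=samples,
            sampling_rate=self.sampling_rate,
            t0=self.t0,
            label=self.label,
            schedule=self.schedule,
        )


def write_trace(trace: Trace, path: str | os.PathLike) -> None:
    """Write ``trace`` in the csv_2col dialect.

    Metadata goes into ``#`` comment lines (label, sampling rate and, when
    non-empty, the schedule serialized as JSON on a single line).
    """
    header_lines = []
    if trace.label:
        header_lines.append(f"# label: {trace.label}")
    header_lines.append(f"# sampling_rate_hz: {trace.sampling_rate!r}")
    if trace.schedule is not None and trace.schedule.intervals:
        header_lines.append(f"# schedule: {trace.schedule.to_json()}")
    df = pd.DataFrame({"time_s": trace.times, "signal_mV": trace.samples})
    try:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write("\n".join(header_lines) + "\n")
            # str() on float64 is shortest round-trip formatting
            df.to_csv(fh, index=False)
    except OSError as exc:
        raise OSError(f"cannot write trace to {path!r}: {exc}") from exc


def _read_metadata(path: str | os.PathLike) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    return meta


def read_trace(path: str | os.PathLike, dialect: str = "csv_2col") -> Trace:
    """Read a csv_2col trace file.

    The sampling rate is taken from the ``sampling_rate_hz`` header when
    present, otherwise inferred from the median time step.  The time column
    must be strictly increasing and uniform to within a relative tolerance of
    1e-6; the first offending timestamp index is reported otherwise.
    """
    if dialect != "csv_2col":
        raise ValueError(f"unknown trace dialect {dialect!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(f"trace file not found: {path!r}")
    meta = _read_metadata(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = {"time_s", "signal_mV"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path!r}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    for col in ("time_s", "signal_mV"):
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            row = int(bad.idxmax()) if bad.any() else int(coerced.isna().idxmax())
            raise ValueError(
                f"{path!r}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r} at data row {row}"
            )
    t = df["time_s"].to_numpy(dtype=np.float64)
    x = df["signal_mV"].to_numpy(dtype=np.float64)
    if t.size < 2:
        raise ValueError(f"{path!r}: need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        idx = int(np.argmax(dt <= 0)) + 1
        raise ValueError(f"{path!r}: time not strictly increasing at index {idx}")
    dt_med = float(np.median(dt))
    rel = np.abs(dt - dt_med) / dt_med
    if np.any(rel > UNIFORMITY_RTOL):
        idx = int(np.argmax(rel > UNIFORMITY_RTOL)) + 1
        raise ValueError(
            f"{path!r}: non-uniform sampling at index {idx} "
            f"(dt={dt[idx - 1]!r}, median dt={dt_med!r})"
        )
    if "sampling_rate_hz" in meta:
        rate = float(meta["sampling_rate_hz"])
    else:
        rate = 1.0 / dt_med
    schedule = None
    if "schedule" in meta:
        schedule = ConditionSchedule.from_json(meta["schedule"])
    return Trace(
        samples=x,
        sampling_rate=rate,
        t0=float(t[0]),
        label=meta.get("label", ""),
        schedule=schedule,
    )
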