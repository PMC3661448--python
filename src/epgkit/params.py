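"""Per-recording EPG summary parameters, time courses and group statistics.

The seven summary metrics are computed per recording (one worm) and
averaged across worms downstream — the worm, never the pump, is the unit of
replication for group statistics.
"""

from __future__ import annotations

import json
import math
import warnings as _warnings
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .detect import EventTable
from .trace import ConditionSchedule, Trace

__all__ = [
    "EPGParameters",
    "TimeCourse",
    "GroupComparison",
    "compute_parameters",
    "frequency_timecourse",
    "epoch_summary",
    "compare_groups",
]


@dataclass
class EPGParameters:
    """The seven per-recording EPG metrics plus counts.

    ``None`` marks a metric that could not be measured (e.g. no pump with a
    detected e spike).
    """

    worm_id: str = ""
    n_pumps: int = 0
    analyzed_s: float = 0.0
    amp_pp: Optional[float] = None  # mV, mean per-pump a_E - a_R
    frequency: Optional[float] = None  # pumps/s, n_pumps / analyzed_s
    duration: Optional[float] = None  # s, mean peak-E-to-peak-R
    re_interval: Optional[float] = None  # s, mean R-to-next-E gap
    p_per_pump: Optional[float] = None  # total P waves / n_pumps
    e_amp: Optional[float] = None  # mV, mean over pumps with a detected e
    re_ratio: Optional[float] = None  # mean |a_R| / a_E

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


@dataclass
class TimeCourse:
    """Contiguous fixed-width bins of pump frequency and mean duration."""

    bin_start_s: np.ndarray
    bin_width: float
    frequency: np.ndarray  # pumps/s per bin
    duration: np.ndarray  # mean s per bin, NaN when the bin is empty
    counts: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start_s": self.bin_start_s,
                "frequency": self.frequency,
                "duration": self.duration,
                "count": self.counts,
            }
        )


@dataclass
class GroupComparison:
    metric: str
    t_stat: float
    p_value: float
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    n_a: int
    n_b: int


def compute_parameters(
    events: EventTable,
    trace: Optional[Trace] = None,
    analyzed_s: Optional[float] = None,
) -> EPGParameters:
    """Summarize an event table into the seven EPG parameters.

    ``analyzed_s`` defaults to the trace duration (or the event table's
    metadata).  Inter-pump R-to-E gaps that span a condition-schedule
    boundary are excluded from ``re_interval`` so wash-in transients do not
    bias the interval statistics.
    """
    if analyzed_s is None:
        analyzed_s = trace.duration if trace is not None else events.analyzed_s
    wid = events.worm_id
    pumps = sorted(events.pumps, key=lambda p: p.t_E)
    out = EPGParameters(worm_id=wid, n_pumps=len(pumps), analyzed_s=float(analyzed_s))
    if analyzed_s and analyzed_s > 0:
        out.frequency = len(pumps) / analyzed_s
    if not pumps:
        return out
    out.amp_pp = float(np.mean([p.amp_pp for p in pumps]))
    out.duration = float(np.mean([p.duration for p in pumps]))
    out.re_ratio = float(np.mean([abs(p.a_R) / p.a_E for p in pumps]))
    out.p_per_pump = float(sum(p.n_P for p in pumps) / len(pumps))
    e_vals = [p.a_e for p in pumps if p.a_e is not None]
    out.e_amp = float(np.mean(e_vals)) if e_vals else None
    if len(pumps) >= 2:
        boundaries = []
        if trace is not None and trace.schedule is not None:
            boundaries = trace.schedule.boundaries()
        gaps = []
        for prev, nxt in zip(pumps, pumps[1:]):
            if any(prev.t_R < b < nxt.t_E for b in boundaries):
                continue
            gaps.append(nxt.t_E - prev.t_R)
        out.re_interval = float(np.mean(gaps)) if gaps else None
    return out


def frequency_timecourse(
    events: EventTable,
    bin_width: float,
    t_start: Optional[float] = None,
    t_end: Optional[float] = None,
) -> TimeCourse:
    """Bin pumps by their E-peak time into contiguous fixed-width bins."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    pumps = sorted(events.pumps, key=lambda p: p.t_E)
    if t_start is None:
        t_start = 0.0 if not pumps else math.floor(pumps[0].t_E / bin_width) * bin_width
    if t_end is None:
        span = events.analyzed_s if math.isfinite(events.analyzed_s) else 0.0
        t_end = max(t_start + span, pumps[-1].t_E + bin_width if pumps else t_start + bin_width)
    n_bins = max(1, int(math.ceil((t_end - t_start) / bin_width - 1e-9)))
    starts = t_start + bin_width * np.arange(n_bins)
    counts = np.zeros(n_bins)
    dur_sum = np.zeros(n_bins)
    for p in pumps:
        b = int((p.t_E - t_start) / bin_width)
        if 0 <= b < n_bins:
            counts[b] += 1
            dur_sum[b] += p.duration
    freq = counts / bin_width
    with np.errstate(invalid="ignore", divide="ignore"):
        dur = np.where(counts > 0, dur_sum / np.maximum(counts, 1), np.nan)
    return TimeCourse(
        bin_start_s=starts, bin_width=bin_width,
        frequency=freq, duration=dur, counts=counts,
    )


def epoch_summary(tc: TimeCourse, schedule: ConditionSchedule) -> pd.DataFrame:
    """Mean frequency and duration per labeled schedule interval.

    A bin belongs to an interval when its centre falls inside it.  Intervals
    covering no bins produce a NaN row with a warning.
    """
    rows = []
    centres = tc.bin_start_s + tc.bin_width / 2.0
    for start, end, label in schedule.intervals:
        inside = (centres >= start) & (centres < end)
        if not np.any(inside):
            _warnings.warn(
                f"schedule interval ({start}, {end}, {label!r}) covers no bins"
            )
            rows.append(
                {"condition": label, "start_s": start, "end_s": end,
                 "n_bins": 0, "mean_frequency": np.nan, "mean_duration": np.nan}
            )
            continue
        freq = float(np.mean(tc.frequency[inside]))
        durs = tc.duration[inside]
        dur = float(np.nanmean(durs)) if np.any(~np.isnan(durs)) else np.nan
        rows.append(
            {"condition": label, "start_s": start, "end_s": end,
             "n_bins": int(inside.sum()), "mean_frequency": freq,
             "mean_duration": dur}
        )
    return pd.DataFrame(rows)


def compare_groups(
    a: Sequence[EPGParameters],
    b: Sequence[EPGParameters],
    metric: str,
) -> GroupComparison:
    """Welch two-sample t-test on a per-worm metric.

    Worms whose metric is missing are excluded with a warning; each group
    must retain at least two worms.
    """
    def _values(group, name):
        vals = []
        for p in group:
            v = getattr(p, metric)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                _warnings.warn(f"{name}: worm {p.worm_id!r} missing {metric}, excluded")
                continue
            vals.append(float(v))
        return np.array(vals)

    va = _values(a, "group a")
    vb = _values(b, "group b")
    if va.size < 2 or vb.size < 2:
        raise ValueError("need >= 2 worms with the metric in each group")
    if np.ptp(va) == 0 and np.ptp(vb) == 0 and va[0] == vb[0]:
        t_stat, p_value = 0.0, 1.0  # identical degenerate groups
    else:
        t_stat, p_value = stats.ttest_ind(va, vb, equal_var=False)
    return GroupComparison(
        metric=metric,
        t_stat=float(t_stat),
        p_value=float(p_value),
        mean_a=float(va.mean()),
        sem_a=float(va.std(ddof=1) / math.sqrt(va.size)),
        mean_b=float(vb.mean()),
        sem_b=float(vb.std(ddof=1) / math.sqrt(vb.size)),
        n_a=int(va.size),
        n_b=int(vb.size),
    )
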