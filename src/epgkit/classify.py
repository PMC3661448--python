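"""Wild-type reference bounds and worm-sorting by EPG signature.

A worm is called mutant when its mean pump duration exceeds the upper
duration bound AND its P-wave count per pump falls below the lower P bound
(strict inequalities; the conjunction is the default decision rule, the
disjunction is available as a config option).  Bounds are either given
explicitly — the published screening constants are duration > 0.1445 s and
P/pump < 0.169 — or fitted as mean +/- k standard deviations across a
wild-type reference group.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np

from .detect import DetectionConfig, detect_pumps, orientation_gate
from .params import EPGParameters, compute_parameters
from .preprocess import FilterSpec, highpass
from .trace import Trace

__all__ = [
    "MetricBounds",
    "ReferenceBounds",
    "Thresholds",
    "SCREEN_THRESHOLDS",
    "Verdict",
    "ScreenReport",
    "fit_reference",
    "classify",
    "screen_cohort",
]

#: Decision metrics; only the duration upper bound and the P-per-pump lower
#: bound are active (the mutant phenotype direction).
DECISION_METRICS = ("duration", "p_per_pump")


@dataclass(frozen=True)
class MetricBounds:
    mean: float
    sd: float
    k: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")


@dataclass
class ReferenceBounds:
    metrics: dict[str, MetricBounds]
    n_worms: int = 0
    source: str = ""

    @property
    def thresholds(self) -> "Thresholds":
        return Thresholds(
            duration_upper=self.metrics["duration"].upper,
            p_per_pump_lower=self.metrics["p_per_pump"].lower,
        )


@dataclass(frozen=True)
class Thresholds:
    """Explicit one-sided decision thresholds."""

    duration_upper: float = 0.1445  # s
    p_per_pump_lower: float = 0.169


#: Published screening constants (duration upper bound, P/pump lower bound).
SCREEN_THRESHOLDS = Thresholds()


@dataclass
class Verdict:
    worm_id: str
    label: str  # wild_type | mutant | unclassifiable
    duration_out: Optional[bool] = None
    p_out: Optional[bool] = None
    duration: Optional[float] = None
    p_per_pump: Optional[float] = None
    n_pumps: int = 0
    rule: str = "conjunction"
    thresholds: Optional[Thresholds] = None
    reason: str = ""

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.thresholds is not None:
            d["thresholds"] = asdict(self.thresholds)
        return d


def fit_reference(
    wild_type_params: Sequence[EPGParameters],
    k: float = 3.0,
    metrics: Sequence[str] = DECISION_METRICS,
    source: str = "",
) -> ReferenceBounds:
    """Per-metric mean and sample standard deviation across >= 3 worms;
    bounds at mean +/- k sd."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if len(wild_type_params) < 3:
        raise ValueError("need >= 3 reference worms for reliable bounds")
    out: dict[str, MetricBounds] = {}
    for m in metrics:
        vals = np.array(
            [getattr(p, m) for p in wild_type_params if getattr(p, m) is not None],
            dtype=float,
        )
        if vals.size < 3:
            raise ValueError(f"metric {m!r} available for fewer than 3 worms")
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        out[m] = MetricBounds(mean=mean, sd=sd, k=k,
                              lower=mean - k * sd, upper=mean + k * sd)
    return ReferenceBounds(metrics=out, n_worms=len(wild_type_params), source=source)


def classify(
    params: EPGParameters,
    bounds: Optional[ReferenceBounds] = None,
    thresholds: Optional[Thresholds] = None,
    rule: str = "conjunction",
    min_pumps: int = 5,
) -> Verdict:
    """Sort one worm against the reference bounds.

    ``duration_out`` is duration strictly greater than the upper bound;
    ``p_out`` is P/pump strictly below the lower bound.  The worm is mutant
    when both flags hold (conjunction, default) or either does
    (disjunction).  Worms with fewer than ``min_pumps`` pumps are
    unclassifiable.
    """
    if rule not in ("conjunction", "disjunction"):
        raise ValueError(f"unknown decision rule {rule!r}")
    if thresholds is None:
        thresholds = bounds.thresholds if bounds is not None else SCREEN_THRESHOLDS
    v = Verdict(
        worm_id=params.worm_id, label="unclassifiable", rule=rule,
        thresholds=thresholds, n_pumps=params.n_pumps,
        duration=params.duration, p_per_pump=params.p_per_pump,
    )
    if params.n_pumps < min_pumps:
        v.reason = f"only {params.n_pumps} pumps (< {min_pumps})"
        return v
    if params.duration is None or params.p_per_pump is None:
        v.reason = "decision metrics missing"
        return v
    v.duration_out = params.duration > thresholds.duration_upper
    v.p_out = params.p_per_pump < thresholds.p_per_pump_lower
    if rule == "conjunction":
        mutant = v.duration_out and v.p_out
    else:
        mutant = v.duration_out or v.p_out
    v.label = "mutant" if mutant else "wild_type"
    return v


@dataclass
class ScreenReport:
    verdicts: list[Verdict]
    n_analyzed: int
    n_rejected: int
    n_wild_type: int
    n_mutant: int
    n_unclassifiable: int
    rule: str
    thresholds: Thresholds
    confusion: Optional[dict] = None  # {"tp":..,"fp":..,"fn":..,"tn":..}

    def to_dict(self) -> dict:
        return {
            "rule": self.rule,
            "thresholds": asdict(self.thresholds),
            "counts": {
                "analyzed": self.n_analyzed,
                "rejected": self.n_rejected,
                "wild_type": self.n_wild_type,
                "mutant": self.n_mutant,
                "unclassifiable": self.n_unclassifiable,
            },
            "confusion": self.confusion,
            "verdicts": [v.to_dict() for v in self.verdicts],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def screen_cohort(
    traces: Sequence[Trace],
    thresholds: Optional[Thresholds] = None,
    bounds: Optional[ReferenceBounds] = None,
    cfg: DetectionConfig = DetectionConfig(),
    filter_spec: Optional[FilterSpec] = FilterSpec(),
    rule: str = "conjunction",
    min_pumps: int = 5,
    reference_amp: float = 4.410,
    worm_ids: Optional[Sequence[str]] = None,
    true_labels: Optional[Sequence[str]] = None,
    mutant_classes: Sequence[str] = ("mutant", "eat4", "eat4_chip", "eat4_conventional"),
) -> ScreenReport:
    """Run the full per-worm pipeline (gate -> detect -> parameters ->
    classify) over a cohort and tally verdicts.

    Worms failing the orientation gate are counted as rejected and excluded
    from the confusion matrix.  Per-worm failures never abort the run.
    """
    if len(traces) == 0:
        raise ValueError("empty cohort")
    if thresholds is None:
        thresholds = bounds.thresholds if bounds is not None else SCREEN_THRESHOLDS
    if worm_ids is None:
        worm_ids = [f"worm{i:03d}" for i in range(len(traces))]
    verdicts: list[Verdict] = []
    rejected = 0
    confusion = {"tp": 0, "fp": 0, "fn": 0, "tn": 0} if true_labels is not None else None
    for i, trace in enumerate(traces):
        wid = worm_ids[i]
        try:
            work = highpass(trace, filter_spec) if filter_spec is not None else trace
            events = detect_pumps(work, cfg)
            events.worm_id = wid
            gate = orientation_gate(work, cfg, reference_amp=reference_amp, events=events)
            if gate.decision != "head":
                rejected += 1
                verdicts.append(
                    Verdict(worm_id=wid, label="unclassifiable", rule=rule,
                            thresholds=thresholds, reason=f"gate: {gate.reason}")
                )
                continue
            p = compute_parameters(events, work)
            p.worm_id = wid
            v = classify(p, thresholds=thresholds, rule=rule, min_pumps=min_pumps)
            verdicts.append(v)
            if confusion is not None and v.label in ("wild_type", "mutant"):
                truly_mutant = true_labels[i] in mutant_classes
                called_mutant = v.label == "mutant"
                key = {
                    (True, True): "tp",
                    (True, False): "fn",
                    (False, True): "fp",
                    (False, False): "tn",
                }[(truly_mutant, called_mutant)]
                confusion[key] += 1
        except Exception as exc:  # per-worm failure -> unclassifiable
            verdicts.append(
                Verdict(worm_id=wid, label="unclassifiable", rule=rule,
                        thresholds=thresholds, reason=f"error: {exc}")
            )
    labels = [v.label for v in verdicts]
    return ScreenReport(
        verdicts=verdicts,
        n_analyzed=len(traces) - rejected,
        n_rejected=rejected,
        n_wild_type=labels.count("wild_type"),
        n_mutant=labels.count("mutant"),
        n_unclassifiable=labels.count("unclassifiable") - rejected,
        rule=rule,
        thresholds=thresholds,
        confusion=confusion,
    )
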