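"""End-to-end convenience wrappers: simulate -> filter -> detect -> summarize.

Used by the CLI, the validation tests and the acceptance report.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .detect import DetectionConfig, EventTable, detect_pumps
from .params import EPGParameters, compute_parameters
from .preprocess import FilterSpec, highpass
from .synth import (
    DEFAULT_RATE,
    DEFAULT_SNR,
    PhenotypePreset,
    PumpKernelSpec,
    generate_trace,
    load_preset,
)
from .trace import Trace

__all__ = ["analyze_trace", "recover_preset", "grand_stats"]

RECOVERY_METRICS = ("frequency", "duration", "p_per_pump", "amp_pp", "e_amp", "re_ratio")


def analyze_trace(
    trace: Trace,
    filter_spec: Optional[FilterSpec] = FilterSpec(),
    cfg: DetectionConfig = DetectionConfig(),
    worm_id: str = "",
) -> tuple[EventTable, EPGParameters]:
    """High-pass, detect pumps and summarize one recording."""
    work = highpass(trace, filter_spec) if filter_spec is not None else trace
    events = detect_pumps(work, cfg)
    events.worm_id = worm_id
    params = compute_parameters(events, work)
    params.worm_id = worm_id
    return events, params


def recover_preset(
    preset: str | PhenotypePreset,
    n_worms: int,
    duration: float,
    seed: int,
    rate: float = DEFAULT_RATE,
    snr: float = DEFAULT_SNR,
    drift: bool = True,
    kernel: Optional[PumpKernelSpec] = None,
    filter_spec: Optional[FilterSpec] = FilterSpec(),
    cfg: DetectionConfig = DetectionConfig(),
) -> pd.DataFrame:
    """Simulate ``n_worms`` independent worms and run the full pipeline.

    Returns one row of recovered :class:`EPGParameters` per worm.
    """
    if isinstance(preset, str):
        preset = load_preset(preset)
    ss = np.random.SeedSequence(seed)
    rows = []
    for i, child in enumerate(ss.spawn(n_worms)):
        wid = f"worm{i:03d}"
        trace, _ = generate_trace(
            preset,
            kernel=kernel,
            duration=duration,
            rate=rate,
            snr=snr,
            seed=np.random.default_rng(child),
            drift=drift,
            worm_id=wid,
        )
        _, params = analyze_trace(trace, filter_spec=filter_spec, cfg=cfg, worm_id=wid)
        rows.append(params.to_dict())
    return pd.DataFrame(rows)


def grand_stats(per_worm: pd.DataFrame, metric: str) -> tuple[float, float]:
    """Across-worm mean and standard error of a per-worm metric."""
    vals = per_worm[metric].dropna().to_numpy(dtype=float)
    if vals.size == 0:
        raise ValueError(f"metric {metric!r} missing for every worm")
    sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else float("nan")
    return float(vals.mean()), sem
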