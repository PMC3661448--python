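"""Baseline-drift removal and signal-quality estimation.

Drift below the pumping band is removed with a zero-phase (forward-backward)
Bessel high-pass whose single-pass gain at the configured cutoff equals the
configured attenuation (default 0.5 Hz at -30 dB).  The corner frequency
needed to satisfy that constraint is solved numerically from the designed
filter's frequency response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal

from .trace import Trace

__all__ = [
    "FilterSpec",
    "design_sos",
    "frequency_response",
    "highpass",
    "estimate_baseline",
    "estimate_snr",
    "robust_sigma",
]

MAD_TO_SIGMA = 1.4826


@dataclass(frozen=True)
class FilterSpec:
    """High-pass specification: gain at ``cutoff`` is ``-attenuation_db`` dB.

    The conventional -3 dB reading of a published cutoff is one config change
    away (``attenuation_db=3``).
    """

    kind: str = "bessel_highpass"
    cutoff: float = 0.5
    attenuation_db: float = 30.0
    order: int = 4

    def __post_init__(self) -> None:
        if self.kind != "bessel_highpass":
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        if self.attenuation_db <= 0:
            raise ValueError("attenuation_db must be > 0")
        if not (2 <= self.order <= 8):
            raise ValueError("order must be in [2, 8]")


_SOS_CACHE: dict[tuple, np.ndarray] = {}


def design_sos(spec: FilterSpec, fs: float) -> np.ndarray:
    """Design the Bessel high-pass for sampling rate ``fs``.

    The corner parameter is bisected until the single-pass magnitude at
    ``spec.cutoff`` equals ``10**(-attenuation_db/20)``.
    """
    nyq = fs / 2.0
    if spec.cutoff >= nyq:
        raise ValueError(
            f"cutoff {spec.cutoff} Hz is at or above Nyquist ({nyq} Hz)"
        )
    key = (spec.cutoff, spec.attenuation_db, spec.order, fs)
    if key in _SOS_CACHE:
        return _SOS_CACHE[key]
    target = 10.0 ** (-spec.attenuation_db / 20.0)

    def gain_at_cutoff(wn: float) -> float:
        sos = signal.bessel(spec.order, wn, "highpass", output="sos", norm="mag", fs=fs)
        _, h = signal.sosfreqz(sos, worN=[spec.cutoff], fs=fs)
        return float(np.abs(h[0]))

    lo = spec.cutoff  # -3 dB at the cutoff itself: gain above target
    hi = min(spec.cutoff * 50.0, nyq * 0.99)
    if gain_at_cutoff(hi) > target:
        raise ValueError(
            "cannot reach the requested attenuation below Nyquist; "
            "raise the order or lower the cutoff"
        )
    for _ in range(80):
        mid = math.sqrt(lo * hi)  # bisect in log-frequency
        if gain_at_cutoff(mid) > target:
            lo = mid
        else:
            hi = mid
    wn = math.sqrt(lo * hi)
    sos = signal.bessel(spec.order, wn, "highpass", output="sos", norm="mag", fs=fs)
    _SOS_CACHE[key] = sos
    return sos


def frequency_response(
    spec: FilterSpec, freqs: np.ndarray, fs: float
) -> np.ndarray:
    """Single-pass magnitude response of the designed filter at ``freqs`` (Hz)."""
    sos = design_sos(spec, fs)
    _, h = signal.sosfreqz(sos, worN=np.atleast_1d(freqs).astype(float), fs=fs)
    return np.abs(h)


def highpass(trace: Trace, spec: FilterSpec = FilterSpec()) -> Trace:
    """Apply the high-pass forward and backward (zero phase, no peak shift)."""
    sos = design_sos(spec, trace.sampling_rate)
    filtered = signal.sosfiltfilt(sos, trace.samples)
    return trace.replace_samples(filtered)


def estimate_baseline(
    trace: Trace | np.ndarray,
    window: float = 2.0,
    rate: Optional[float] = None,
) -> np.ndarray:
    """Running-median baseline, same length as the input.

    For long windows the median is computed on a decimated copy (the baseline
    band is far below the decimated Nyquist) and linearly interpolated back.
    """
    if isinstance(trace, Trace):
        x = trace.samples
        rate = trace.sampling_rate
    else:
        x = np.asarray(trace, dtype=np.float64)
        if rate is None:
            raise ValueError("rate is required when passing a bare array")
    w = int(round(window * rate))
    if w < 3:
        raise ValueError(f"baseline window of {w} samples is too short (< 3)")
    if w < 75:
        return (
            pd.Series(x)
            .rolling(w if w % 2 else w + 1, center=True, min_periods=1)
            .median()
            .to_numpy()
        )
    # the baseline band is far below the decimated Nyquist: ~25 support
    # points per window are ample
    dec = max(1, w // 25)
    xs = x[::dec]
    ws = max(3, w // dec)
    if ws % 2 == 0:
        ws += 1
    from scipy import ndimage

    med = ndimage.median_filter(xs, size=ws, mode="nearest")
    idx = np.arange(xs.size) * dec
    return np.interp(np.arange(x.size), idx, med)


def robust_sigma(x: np.ndarray) -> float:
    """1.4826 x median absolute deviation from the median."""
    x = np.asarray(x)
    if x.size == 0:
        return 0.0
    return MAD_TO_SIGMA * float(np.median(np.abs(x - np.median(x))))


def estimate_snr(trace: Trace, events=None, config=None) -> float:
    """Signal-to-noise ratio: median per-pump peak-to-peak amplitude over the
    robust noise sigma of samples outside all pump windows.

    A pump window is ``[t_E - 50 ms, t_r + 50 ms]`` (``t_R`` when no r spike
    was labeled).  When ``events`` is omitted, pumps are detected first with
    default settings (the trace must then be at least 10 s long).  Returns
    ``math.inf`` for noise-free signals; raises when no pump is available.
    """
    from .detect import DetectionConfig, detect_pumps  # circular at module level

    if events is None:
        if trace.duration < 10.0:
            raise ValueError("need >= 10 s of signal to estimate SNR without events")
        events = detect_pumps(trace, config or DetectionConfig())
    if len(events.pumps) == 0:
        raise ValueError("SNR undefined: no pumps detected and none supplied")
    rate = trace.sampling_rate
    mask = np.ones(trace.n, dtype=bool)
    amps = []
    for p in events.pumps:
        t_hi = p.t_r if p.t_r is not None else p.t_R
        i0 = max(0, int(math.floor((p.t_E - 0.050 - trace.t0) * rate)))
        i1 = min(trace.n, int(math.ceil((t_hi + 0.050 - trace.t0) * rate)) + 1)
        mask[i0:i1] = False
        amps.append(p.a_E - p.a_R)
    out = trace.samples[mask]
    if out.size < 10:
        raise ValueError("not enough out-of-pump samples to estimate noise")
    sigma = robust_sigma(out)
    amp = float(np.median(amps))
    if sigma == 0.0:
        return math.inf
    return amp / sigma
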