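"""Pump segmentation and five-phase labeling.

The detector works on a baseline-subtracted, lightly smoothed copy of the
trace (zero-phase Gaussian smoothing matched to the expected transient
widths) so that thresholds expressed in noise-sigma multiples remain
meaningful down to the device's SNR floor.  Candidate E (positive) and R
(negative) extrema are paired, conflicts resolved greedily by combined spike
magnitude, and the small transients (e before E, P waves in the plateau, r
after R) are labeled inside per-pump search windows.

Amplitudes are estimated by least-squares projection of the raw
baseline-subtracted signal onto a unit-peak Gaussian template of the
expected width centred on the detected extremum — a matched-filter estimate
that is unbiased at any noise level when the template width matches the
transient, unlike the raw sample value at a noisy argmax.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage, signal as sp_signal

from .preprocess import estimate_baseline, robust_sigma
from .trace import Trace

__all__ = [
    "DetectionConfig",
    "PumpEvent",
    "EventTable",
    "GateResult",
    "detect_pumps",
    "orientation_gate",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholds (in noise-sigma multiples of the smoothed working signal)
    and search windows for pump detection and phase labeling."""

    spike_threshold_k: float = 5.0
    p_threshold_k: float = 4.0
    confirm_k: float = 2.5  # matched-filter amplitude floor for E/R, in
    # units of the fitted-amplitude noise; rejects shelf-riding junk peaks
    p_rel_floor: float = 0.10  # P waves smaller than this fraction of the
    # median pump span are filter-undershoot artefacts, not M3 transients
    min_inter_pump: float = 0.05
    max_ER_interval: float = 0.5
    e_search_window: tuple[float, float] = (0.005, 0.060)  # s before t_E
    r_search_window: tuple[float, float] = (0.005, 0.120)  # s after t_R
    p_exclusion_radius: float = 0.010  # s around t_R
    p_merge_window: float = 0.004  # P minima closer than this are merged
    smooth_sigma_s: float = 0.002  # 0 disables smoothing
    baseline_window: float = 2.0  # s; 0 disables baseline subtraction
    local_level_window: float = 0.3  # s; short running median tracking the
    # slow rebound shelf the high-pass leaves around pumps; 0 disables
    # expected transient FWHM per phase, used for template amplitude fits
    expected_fwhm: dict = field(
        default_factory=lambda: {
            "e": 0.008,
            "E": 0.010,
            "P": 0.008,
            "R": 0.010,
            "r": 0.010,
        }
    )

    def __post_init__(self) -> None:
        if self.p_threshold_k > self.spike_threshold_k:
            raise ValueError("p_threshold_k must be <= spike_threshold_k")
        for name in ("min_inter_pump", "max_ER_interval", "p_exclusion_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for win in (self.e_search_window, self.r_search_window):
            if not (0 <= win[0] < win[1]):
                raise ValueError(f"invalid search window {win}")


@dataclass
class PumpEvent:
    """One pump: times (s, trace frame) and signed baseline-relative
    amplitudes (mV) of its labeled transients."""

    t_E: float
    a_E: float
    t_R: float
    a_R: float
    t_e: Optional[float] = None
    a_e: Optional[float] = None
    t_r: Optional[float] = None
    a_r: Optional[float] = None
    t_P: list[float] = field(default_factory=list)
    a_P: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.t_E < self.t_R, "E peak must precede R peak"
        assert self.a_E > 0, "E amplitude must be positive"
        assert self.a_R < 0, "R amplitude must be negative"
        for tp, ap in zip(self.t_P, self.a_P):
            assert self.t_E < tp < self.t_R, "P waves must lie inside (t_E, t_R)"
            assert ap < 0, "P amplitudes must be negative"
        if self.t_e is not None:
            assert self.t_e < self.t_E

    @property
    def n_P(self) -> int:
        return len(self.t_P)

    @property
    def duration(self) -> float:
        return self.t_R - self.t_E

    @property
    def amp_pp(self) -> float:
        return self.a_E - self.a_R

    @property
    def flags(self) -> list[str]:
        out = []
        if self.t_e is None:
            out.append("missing_e")
        if self.t_r is None:
            out.append("missing_r")
        return out or ["complete"]


@dataclass
class EventTable:
    """Ordered pump events plus recording metadata."""

    pumps: list[PumpEvent]
    analyzed_s: float
    noise_sigma: float
    worm_id: str = ""
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pumps)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, p in enumerate(self.pumps):
            rows.append(
                {
                    "worm_id": self.worm_id,
                    "pump_index": i,
                    "t_e": p.t_e,
                    "a_e": p.a_e,
                    "t_E": p.t_E,
                    "a_E": p.a_E,
                    "n_P": p.n_P,
                    "t_P_list": ";".join(f"{t:.6f}" for t in p.t_P),
                    "a_P_list": ";".join(f"{a:.6f}" for a in p.a_P),
                    "t_R": p.t_R,
                    "a_R": p.a_R,
                    "t_r": p.t_r,
                    "a_r": p.a_r,
                    "flags": ",".join(p.flags),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "worm_id",
                "pump_index",
                "t_e",
                "a_e",
                "t_E",
                "a_E",
                "n_P",
                "t_P_list",
                "a_P_list",
                "t_R",
                "a_R",
                "t_r",
                "a_r",
                "flags",
            ],
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, analyzed_s: float = float("nan"),
                 noise_sigma: float = float("nan")) -> "EventTable":
        df = pd.read_csv(path, sep="\t")
        pumps = []
        for _, row in df.iterrows():
            def _lst(cell):
                if isinstance(cell, str) and cell:
                    return [float(v) for v in cell.split(";")]
                return []
            pumps.append(
                PumpEvent(
                    t_E=float(row["t_E"]),
                    a_E=float(row["a_E"]),
                    t_R=float(row["t_R"]),
                    a_R=float(row["a_R"]),
                    t_e=None if pd.isna(row["t_e"]) else float(row["t_e"]),
                    a_e=None if pd.isna(row["a_e"]) else float(row["a_e"]),
                    t_r=None if pd.isna(row["t_r"]) else float(row["t_r"]),
                    a_r=None if pd.isna(row["a_r"]) else float(row["a_r"]),
                    t_P=_lst(row["t_P_list"]),
                    a_P=_lst(row["a_P_list"]),
                )
            )
        wid = str(df["worm_id"].iloc[0]) if len(df) else ""
        return cls(pumps, analyzed_s=analyzed_s, noise_sigma=noise_sigma, worm_id=wid)


@dataclass(frozen=True)
class GateResult:
    decision: str  # "head" or "tail_or_bad"
    reason: str = ""


def _fit_amplitude(x: np.ndarray, idx: int, sigma_samples: float) -> float:
    """Least-squares amplitude of a unit-peak Gaussian centred at ``idx``,
    fitted jointly with a local constant offset (absorbs residual baseline
    and filter-rebound shelves).  The window is kept to +/-2 sigma so the
    offset term is not contaminated by neighbouring transients."""
    half = max(1, int(round(2.0 * sigma_samples)))
    i0 = max(0, idx - half)
    i1 = min(x.size, idx + half + 1)
    seg = x[i0:i1]
    j = np.arange(i0, i1) - idx
    k = np.exp(-0.5 * (j / sigma_samples) ** 2)
    n = k.size
    kk = float(np.dot(k, k))
    ks = float(k.sum())
    det = kk * n - ks * ks
    if det <= 0:
        return float(np.dot(seg, k) / kk)
    return float((n * np.dot(seg, k) - ks * seg.sum()) / det)


def _fit_noise_factor(sigma_samples: float) -> float:
    """Standard deviation of the fitted amplitude per unit raw-noise sigma."""
    half = max(1, int(round(2.0 * sigma_samples)))
    j = np.arange(-half, half + 1)
    k = np.exp(-0.5 * (j / sigma_samples) ** 2)
    denom = float(np.dot(k, k) - k.sum() ** 2 / k.size)
    return 1.0 / math.sqrt(max(denom, 1e-12))


def _local_extrema(x: np.ndarray, lo: int, hi: int, minima: bool) -> np.ndarray:
    """Indices of strict local extrema of x within [lo, hi)."""
    seg = x[lo:hi]
    if seg.size < 3:
        return np.empty(0, dtype=int)
    y = -seg if minima else seg
    idx, _ = sp_signal.find_peaks(y)
    return idx + lo


def detect_pumps(trace: Trace, cfg: DetectionConfig = DetectionConfig()) -> EventTable:
    """Segment a (drift-free) trace into pumps and label the five phases.

    Steps: estimate the working noise sigma as 1.4826 x MAD of the smoothed,
    baseline-subtracted signal; collect E/R candidates above
    ``spike_threshold_k`` sigma; pair each E with the nearest following R
    within ``max_ER_interval``; resolve overlaps greedily by combined spike
    magnitude; then label e, P and r inside their per-pump windows at the
    ``p_threshold_k`` sigma threshold.
    """
    rate = trace.sampling_rate
    warnings: list[str] = []
    if trace.duration < 2 * cfg.min_inter_pump:
        return EventTable(
            [], analyzed_s=trace.duration, noise_sigma=float("nan"),
            warnings=["trace shorter than 2x min_inter_pump"],
        )

    # x: globally baselined signal used for amplitude fits (the fit's own
    # local offset term absorbs slow shelves).  xs: additionally local-level
    # subtracted and smoothed, used for thresholds and candidate selection.
    x = trace.samples
    if cfg.baseline_window > 0:
        x = x - estimate_baseline(x, window=cfg.baseline_window, rate=rate)
    x_thr = x
    if cfg.local_level_window > 0 and cfg.local_level_window * rate >= 3:
        x_thr = x - estimate_baseline(x, window=cfg.local_level_window, rate=rate)
    sig_samples = cfg.smooth_sigma_s * rate
    if sig_samples >= 0.5:
        xs = ndimage.gaussian_filter1d(x_thr, sigma=sig_samples, mode="nearest")
    else:
        xs = x_thr
    peak_scale = float(np.max(np.abs(xs))) if xs.size else 0.0
    # Noise sigma of the raw and smoothed working signals.  A plain MAD of
    # the trace counts the pump transients themselves and overestimates the
    # noise by up to ~2x on dense recordings, so the raw noise is taken
    # from the high-frequency residual (signal-free to first order) and
    # propagated through the smoother's noise-reduction factor.
    if sig_samples >= 0.5:
        k0 = 1.0 / (sig_samples * math.sqrt(2.0 * math.pi))
        s2 = 1.0 / (2.0 * sig_samples * math.sqrt(math.pi))
        resid_var_frac = max(1.0 - 2.0 * k0 + s2, 0.1)
        sigma_raw = robust_sigma(x - ndimage.gaussian_filter1d(
            x, sigma=sig_samples, mode="nearest")) / math.sqrt(resid_var_frac)
        sigma = min(robust_sigma(xs), sigma_raw * math.sqrt(s2))
    else:
        sigma_raw = robust_sigma(x)
        sigma = robust_sigma(xs)
    sigma = max(sigma, 1e-9 * peak_scale, 1e-12)
    sigma_raw = max(sigma_raw, 1e-9 * peak_scale, 1e-12)

    thr_spike = cfg.spike_threshold_k * sigma
    thr_small = cfg.p_threshold_k * sigma

    fw = cfg.expected_fwhm
    sig_of = {k: fw[k] * _FWHM_TO_SIGMA * rate for k in fw}
    # minimum believable fitted E/R amplitude: the matched-filter estimate
    # must clear ``confirm_k`` fitted-amplitude noise sigmas.  This rejects
    # smoothed-threshold crossings that ride on the slow rebound shelves the
    # high-pass leaves around large transients at high SNR, while staying
    # far below true spikes at the device's SNR floor.
    conf = {
        k: sigma_raw * _fit_noise_factor(sig_of[k]) * cfg.confirm_k
        for k in ("E", "R")
    }

    e_idx, _ = sp_signal.find_peaks(xs, height=thr_spike)
    r_idx, _ = sp_signal.find_peaks(-xs, height=thr_spike)
    e_idx = np.array(
        [i for i in e_idx if _fit_amplitude(x, int(i), sig_of["E"]) > conf["E"]],
        dtype=int,
    )
    r_idx = np.array(
        [i for i in r_idx if _fit_amplitude(x, int(i), sig_of["R"]) < -conf["R"]],
        dtype=int,
    )

    # Candidate pairs: every following minimum within the E-R window.  The
    # greedy pass below keeps the largest-magnitude pair per region, which
    # selects the true R over P waves and r spikes that also cross threshold.
    max_er = int(round(cfg.max_ER_interval * rate))
    pairs = []  # (score, iE, iR)
    if e_idx.size and r_idx.size:
        lo = np.searchsorted(r_idx, e_idx, side="right")
        hi = np.searchsorted(r_idx, e_idx + max_er, side="right")
        for iE, p0, p1 in zip(e_idx, lo, hi):
            for iR in r_idx[p0:p1]:
                # a pair spanning another comparably sized E candidate
                # straddles two pumps; smaller intervening maxima (noise,
                # residual shelf bumps) are ignored
                b0, b1 = np.searchsorted(e_idx, [iE, iR])
                mid = e_idx[b0:b1]
                mid = mid[mid != iE]
                if mid.size and np.any(xs[mid] >= 0.5 * xs[iE]):
                    continue
                pairs.append((float(xs[iE] - xs[iR]), int(iE), int(iR)))
    pairs.sort(key=lambda t: -t[0])

    min_gap = int(round(cfg.min_inter_pump * rate))
    accepted: list[tuple[int, int]] = []
    used_E: set[int] = set()
    used_R: set[int] = set()
    for _, iE, iR in pairs:
        if iE in used_E or iR in used_R:
            continue
        ok = True
        for aE, aR in accepted:
            if iE - min_gap < aR and iR + min_gap > aE:  # overlap incl. margin
                ok = False
                break
        if not ok:
            continue
        accepted.append((iE, iR))
        used_E.add(iE)
        used_R.add(iR)
    accepted.sort()

    t_of = lambda i: trace.t0 + i / rate

    fits: list[Optional[tuple[float, float]]] = []
    for iE, iR in accepted:
        a_E = _fit_amplitude(x, iE, sig_of["E"])
        a_R = _fit_amplitude(x, iR, sig_of["R"])
        if a_E <= conf["E"] or a_R >= -conf["R"]:
            warnings.append(
                f"pump at {t_of(iE):.3f}s dropped: fitted amplitude below noise"
            )
            fits.append(None)
        else:
            fits.append((a_E, a_R))
    spans = [aE - aR for f in fits if f is not None for aE, aR in [f]]
    # P acceptance floor: a morphology bound (fraction of the pump span,
    # rejecting filter-undershoot artefacts) and a noise bound on the fit
    p_floor = max(
        cfg.p_rel_floor * float(np.median(spans)) if spans else 0.0,
        cfg.confirm_k * sigma_raw * _fit_noise_factor(sig_of["P"]),
    )

    pumps: list[PumpEvent] = []
    for n_i, (iE, iR) in enumerate(accepted):
        if fits[n_i] is None:
            continue
        a_E, a_R = fits[n_i]

        # --- e: largest local max above threshold in the window before E
        w0 = iE - int(round(cfg.e_search_window[1] * rate))
        w1 = iE - int(round(cfg.e_search_window[0] * rate))
        cand = _local_extrema(xs, max(0, w0), max(0, w1), minima=False)
        cand = cand[xs[cand] > thr_small]
        t_e = a_e = None
        if cand.size:
            ie = int(cand[np.argmax(xs[cand])])
            t_e, a_e = t_of(ie), _fit_amplitude(x, ie, sig_of["e"])
            if a_e <= 0 or t_e >= t_of(iE):
                t_e = a_e = None

        # --- r: largest local min above threshold after R, capped at next pump
        w0 = iR + int(round(cfg.r_search_window[0] * rate))
        w1 = iR + int(round(cfg.r_search_window[1] * rate))
        if n_i + 1 < len(accepted):
            cap = accepted[n_i + 1][0] - int(round(cfg.e_search_window[1] * rate))
            w1 = min(w1, cap)
        cand = _local_extrema(xs, w0, min(trace.n, w1), minima=True)
        cand = cand[xs[cand] < -thr_small]
        t_r = a_r = None
        if cand.size:
            ir = int(cand[np.argmin(xs[cand])])
            t_r, a_r = t_of(ir), _fit_amplitude(x, ir, sig_of["r"])
            if a_r >= 0:
                t_r = a_r = None

        # --- P: local minima in (t_E, t_R) beyond threshold, away from R
        excl = int(round(cfg.p_exclusion_radius * rate))
        cand = _local_extrema(xs, iE + 1, iR, minima=True)
        cand = cand[(xs[cand] < -thr_small) & (np.abs(cand - iR) > excl)]
        merged: list[int] = []
        merge_n = int(round(cfg.p_merge_window * rate))
        for ci in cand:
            if merged and ci - merged[-1] < merge_n:
                if xs[ci] < xs[merged[-1]]:
                    merged[-1] = int(ci)
            else:
                merged.append(int(ci))
        t_P, a_P = [], []
        for ci in merged:
            ap = _fit_amplitude(x, ci, sig_of["P"])
            if ap < -p_floor:
                t_P.append(t_of(ci))
                a_P.append(ap)

        pumps.append(
            PumpEvent(
                t_E=t_of(iE), a_E=a_E, t_R=t_of(iR), a_R=a_R,
                t_e=t_e, a_e=a_e, t_r=t_r, a_r=a_r, t_P=t_P, a_P=a_P,
            )
        )

    # The e-to-E lead is stable within a recording.  Once a majority of
    # pumps exhibit a per-pump e detection, re-measure e on *every* pump at
    # the recording's median lead: fitting at a fixed predicted position
    # removes both the argmax-selection bias and the threshold-truncation
    # bias that inflate the mean of per-pump detections near the noise
    # floor (the equivalent of measuring a small wave where it is known to
    # sit on the waveform).
    leads = [p.t_E - p.t_e for p in pumps if p.t_e is not None]
    if len(leads) >= max(5, 0.5 * len(pumps)):
        lead = float(np.median(leads))
        lead_n = int(round(lead * rate))
        for p in pumps:
            ie = int(round((p.t_E - trace.t0) * rate)) - lead_n
            if 0 <= ie < trace.n:
                a_e = _fit_amplitude(x, ie, sig_of["e"])
                if a_e > 0:
                    p.t_e = t_of(ie)
                    p.a_e = a_e
                else:
                    p.t_e = None
                    p.a_e = None

    return EventTable(
        pumps,
        analyzed_s=trace.duration,
        noise_sigma=sigma,
        warnings=warnings,
    )


def orientation_gate(
    trace: Trace,
    cfg: DetectionConfig = DetectionConfig(),
    reference_amp: float = 4.410,
    events: Optional[EventTable] = None,
) -> GateResult:
    """Decide whether a recording shows head-quality EPG structure.

    ``tail_or_bad`` when fewer than 10 pumps are found, when the median
    per-pump peak-to-peak amplitude is below 25% of ``reference_amp``, or
    when fewer than 5% of pumps carry any e/P/r fine structure.
    """
    if events is None:
        events = detect_pumps(trace, cfg)
    if len(events.pumps) < 10:
        return GateResult("tail_or_bad", "too_few_events")
    amps = np.array([p.amp_pp for p in events.pumps])
    if float(np.median(amps)) < 0.25 * reference_amp:
        return GateResult("tail_or_bad", "low_amplitude")
    detail = np.mean(
        [1.0 if (p.t_e is not None or p.n_P > 0 or p.t_r is not None) else 0.0
         for p in events.pumps]
    )
    if detail < 0.05:
        return GateResult("tail_or_bad", "no_fine_structure")
    return GateResult("head", "ok")
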