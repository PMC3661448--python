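"""Phenomenological EPG trace generator with per-transient ground truth.

Each pharyngeal pump is rendered as five Gaussian transients on a flat
baseline: a small positive ``e`` spike leading the large positive ``E``
spike, a Poisson-distributed number of small negative ``P`` waves in the
plateau, and the large/small negative ``R``/``r`` relaxation spikes.  Pump
onsets follow a refractory gamma renewal process whose mean interval equals
1/frequency exactly, so the long-run pump rate matches the requested
frequency.  Between-worm variability is modelled as independent
mean-preserving lognormal multipliers on all preset means.

Optional condition schedules (serotonin wash-in, ethanol, light epochs)
modulate frequency, duration, P-wave intensity and E amplitude through
:class:`ScheduleEffect` profiles.

Noise is white Gaussian with sigma = amp_pp / snr; drift is a sum of three
sub-0.3 Hz sinusoids totalling 20% of the peak-to-peak amplitude, i.e.
entirely below the 0.5 Hz high-pass used by the preprocessing stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .trace import ConditionSchedule, Trace

__all__ = [
    "DEFAULT_SNR",
    "PhenotypePreset",
    "TailPreset",
    "PumpKernelSpec",
    "ScheduleEffect",
    "DEFAULT_EFFECTS",
    "WormParams",
    "GroundTruthTable",
    "CohortMember",
    "available_presets",
    "load_preset",
    "draw_worm",
    "generate_trace",
    "generate_tail_trace",
    "generate_cohort",
]

#: Default simulator signal-to-noise ratio (amp_pp / noise sigma).  The
#: recorded floor for the device is 8, but the smallest measured transient
#: ('e' at ~0.26 mV in a 4.4 mV recording) implies working noise well below
#: amp_pp/17, so clean-recording simulations default to 40.
DEFAULT_SNR = 40.0

#: Default simulation sampling rate in Hz (transients last ~10-100 ms; 2 kHz
#: gives >= 16 samples across the narrowest default transient).
DEFAULT_RATE = 2000.0

_GAUSS_TRUNC_SIGMAS = 4.0  # transients are exactly zero beyond this
_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class PhenotypePreset:
    """Generative parameter set for one strain/condition.

    Means are per-recording population means; ``*_cv`` are within-worm
    coefficients of variation; ``worm_cv`` is the between-worm multiplicative
    spread applied to every mean.
    """

    name: str
    freq_mean: float  # pumps/s
    dur_mean: float  # s, peak-E-to-peak-R
    p_rate: float  # mean P waves per pump (Poisson intensity)
    amp_pp_mean: float  # mV, E-to-R peak-to-peak span
    e_amp_mean: float  # mV
    re_ratio_mean: float  # |R| / E amplitude ratio
    freq_cv: float = 0.3
    dur_cv: float = 0.08
    amp_pp_cv: float = 0.10
    e_amp_cv: float = 0.10
    re_ratio_cv: float = 0.05
    worm_cv: float = 0.05
    p_amp_frac: float = 0.35  # P amplitude as a fraction of amp_pp (unprinted)

    def __post_init__(self) -> None:
        if self.freq_mean < 0:
            raise ValueError("freq_mean must be >= 0")
        for fname in ("dur_mean", "amp_pp_mean", "e_amp_mean", "re_ratio_mean"):
            if getattr(self, fname) <= 0:
                raise ValueError(f"{fname} must be > 0")
        if self.p_rate < 0:
            raise ValueError("p_rate must be >= 0")
        for fname in (
            "freq_cv",
            "dur_cv",
            "amp_pp_cv",
            "e_amp_cv",
            "re_ratio_cv",
            "worm_cv",
        ):
            v = getattr(self, fname)
            if not (0 <= v < 1):
                raise ValueError(f"{fname} must be in [0, 1)")
        if not (0 < self.p_amp_frac < 1):
            raise ValueError("p_amp_frac must be in (0, 1)")


@dataclass(frozen=True)
class TailPreset:
    """Degenerate preset for worms recorded tail-first: small monophasic blips."""

    name: str = "tail"
    blip_rate: float = 0.7  # blips per second
    amp_mean: float = 0.70  # mV; ~16% of the wild-type head amplitude
    blip_width: float = 0.012  # s FWHM
    rate_cv: float = 0.3
    amp_cv: float = 0.10


@dataclass(frozen=True)
class PumpKernelSpec:
    """Micro-timing of the five transients within one pump.

    Widths are FWHM of Gaussian bumps.  ``e_lead`` is measured peak-of-e to
    peak-of-E; ``r_lag`` peak-of-R to peak-of-r.
    """

    e_lead: float = 0.025
    e_width: float = 0.008
    E_width: float = 0.010
    P_width: float = 0.008
    R_width: float = 0.010
    r_lag: float = 0.020
    r_width: float = 0.010
    r_rel_amp: float = 0.4  # r amplitude as a fraction of |R|
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        for fname in ("e_lead", "e_width", "E_width", "P_width", "R_width",
                      "r_lag", "r_width"):
            if getattr(self, fname) <= 0:
                raise ValueError(f"{fname} must be > 0")
        if self.e_lead <= self.e_width / 2:
            raise ValueError("e_lead must exceed e_width/2 so 'e' is resolvable")
        if not (0 < self.r_rel_amp < 1):
            raise ValueError("r_rel_amp must be in (0, 1)")
        if self.shape not in ("gaussian", "biexponential"):
            raise ValueError(f"unknown transient shape {self.shape!r}")

    def validate_against(self, dur_mean: float) -> None:
        for fname in ("e_width", "E_width", "P_width", "R_width", "r_width"):
            if getattr(self, fname) >= dur_mean / 2:
                raise ValueError(
                    f"kernel {fname}={getattr(self, fname)} incompatible with "
                    f"dur_mean={dur_mean} (must be < dur_mean/2)"
                )

    @property
    def head_margin(self) -> float:
        """Footprint before the E peak (e spike fully rendered)."""
        return self.e_lead + 2 * self.e_width

    @property
    def tail_margin(self) -> float:
        """Footprint after the R peak (r spike fully rendered)."""
        return self.r_lag + 2 * self.r_width


@dataclass(frozen=True)
class ScheduleEffect:
    """Multiplicative response profile tied to one condition label.

    Asymptotic multipliers are approached exponentially with
    ``time_constant`` after ``onset_latency`` from the interval start
    (``time_constant`` 0 means a step).  ``persists`` controls whether the
    effect survives past the interval end (drug wash-in) or switches off
    with it (light).
    """

    condition_label: str
    freq_mult: float = 1.0
    dur_mult: float = 1.0
    p_rate_mult: float = 1.0
    E_amp_mult: float = 1.0
    onset_latency: float = 0.0
    time_constant: float = 0.0
    persists: bool = False

    def __post_init__(self) -> None:
        for fname in ("freq_mult", "dur_mult", "p_rate_mult", "E_amp_mult"):
            if getattr(self, fname) <= 0:
                raise ValueError(f"{fname} must be > 0")
        if self.onset_latency < 0 or self.time_constant < 0:
            raise ValueError("onset_latency and time_constant must be >= 0")

    def _ramp(self, elapsed: float) -> float:
        """Fractional approach to the asymptotic multiplier at ``elapsed`` s."""
        s = elapsed - self.onset_latency
        if s <= 0:
            return 0.0
        if self.time_constant == 0:
            return 1.0
        return 1.0 - math.exp(-s / self.time_constant)

    def multipliers_at(self, t: float, start: float, end: float) -> tuple[float, float, float, float]:
        if t < start or (not self.persists and t >= end):
            return (1.0, 1.0, 1.0, 1.0)
        f = self._ramp(t - start)
        mix = lambda m: 1.0 + (m - 1.0) * f
        return (
            mix(self.freq_mult),
            mix(self.dur_mult),
            mix(self.p_rate_mult),
            mix(self.E_amp_mult),
        )


#: Default condition responses: serotonin wash-in with a 5 min latency and
#: ~15 min to full effect; fast ethanol onset (half-time < 2 min) slowing
#: and lengthening pumps while suppressing P waves and the E spike; a step
#: light effect raising rate and shortening pumps only while the light is on.
DEFAULT_EFFECTS: dict[str, ScheduleEffect] = {
    "5HT": ScheduleEffect(
        "5HT",
        freq_mult=46.0,  # 0.075 -> 3.467 pumps/s
        dur_mult=0.87,  # 0.116 -> 0.101 s
        p_rate_mult=0.07,  # 1.788 -> 0.126 P/pump
        E_amp_mult=1.9,
        onset_latency=300.0,
        time_constant=300.0,
        persists=True,
    ),
    "ethanol": ScheduleEffect(
        "ethanol",
        freq_mult=0.5,
        dur_mult=1.3,
        p_rate_mult=0.3,
        E_amp_mult=0.6,
        onset_latency=0.0,
        time_constant=100.0,  # half-time ~70 s
        persists=True,
    ),
    "light_on": ScheduleEffect(
        "light_on",
        freq_mult=1.5,
        dur_mult=0.8,
        persists=False,
    ),
}


@dataclass(frozen=True)
class WormParams:
    """Per-worm latent means drawn from a preset."""

    preset: PhenotypePreset
    freq: float
    dur: float
    p_rate: float
    amp_pp: float
    e_amp: float
    re_ratio: float


@dataclass
class GroundTruthTable:
    """Long-format record of every placed transient.

    Columns: ``worm_id, pump_index, event_type, time_s, amplitude_mV`` with
    ``event_type`` in {e, E, P, R, r}.
    """

    events: pd.DataFrame

    COLUMNS = ["worm_id", "pump_index", "event_type", "time_s", "amplitude_mV"]

    def __post_init__(self) -> None:
        if list(self.events.columns) != self.COLUMNS:
            self.events = self.events.reindex(columns=self.COLUMNS)

    @classmethod
    def empty(cls) -> "GroundTruthTable":
        return cls(
            pd.DataFrame(
                {
                    "worm_id": pd.Series(dtype=str),
                    "pump_index": pd.Series(dtype=np.int64),
                    "event_type": pd.Series(dtype=str),
                    "time_s": pd.Series(dtype=np.float64),
                    "amplitude_mV": pd.Series(dtype=np.float64),
                }
            )
        )

    @property
    def n_pumps(self) -> int:
        if self.events.empty:
            return 0
        return int(self.events["pump_index"].nunique())

    def times(self, event_type: str) -> np.ndarray:
        sel = self.events[self.events["event_type"] == event_type]
        return sel.sort_values("time_s")["time_s"].to_numpy()

    def pump(self, pump_index: int) -> pd.DataFrame:
        return self.events[self.events["pump_index"] == pump_index]

    def to_tsv(self, path) -> None:
        self.events.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GroundTruthTable":
        return cls(pd.read_csv(path, sep="\t"))

    def check_ordering(self) -> None:
        """Assert the within-pump phase ordering e < E < P... < R < r."""
        for _, grp in self.events.groupby("pump_index"):
            by_type = {t: grp[grp["event_type"] == t]["time_s"] for t in "eEPRr"}
            t_E = float(by_type["E"].iloc[0])
            t_R = float(by_type["R"].iloc[0])
            if not by_type["e"].empty:
                assert float(by_type["e"].iloc[0]) < t_E
            assert t_E < t_R
            for tp in by_type["P"]:
                assert t_E < tp < t_R
            if not by_type["r"].empty:
                assert t_R < float(by_type["r"].iloc[0])


@dataclass
class CohortMember:
    worm_id: str
    trace: Trace
    truth: GroundTruthTable
    true_label: str


# ---------------------------------------------------------------------------
# presets on disk


def available_presets() -> list[str]:
    root = resources.files("epgkit").joinpath("presets")
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str) -> PhenotypePreset | TailPreset:
    """Load a shipped preset by name, or any preset YAML by path."""
    root = resources.files("epgkit").joinpath("presets")
    candidate = root.joinpath(f"{name}.yaml")
    if candidate.is_file():
        data = yaml.safe_load(candidate.read_text())
    else:
        import os

        if os.path.exists(name):
            with open(name) as fh:
                data = yaml.safe_load(fh)
        else:
            raise KeyError(
                f"unknown preset {name!r}; shipped presets: "
                + ", ".join(available_presets())
            )
    if data.get("kind") == "tail":
        data.pop("kind")
        return TailPreset(**data)
    data.pop("kind", None)
    return PhenotypePreset(**data)


# ---------------------------------------------------------------------------
# sampling helpers


def _lognormal_mult(rng: np.random.Generator, cv: float, size=None):
    """Mean-preserving lognormal multiplier(s) with coefficient of variation cv."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    s2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-s2 / 2.0, sigma=math.sqrt(s2), size=size)


def _gamma_interval(rng: np.random.Generator, mean: float, sd: float) -> float:
    if mean <= 0:
        raise ValueError("gamma interval mean must be > 0")
    if sd <= 0:
        return mean
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return float(rng.gamma(shape, scale))


def draw_worm(
    preset: PhenotypePreset,
    seed: int | np.random.Generator,
) -> WormParams:
    """Draw per-worm latent means: preset means times independent
    mean-preserving lognormal(worm_cv) multipliers.  Deterministic under a
    fixed integer seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cv = preset.worm_cv
    m = _lognormal_mult(rng, cv, size=6)
    return WormParams(
        preset=preset,
        freq=preset.freq_mean * float(m[0]),
        dur=preset.dur_mean * float(m[1]),
        p_rate=preset.p_rate * float(m[2]),
        amp_pp=preset.amp_pp_mean * float(m[3]),
        e_amp=preset.e_amp_mean * float(m[4]),
        re_ratio=preset.re_ratio_mean * float(m[5]),
    )


def _add_bump(
    samples: np.ndarray, rate: float, t_peak: float, amp: float, fwhm: float
) -> None:
    """Add a Gaussian transient, truncated to exactly zero beyond 4 sigma."""
    sigma = fwhm * _FWHM_TO_SIGMA
    half = _GAUSS_TRUNC_SIGMAS * sigma
    i0 = max(0, int(math.ceil((t_peak - half) * rate)))
    i1 = min(samples.size - 1, int(math.floor((t_peak + half) * rate)))
    if i1 < i0:
        return
    tt = np.arange(i0, i1 + 1) / rate - t_peak
    samples[i0 : i1 + 1] += amp * np.exp(-0.5 * (tt / sigma) ** 2)


class _ScheduleState:
    """Evaluates combined schedule multipliers at a time point."""

    def __init__(
        self,
        schedule: Optional[ConditionSchedule],
        effects: Optional[dict[str, ScheduleEffect]],
    ) -> None:
        self.active: list[tuple[float, float, ScheduleEffect]] = []
        if schedule is not None:
            table = dict(DEFAULT_EFFECTS)
            if effects:
                table.update(effects)
            for start, end, label in schedule.intervals:
                eff = table.get(label)
                if eff is not None:
                    self.active.append((start, end, eff))

    def at(self, t: float) -> tuple[float, float, float, float]:
        f = d = p = a = 1.0
        for start, end, eff in self.active:
            mf, md, mp, ma = eff.multipliers_at(t, start, end)
            f *= mf
            d *= md
            p *= mp
            a *= ma
        return f, d, p, a


def _place_p_waves(
    rng: np.random.Generator,
    n_p: int,
    lo: float,
    hi: float,
    min_sep: float,
) -> np.ndarray:
    """Uniform placement in (lo, hi) with pairwise separation >= min_sep.

    Stick-breaking construction: subtracting the mandatory gaps and sorting
    uniforms over the remaining free length samples the
    separation-constrained uniform distribution exactly, so the Poisson
    count is only truncated when the plateau genuinely cannot hold it."""
    span = hi - lo
    if span <= 0:
        return np.empty(0)
    while n_p > 0 and span < (n_p - 1) * min_sep:
        n_p -= 1
    if n_p <= 0:
        return np.empty(0)
    free = span - (n_p - 1) * min_sep
    u = np.sort(rng.uniform(0.0, free, size=n_p))
    return lo + u + np.arange(n_p) * min_sep


def generate_trace(
    preset: PhenotypePreset,
    kernel: Optional[PumpKernelSpec] = None,
    schedule: Optional[ConditionSchedule] = None,
    effects: Optional[dict[str, ScheduleEffect]] = None,
    duration: float = 120.0,
    rate: float = DEFAULT_RATE,
    snr: float = DEFAULT_SNR,
    seed: int | np.random.Generator = 0,
    drift: bool = True,
    worm: Optional[WormParams] = None,
    worm_id: str = "worm0",
    t0: float = 0.0,
) -> tuple[Trace, GroundTruthTable]:
    """Simulate one worm's EPG recording and its ground-truth event table.

    Pump onsets follow a refractory gamma renewal process: the interval
    between successive E peaks is pump duration + kernel footprint + a gamma
    variate whose mean makes the expected interval exactly 1/frequency, so
    pumps can never overlap and the long-run rate is unbiased.

    ``snr`` is peak-to-peak amplitude over noise sigma; pass ``math.inf`` to
    disable noise.  ``drift=False`` disables the sub-0.3 Hz baseline drift.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if not (snr > 0):
        raise ValueError("snr must be > 0")
    kernel = kernel or PumpKernelSpec()
    kernel.validate_against(preset.dur_mean)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if worm is None:
        worm = draw_worm(preset, rng)
    sched = _ScheduleState(schedule, effects)

    n = int(round(duration * rate))
    if n < 2:
        raise ValueError("duration * rate must give at least 2 samples")
    samples = np.zeros(n, dtype=np.float64)
    refrac = kernel.head_margin + kernel.tail_margin
    rows: list[tuple[str, int, str, float, float]] = []

    def record(pump_idx: int, etype: str, t: float, a: float) -> None:
        rows.append((worm_id, pump_idx, etype, t0 + t, a))

    if worm.freq > 1e-9:
        fm0 = sched.at(0.0)[0]
        f0 = worm.freq * fm0
        first_gap = rng.uniform(0.0, 1.0 / f0) if f0 > 1e-9 else duration
        t_E = kernel.head_margin + first_gap
        pump_idx = 0
        while True:
            fm, dm, pm, am = sched.at(t_E)
            dur_i = worm.dur * dm * float(_lognormal_mult(rng, preset.dur_cv))
            if t_E + dur_i + kernel.tail_margin > duration:
                break
            t_R = t_E + dur_i
            amp_i = worm.amp_pp * float(_lognormal_mult(rng, preset.amp_pp_cv))
            re_i = worm.re_ratio * float(_lognormal_mult(rng, preset.re_ratio_cv))
            a_E_base = amp_i / (1.0 + re_i)
            a_E = a_E_base * am
            a_R = -re_i * a_E_base
            a_e = worm.e_amp * float(_lognormal_mult(rng, preset.e_amp_cv))
            a_r = -kernel.r_rel_amp * abs(a_R)
            t_e = t_E - kernel.e_lead
            t_r = t_R + kernel.r_lag

            n_p = int(rng.poisson(worm.p_rate * pm))
            p_lo = t_E + 2 * kernel.P_width
            p_hi = t_R - max(2 * kernel.P_width, 0.012)
            t_ps = _place_p_waves(rng, n_p, p_lo, p_hi, 2 * kernel.P_width)

            _add_bump(samples, rate, t_e, a_e, kernel.e_width)
            _add_bump(samples, rate, t_E, a_E, kernel.E_width)
            for t_p in t_ps:
                a_p = -preset.p_amp_frac * amp_i * float(_lognormal_mult(rng, 0.1))
                _add_bump(samples, rate, t_p, a_p, kernel.P_width)
                record(pump_idx, "P", float(t_p), a_p)
            _add_bump(samples, rate, t_R, a_R, kernel.R_width)
            _add_bump(samples, rate, t_r, a_r, kernel.r_width)
            record(pump_idx, "e", t_e, a_e)
            record(pump_idx, "E", t_E, a_E)
            record(pump_idx, "R", t_R, a_R)
            record(pump_idx, "r", t_r, a_r)
            pump_idx += 1

            f_now = worm.freq * sched.at(t_E)[0]
            if f_now <= 1e-9:
                break
            mean_ivl = 1.0 / f_now
            extra_mean = mean_ivl - worm.dur * dm - refrac
            if extra_mean <= 0:
                raise ValueError(
                    f"pump frequency {f_now:.3f}/s too high for duration "
                    f"{worm.dur * dm:.3f}s plus kernel footprint {refrac:.3f}s"
                )
            sd_total = preset.freq_cv * mean_ivl
            var_dur = (worm.dur * dm * preset.dur_cv) ** 2
            sd_extra = math.sqrt(max(sd_total**2 - var_dur, (0.05 * extra_mean) ** 2))
            extra = _gamma_interval(rng, extra_mean, sd_extra)
            t_E = t_E + dur_i + refrac + extra

    if drift:
        amp_pp_ref = worm.amp_pp
        fs = rng.uniform(0.02, 0.3, size=3)
        phases = rng.uniform(0, 2 * math.pi, size=3)
        weights = rng.uniform(0.3, 1.0, size=3)
        weights = weights / weights.sum() * 0.2 * amp_pp_ref
        tt = np.arange(n) / rate
        for fd, ph, w in zip(fs, phases, weights):
            samples += w * np.sin(2 * math.pi * fd * tt + ph)

    if math.isfinite(snr):
        sigma = worm.amp_pp / snr
        samples += rng.normal(0.0, sigma, size=n)

    truth = GroundTruthTable.empty()
    if rows:
        truth = GroundTruthTable(
            pd.DataFrame(rows, columns=GroundTruthTable.COLUMNS)
        )
    trace = Trace(
        samples=samples,
        sampling_rate=rate,
        t0=t0,
        label=preset.name,
        schedule=schedule,
    )
    return trace, truth


def generate_tail_trace(
    duration: float,
    rate: float = DEFAULT_RATE,
    seed: int | np.random.Generator = 0,
    preset: Optional[TailPreset] = None,
    snr: float = DEFAULT_SNR,
) -> Trace:
    """Simulate a worm recorded tail-first: small monophasic positive blips
    with none of the e/P/r fine structure, at <= 25% of the head amplitude."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    preset = preset or TailPreset()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * rate))
    samples = np.zeros(n, dtype=np.float64)
    if preset.blip_rate > 1e-9:
        mean_ivl = 1.0 / preset.blip_rate
        t = rng.uniform(0, mean_ivl)
        while t < duration:
            amp = preset.amp_mean * float(_lognormal_mult(rng, preset.amp_cv))
            _add_bump(samples, rate, t, amp, preset.blip_width)
            t += _gamma_interval(rng, mean_ivl, preset.rate_cv * mean_ivl)
    if math.isfinite(snr):
        samples += rng.normal(0.0, preset.amp_mean / snr, size=n)
    return Trace(samples=samples, sampling_rate=rate, label=preset.name)


def generate_cohort(
    composition: Sequence[tuple[PhenotypePreset | TailPreset, int]],
    duration: float,
    seed: int = 0,
    rate: float = DEFAULT_RATE,
    snr: float = DEFAULT_SNR,
    drift: bool = True,
    kernel: Optional[PumpKernelSpec] = None,
) -> list[CohortMember]:
    """Simulate one independent worm per composition entry count.

    Worm order is shuffled deterministically by the seed; true labels (the
    preset names) are retained for screening validation.
    """
    entries: list[PhenotypePreset | TailPreset] = []
    for preset, count in composition:
        if count < 0:
            raise ValueError("composition counts must be >= 0")
        entries.extend([preset] * count)
    if not entries:
        raise ValueError("empty cohort composition")
    ss = np.random.SeedSequence(seed)
    order_rng = np.random.default_rng(ss.spawn(1)[0])
    order = order_rng.permutation(len(entries))
    child_seeds = ss.spawn(len(entries))
    members: list[CohortMember] = []
    for slot, src in enumerate(order):
        preset = entries[src]
        wid = f"worm{slot:03d}"
        rng = np.random.default_rng(child_seeds[src])
        if isinstance(preset, TailPreset):
            trace = generate_tail_trace(duration, rate=rate, seed=rng, preset=preset, snr=snr)
            truth = GroundTruthTable.empty()
        else:
            trace, truth = generate_trace(
                preset,
                kernel=kernel,
                duration=duration,
                rate=rate,
                snr=snr,
                seed=rng,
                drift=drift,
                worm_id=wid,
            )
        members.append(CohortMember(wid, trace, truth, preset.name))
    return members
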