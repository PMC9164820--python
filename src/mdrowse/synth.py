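"""Synthetic drowsy-driving sessions with ground truth for every stage.

A session emulates the statistical structure the drowsiness index assumes:
1/f background EEG on every channel, a sustained alpha oscillation at a
configurable individual alpha frequency (IAF) with condition-dependent
amplitude, episodic alpha-spindle bursts (Hann-enveloped oscillations of
0.5-2 s, Poisson arrivals, coherent across the parietal channels with +-10%
per-channel gain jitter), blink templates on Fpz, and an ECG trace built
from an RR-interval model. Injected spindle intervals, blink times and
R-peak times are returned as ground truth.

Two presets ship with the package: ``paper_preset`` mirrors a full
experimental timeline (60 s eyes-open baseline, then four driving conditions
of 780/700/760/1470 s), and ``fast_preset`` scales the driving conditions to
one tenth for quick runs while keeping the 60-s baseline, which the IAF
estimator needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MDrowSeries
from .io import ConditionAnnotation, Recording
from .spectral import PARIETAL_CHANNELS

__all__ = [
    "SessionSpec",
    "SyntheticGroundTruth",
    "DetectionReport",
    "simulate_session",
    "evaluate_detection",
    "paper_preset",
    "fast_preset",
]

DEFAULT_CHANNELS = tuple(PARIETAL_CHANNELS) + ("Fpz", "ECG")


def _per_condition(value, label: str, default=0.0) -> float:
    """Resolve a scalar-or-mapping parameter for one condition."""
    if isinstance(value, dict):
        return float(value.get(label, value.get("default", default)))
    return float(value)


def _per_condition_pair(value, label: str) -> tuple[float, float]:
    if isinstance(value, dict):
        pair = value.get(label, value.get("default", (0.5, 2.0)))
    else:
        pair = value
    return float(pair[0]), float(pair[1])


@dataclass
class SessionSpec:
    """Parameters of one synthetic session.

    Any of the per-condition fields accepts either a scalar (applied to all
    conditions) or a mapping ``{condition: value, "default": value}``.
    """

    rate_hz: float = 250.0
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    iaf_hz: float = 10.0
    background_exponent: float = 1.0
    background_rms_uv: float = 10.0
    alpha_uv: float | dict = 2.0                 # sustained alpha amplitude
    spindle_rate_per_min: float | dict = 0.0
    spindle_duration_s: tuple | dict = (0.5, 2.0)
    spindle_amplitude_uv: float | dict = 10.0
    blink_rate_per_min: float | dict = 0.0
    blink_amplitude_uv: float = 120.0
    blink_duration_s: float = 0.3
    hr_bpm: float | dict = 70.0
    rr_jitter_s: float | dict = 0.05
    conditions: tuple = (("OE", 60.0), ("DROW", 300.0))
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for _, d in self.conditions):
            raise ValueError("condition durations must be positive")
        for label, dur in self.conditions:
            lo, hi = _per_condition_pair(self.spindle_duration_s, label)
            if not (0 < lo <= hi <= 10):
                raise ValueError(f"spindle duration range ({lo}, {hi}) outside (0, 10]")
            rate = _per_condition(self.spindle_rate_per_min, label)
            if rate > 0 and 60.0 / rate < hi:
                raise ValueError(
                    f"condition {label!r}: expected spindle spacing {60/rate:.1f} s "
                    f"shorter than the maximum duration {hi} s"
                )

    @property
    def total_duration_s(self) -> float:
        return float(sum(d for _, d in self.conditions))

    def spans(self) -> list[tuple[str, float, float]]:
        out, t = [], 0.0
        for label, dur in self.conditions:
            out.append((label, t, t + dur))
            t += dur
        return out


@dataclass
class SyntheticGroundTruth:
    """Injected event times of one simulated session."""

    spindle_intervals: list[tuple[float, float, str]]
    blink_times_s: np.ndarray
    r_times_s: np.ndarray
    counts: dict[str, dict[str, int]]
    iaf_hz: float
    seed: int

    def spindles_in(self, condition: str) -> list[tuple[float, float]]:
        return [(s, e) for s, e, c in self.spindle_intervals if c == condition]


@dataclass
class DetectionReport:
    """Event-level agreement between the index and the ground truth."""

    sensitivity: float | None
    precision: float | None
    latencies_s: list[float]
    n_truth: int
    n_regions: int
    tolerance_s: float


# ---------------------------------------------------------------------------


def _pink_noise(rng: np.random.Generator, n: int, rate: float,
                exponent: float, rms: float) -> np.ndarray:
    white = rng.standard_normal(n)
    X = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / rate)
    shape = np.ones_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(X * shape, n=n)
    x *= rms / x.std()
    return x


def _poisson_times(rng: np.random.Generator, rate_per_min: float,
                   start: float, end: float) -> np.ndarray:
    n = rng.poisson(rate_per_min * (end - start) / 60.0)
    return np.sort(rng.uniform(start, end, size=n))


def _merge_intervals(iv: list[tuple[float, float]]) -> list[tuple[float, float]]:
    merged: list[list[float]] = []
    for s, e in sorted(iv):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def simulate_session(spec: SessionSpec) -> tuple[Recording, SyntheticGroundTruth]:
    """Generate one fully annotated session; identical seeds give identical output."""
    rng = np.random.default_rng(spec.seed)
    rate = spec.rate_hz
    n = int(round(spec.total_duration_s * rate))
    t = np.arange(n) / rate
    labels = list(spec.channels)
    parietal = [c for c in labels if c in PARIETAL_CHANNELS]
    data = np.zeros((len(labels), n))
    spans = spec.spans()

    # 1/f background on every non-ECG channel
    for i, lab in enumerate(labels):
        if lab != "ECG":
            data[i] += _pink_noise(rng, n, rate, spec.background_exponent,
                                   spec.background_rms_uv)

    # sustained alpha on the parietal set, condition-dependent amplitude
    phase = rng.uniform(0, 2 * np.pi)
    gains = 1.0 + rng.uniform(-0.1, 0.1, size=len(parietal))
    envelope = np.zeros(n)
    for label, s, e in spans:
        a = int(round(s * rate)); b = int(round(e * rate))
        envelope[a:b] = _per_condition(spec.alpha_uv, label)
    carrier = np.sin(2 * np.pi * spec.iaf_hz * t + phase)
    for g, lab in zip(gains, parietal):
        data[labels.index(lab)] += g * envelope * carrier

    # alpha-spindle bursts, coherent across the parietal channels
    spindle_intervals: list[tuple[float, float, str]] = []
    counts: dict[str, dict[str, int]] = {}
    for label, s, e in spans:
        srate = _per_condition(spec.spindle_rate_per_min, label)
        lo, hi = _per_condition_pair(spec.spindle_duration_s, label)
        amp = _per_condition(spec.spindle_amplitude_uv, label)
        starts = _poisson_times(rng, srate, s, e)
        durs = rng.uniform(lo, hi, size=starts.size)
        iv = _merge_intervals(
            [(st, min(st + d, e)) for st, d in zip(starts, durs) if st + 0.1 < e]
        )
        counts[label] = {"spindles": len(iv)}
        for st, en in iv:
            a = int(round(st * rate)); b = int(round(en * rate))
            if b - a < 2:
                continue
            seg_t = t[a:b]
            env = np.hanning(b - a)
            ph = rng.uniform(0, 2 * np.pi)
            wave = amp * env * np.sin(2 * np.pi * spec.iaf_hz * (seg_t - st) + ph)
            ev_gain = 1.0 + rng.uniform(-0.1, 0.1, size=len(parietal))
            for g, lab in zip(ev_gain, parietal):
                data[labels.index(lab), a:b] += g * wave
            spindle_intervals.append((st, en, label))

    # blinks on Fpz
    blink_times: list[float] = []
    if "Fpz" in labels:
        fi = labels.index("Fpz")
        w = int(round(spec.blink_duration_s * rate))
        template = spec.blink_amplitude_uv * 0.5 * (1 - np.cos(
            2 * np.pi * np.arange(w) / w))
        for label, s, e in spans:
            brate = _per_condition(spec.blink_rate_per_min, label)
            times = _poisson_times(rng, brate, s, max(s, e - spec.blink_duration_s))
            kept: list[float] = []
            for bt in times:
                if not kept or bt - kept[-1] >= 0.5:
                    kept.append(float(bt))
            counts.setdefault(label, {})["blinks"] = len(kept)
            for bt in kept:
                a = int(round(bt * rate))
                data[fi, a:a + w] += template[: n - a]
            blink_times.extend(kept)

    # ECG from the RR model, continuous across conditions
    r_times: list[float] = []
    if "ECG" in labels:
        ei = labels.index("ECG")
        total = spec.total_duration_s
        tb = 0.5  # first beat
        while tb < total - 0.5:
            r_times.append(tb)
            label = next(lab for lab, s, e in spans if s <= tb < e)
            rr = 60.0 / _per_condition(spec.hr_bpm, label, 70.0) + rng.normal(
                0.0, _per_condition(spec.rr_jitter_s, label, 0.05))
            tb += float(np.clip(rr, 0.4, 2.0))
        ecg = rng.normal(0.0, 5.0, size=n)  # electrode noise
        waves = (  # (offset s, amplitude uV, width s): P, Q, R, S, T
            (-0.20, 100.0, 0.040), (-0.025, -120.0, 0.010), (0.0, 900.0, 0.012),
            (0.025, -200.0, 0.010), (0.30, 220.0, 0.060),
        )
        for rt in r_times:
            a = max(0, int(round((rt - 0.35) * rate)))
            b = min(n, int(round((rt + 0.55) * rate)))
            seg = t[a:b]
            for off, amp, width in waves:
                ecg[a:b] += amp * np.exp(-0.5 * ((seg - rt - off) / width) ** 2)
        data[ei] = ecg
        for label, s, e in spans:
            counts.setdefault(label, {})["beats"] = int(
                sum(s <= rt < e for rt in r_times))

    annotations = [ConditionAnnotation(lab, s, e) for lab, s, e in spans]
    rec = Recording(
        data, rate, labels, annotations,
        meta={"synthetic": True, "seed": spec.seed, "iaf_hz": spec.iaf_hz},
    )
    truth = SyntheticGroundTruth(
        spindle_intervals, np.asarray(blink_times), np.asarray(r_times),
        counts, spec.iaf_hz, spec.seed,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

_DRIVING = ("WUP", "PERFO", "TAV", "DROW")


def _preset(durations: dict[str, float], seed: int) -> SessionSpec:
    return SessionSpec(
        conditions=tuple((lab, durations[lab]) for lab in ("OE",) + _DRIVING),
        alpha_uv={"OE": 4.0, "DROW": 2.25, "default": 2.0},
        spindle_rate_per_min={"OE": 0.0, "DROW": 6.0, "default": 0.5},
        spindle_amplitude_uv={"DROW": 15.0, "default": 4.0},
        spindle_duration_s={"DROW": (1.5, 2.0), "default": (0.5, 1.0)},
        blink_rate_per_min={"OE": 12.0, "DROW": 20.0, "default": 10.0},
        hr_bpm={"OE": 72.0, "WUP": 75.0, "PERFO": 78.0, "TAV": 78.0, "DROW": 60.0},
        rr_jitter_s={"DROW": 0.02, "default": 0.05},
        seed=seed,
    )


def paper_preset(seed: int = 0) -> SessionSpec:
    """Full-length session: OE 60 s, then WUP/PERFO/TAV/DROW of 780/700/760/1470 s."""
    return _preset(
        {"OE": 60.0, "WUP": 780.0, "PERFO": 700.0, "TAV": 760.0, "DROW": 1470.0}, seed
    )


def fast_preset(seed: int = 0) -> SessionSpec:
    """Driving conditions at one tenth length; the 60-s baseline is kept intact."""
    return _preset(
        {"OE": 60.0, "WUP": 78.0, "PERFO": 70.0, "TAV": 76.0, "DROW": 147.0}, seed
    )


# ---------------------------------------------------------------------------
# event-level evaluation
# ---------------------------------------------------------------------------


def _overlaps(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def evaluate_detection(
    mdrow: MDrowSeries,
    truth: SyntheticGroundTruth,
    tolerance_s: float = 15.0,
    condition: str | None = None,
) -> DetectionReport:
    """Event-level sensitivity and precision of the nonzero index regions.

    Sensitivity: fraction of ground-truth spindle intervals overlapping a
    nonzero region dilated by ``tolerance_s``. Precision: fraction of maximal
    nonzero regions overlapping a dilated truth interval. Latency per detected
    event: earliest nonzero time no earlier than ``tolerance_s`` before the
    spindle start, minus the spindle start (negative down to ``-tolerance_s``
    when the centered window raises the index ahead of the event).
    Empty truth leaves sensitivity as None.
    """
    span = (float(mdrow.times_s.min()),
            float(mdrow.times_s.max()) + mdrow.epoch_len_s)
    if condition is None:
        intervals = [(s, e) for s, e, _ in truth.spindle_intervals]
    else:
        intervals = truth.spindles_in(condition)
    intervals = [iv for iv in intervals if _overlaps(iv, span)]
    regions = mdrow.nonzero_regions()
    dilated = [(s - tolerance_s, e + tolerance_s) for s, e in regions]

    latencies: list[float] = []
    hits = 0
    for iv in intervals:
        over = [r for r, d in zip(regions, dilated) if _overlaps(iv, d)]
        if over:
            hits += 1
            detect = min(max(r[0], iv[0] - tolerance_s) for r in over)
            latencies.append(detect - iv[0])
    sensitivity = hits / len(intervals) if intervals else None

    dil_truth = [(s - tolerance_s, e + tolerance_s) for s, e in intervals]
    if regions:
        good = sum(any(_overlaps(r, dt) for dt in dil_truth) for r in regions)
        precision = good / len(regions)
    else:
        precision = None

    return DetectionReport(
        sensitivity, precision, latencies, len(intervals), len(regions), tolerance_s
    )
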