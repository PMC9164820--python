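"""Autonomic comparison branch: eyeblink rate and ECG-derived heart metrics.

Blinks are read from a prefrontal (Fpz) channel: the trace is low-pass
filtered below 8 Hz and positive deflections exceeding an adaptive
median-absolute-deviation threshold are counted, with a refractory period.
This is a transparent template-free detector with the contract of the more
elaborate blink-isolation methods used in driver-monitoring studies.

QRS detection follows the classic Pan-Tompkins chain: band-pass 5-15 Hz,
derivative, squaring, 150-ms moving-window integration, adaptive
dual-threshold peak acceptance with a 200-ms refractory period and RR-based
searchback. Heart rate and its variability (SDNN, RMSSD) are computed from
the corrected RR series, per condition when annotations are supplied.

Both branches are referenced to the eyes-open baseline by plain subtraction
(the primed metrics EBR', HR', HRV').
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "BlinkSeries",
    "HeartMetrics",
    "BaselinedMetric",
    "detect_blinks",
    "pan_tompkins",
    "baseline_subtract",
]

RR_BOUNDS_S = (0.3, 2.0)  # physiological RR interval bounds used for correction


@dataclass
class BlinkSeries:
    """Detected blink times and per-condition blink rates."""

    blink_times_s: np.ndarray
    duration_s: float
    refractory_s: float = 0.25
    ebr_per_min: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.blink_times_s = np.asarray(self.blink_times_s, dtype=float)
        if self.blink_times_s.size > 1:
            gaps = np.diff(self.blink_times_s)
            if (gaps <= 0).any():
                raise ValueError("blink times must be strictly increasing")
            if (gaps < self.refractory_s - 1e-9).any():
                raise ValueError("blink times violate the refractory period")

    @property
    def n_blinks(self) -> int:
        return self.blink_times_s.size

    def rate_in(self, start_s: float, end_s: float) -> float:
        """Blinks per minute within [start_s, end_s)."""
        n = int(
            ((self.blink_times_s >= start_s) & (self.blink_times_s < end_s)).sum()
        )
        minutes = (end_s - start_s) / 60.0
        return n / minutes if minutes > 0 else 0.0


@dataclass
class HeartMetrics:
    """R-peak times and RR-derived summaries."""

    r_times_s: np.ndarray
    rr_s: np.ndarray               # corrected RR intervals (gaps removed)
    rr_start_s: np.ndarray         # start time of each RR interval
    hr_bpm: float
    sdnn_ms: float
    rmssd_ms: float
    inverted: bool = False
    by_condition: dict[str, dict[str, float]] = field(default_factory=dict)

    def metrics_in(self, start_s: float, end_s: float) -> dict[str, float]:
        """HR/SDNN/RMSSD from RR intervals lying fully within [start_s, end_s)."""
        m = (self.rr_start_s >= start_s) & (self.rr_start_s + self.rr_s <= end_s)
        rr = self.rr_s[m]
        if rr.size == 0:
            return {"hr_bpm": float("nan"), "sdnn_ms": float("nan"),
                    "rmssd_ms": float("nan"), "n_rr": 0}
        return {
            "hr_bpm": 60.0 / float(rr.mean()),
            "sdnn_ms": float(rr.std(ddof=1)) * 1e3 if rr.size > 1 else 0.0,
            "rmssd_ms": float(np.sqrt(np.mean(np.diff(rr) ** 2))) * 1e3
            if rr.size > 1 else 0.0,
            "n_rr": int(rr.size),
        }


@dataclass(frozen=True)
class BaselinedMetric:
    """A metric referenced to its eyes-open value: primed = raw - oe_value."""

    raw: float
    oe_value: float

    @property
    def primed(self) -> float:
        return self.raw - self.oe_value


def baseline_subtract(raw, oe_value):
    """Vectorized construction of baselined metrics.

    Scalars give one :class:`BaselinedMetric`; sequences give a list in the
    same order.
    """
    if np.ndim(raw) == 0:
        return BaselinedMetric(float(raw), float(oe_value))
    oe = np.broadcast_to(np.asarray(oe_value, dtype=float), np.shape(raw))
    return [BaselinedMetric(float(r), float(o)) for r, o in zip(np.ravel(raw), np.ravel(oe))]


# ---------------------------------------------------------------------------
# blink detection
# ---------------------------------------------------------------------------


def detect_blinks(
    fpz: np.ndarray,
    rate: float,
    lowpass_hz: float = 8.0,
    k_mad: float = 6.0,
    refractory_s: float = 0.25,
    annotations=None,
) -> BlinkSeries:
    """Detect blinks as supra-threshold positive deflections below 8 Hz.

    The threshold is ``k_mad`` times the median absolute deviation of the
    low-passed, median-centred trace. A flat trace (MAD = 0) yields an empty
    series with a warning. When ``annotations`` (ConditionAnnotation list) is
    given, per-condition blink rates are filled in.
    """
    x = np.asarray(fpz, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a single-channel trace")
    duration = x.size / rate
    if duration < 5.0:
        raise ValueError(f"need >= 5 s of signal, got {duration:.2f} s")

    sos = signal.butter(4, lowpass_hz, btype="lowpass", fs=rate, output="sos")
    xf = signal.sosfiltfilt(sos, x)
    xf = xf - np.median(xf)
    mad = float(np.median(np.abs(xf)))
    if mad == 0.0:
        warnings.warn("flat trace (MAD = 0): no blinks detected", stacklevel=2)
        times = np.array([])
    else:
        locs, _ = signal.find_peaks(
            xf, height=k_mad * mad, distance=max(1, int(round(refractory_s * rate)))
        )
        times = locs / rate

    series = BlinkSeries(times, duration, refractory_s)
    if annotations:
        for ann in annotations:
            series.ebr_per_min[ann.label] = series.rate_in(ann.start_s, ann.end_s)
    return series


# ---------------------------------------------------------------------------
# Pan-Tompkins QRS detection
# ---------------------------------------------------------------------------


def _pt_stages(ecg: np.ndarray, rate: float) -> tuple[np.ndarray, np.ndarray, bool]:
    """Band-pass, polarity correction, derivative, squaring, integration."""
    sos = signal.butter(2, [5.0, 15.0], btype="bandpass", fs=rate, output="sos")
    bp = signal.sosfiltfilt(sos, ecg)
    inverted = bool(abs(bp.min()) > abs(bp.max()))
    if inverted:
        bp = -bp
    deriv = np.gradient(bp) * rate
    squared = deriv**2
    w = max(1, int(round(0.150 * rate)))
    mwi = np.convolve(squared, np.ones(w) / w, mode="same")
    return bp, mwi, inverted


def pan_tompkins(
    ecg: np.ndarray,
    rate: float,
    annotations=None,
) -> HeartMetrics:
    """Classic Pan-Tompkins R-peak detection and RR-derived metrics.

    Raises a data error naming the failing stage when no peaks survive.
    Polarity is auto-detected from the band-passed trace, so an inverted lead
    yields the same R times.
    """
    x = np.asarray(ecg, dtype=float)
    if rate < 100:
        raise ValueError(f"rate {rate} Hz too low for QRS detection (need >= 100)")
    if x.size / rate < 10.0:
        raise ValueError("need >= 10 s of ECG")

    bp, mwi, inverted = _pt_stages(x, rate)

    refractory = int(round(0.200 * rate))
    cand, _ = signal.find_peaks(mwi, distance=refractory)
    if cand.size == 0:
        raise ValueError("Pan-Tompkins integration stage produced no candidate peaks")

    # Adaptive dual thresholds on the integrated signal.
    init = mwi[: int(2 * rate)]
    spki = float(init.max()) * 0.5 if init.size else float(mwi.max()) * 0.5
    npki = float(init.mean()) * 0.5 if init.size else 0.0
    accepted: list[int] = []
    rr_hist: list[float] = []

    def threshold1() -> float:
        return npki + 0.25 * (spki - npki)

    for c in cand:
        peak = mwi[c]
        if peak > threshold1():
            # searchback is handled implicitly by the low second threshold below
            if accepted and (c - accepted[-1]) < refractory:
                continue
            accepted.append(c)
            spki = 0.125 * peak + 0.875 * spki
            if len(accepted) > 1:
                rr_hist.append((accepted[-1] - accepted[-2]) / rate)
                rr_hist[:] = rr_hist[-8:]
        else:
            npki = 0.125 * peak + 0.875 * npki
        # Searchback: if the gap since the last accepted beat exceeds 1.66x
        # the running RR average, re-scan the interval with half threshold.
        if accepted and rr_hist:
            rr_avg = float(np.mean(rr_hist))
            if (c - accepted[-1]) / rate > 1.66 * rr_avg:
                seg = [
                    s for s in cand
                    if accepted[-1] + refractory < s <= c
                    and mwi[s] > 0.5 * threshold1()
                ]
                if seg:
                    best = max(seg, key=lambda s: mwi[s])
                    if best != c:
                        accepted.append(best)
                        accepted.sort()
                        spki = 0.125 * mwi[best] + 0.875 * spki

    if not accepted:
        raise ValueError("Pan-Tompkins thresholding stage accepted no peaks")

    # Refine each R time on the band-passed waveform (zero-phase chain, so the
    # QRS lies within the integration window around the MWI peak).
    half = int(round(0.100 * rate))
    r_idx = []
    for c in accepted:
        lo, hi = max(0, c - half), min(bp.size, c + half + 1)
        r_idx.append(lo + int(np.argmax(bp[lo:hi])))
    r_idx = np.unique(r_idx)
    r_times = r_idx / rate

    # RR correction: merge implausibly short intervals (drop the later peak),
    # treat implausibly long ones as gaps (excluded from the statistics).
    keep = [0]
    for i in range(1, r_times.size):
        if r_times[i] - r_times[keep[-1]] >= RR_BOUNDS_S[0]:
            keep.append(i)
    r_times = r_times[keep]
    rr_all = np.diff(r_times)
    valid = rr_all <= RR_BOUNDS_S[1]
    rr = rr_all[valid]
    rr_start = r_times[:-1][valid]
    if rr.size == 0:
        raise ValueError("RR-correction stage left no valid intervals")

    metrics = HeartMetrics(
        r_times_s=r_times,
        rr_s=rr,
        rr_start_s=rr_start,
        hr_bpm=60.0 / float(rr.mean()),
        sdnn_ms=float(rr.std(ddof=1)) * 1e3 if rr.size > 1 else 0.0,
        rmssd_ms=float(np.sqrt(np.mean(np.diff(rr) ** 2))) * 1e3 if rr.size > 1 else 0.0,
        inverted=inverted,
    )
    if annotations:
        for ann in annotations:
            metrics.by_condition[ann.label] = metrics.metrics_in(ann.start_s, ann.end_s)
    return metrics
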