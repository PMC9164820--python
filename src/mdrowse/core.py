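"""The drowsiness index: Alpha-OE ratio, threshold, spindle peaks, MDrow.

Pipeline, per session:

1. **Alpha-OE ratio** — per-epoch alpha-band GFP divided by the *maximum*
   alpha GFP observed during the eyes-open (OE) baseline, where alpha is
   assumed maximal at rest. Dimensionless, comparable across subjects.
2. **Threshold** — ``mean + 3 * std`` of the ratio during a reference
   "normal driving" segment (default WUP). Exceedances indicate alpha
   synchronization beyond the normal state.
3. **Peaks** — local maxima of the ratio above the threshold, with
   amplitude = max value - threshold and duration = the interval between the
   flanking local minima; summarized per condition as rate/amplitude/duration.
4. **MDrow** — the rectified excess ``(ratio - threshold)+`` convolved with a
   30-s rectangular window normalized to unit area (a moving average of the
   excess). Nonzero values flag drowsiness episodes; the percentage of
   nonzero samples summarizes a condition.

Rejected epochs leave gaps: peak detection runs per contiguous clean run (run
boundaries act as minima) and the excess is zero at missing epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .spectral import GFPSeries

__all__ = [
    "AlphaOESeries",
    "DrowsinessThreshold",
    "Peak",
    "PeakSummary",
    "MDrowSeries",
    "DistributionStats",
    "alpha_oe_ratio",
    "compute_threshold",
    "detect_peaks",
    "compute_mdrow",
    "distribution_stats",
]


@dataclass
class AlphaOESeries:
    """Per-clean-epoch Alpha-OE ratio (dimensionless, >= 0)."""

    values: np.ndarray
    times_s: np.ndarray
    condition: list[str]
    oe_max: float
    epoch_len_s: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.values.shape != self.times_s.shape:
            raise ValueError("values and times must align")
        if not self.oe_max > 0:
            raise ValueError("oe_max must be positive")

    def __len__(self) -> int:
        return self.values.size

    def where_condition(self, label: str) -> "AlphaOESeries":
        m = np.array([c == label for c in self.condition])
        return AlphaOESeries(
            self.values[m],
            self.times_s[m],
            [c for c in self.condition if c == label],
            self.oe_max,
            self.epoch_len_s,
        )


@dataclass(frozen=True)
class DrowsinessThreshold:
    """Individual threshold: mean + 3 * std of the reference-condition ratio."""

    value: float
    ref_condition: str
    mean_ref: float
    std_ref: float


@dataclass(frozen=True)
class Peak:
    """A supra-threshold local maximum of the Alpha-OE ratio."""

    t_max_s: float
    amplitude: float      # max value - threshold, ratio units
    onset_s: float        # flanking local minimum before (or run start)
    offset_s: float       # flanking local minimum after (or run end)
    condition: str = "unassigned"

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass(frozen=True)
class PeakSummary:
    """Per-condition peak statistics; mean fields are None when n_peaks = 0."""

    condition: str
    n_peaks: int
    rate_per_min: float
    mean_amplitude: float | None
    mean_duration_s: float | None


@dataclass
class MDrowSeries:
    """The convolved index on a uniform epoch grid (zeros at rejected epochs)."""

    values: np.ndarray
    times_s: np.ndarray
    window_s: float
    nonzero_pct: float
    coverage: float       # fraction of grid epochs backed by a clean epoch
    epoch_len_s: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if (self.values < -1e-12).any():
            raise ValueError("MDrow values must be non-negative")
        if not (0.0 <= self.nonzero_pct <= 100.0):
            raise ValueError("nonzero_pct out of [0, 100]")

    def nonzero_regions(self) -> list[tuple[float, float]]:
        """Maximal intervals [start, end) where the index is positive."""
        pos = self.values > 0
        regions = []
        start = None
        for i, p in enumerate(pos):
            if p and start is None:
                start = self.times_s[i]
            elif not p and start is not None:
                regions.append((start, self.times_s[i]))
                start = None
        if start is not None:
            regions.append((start, self.times_s[-1] + self.epoch_len_s))
        return regions


@dataclass(frozen=True)
class DistributionStats:
    """Median and adjusted Fisher-Pearson skewness of a condition's ratio."""

    condition: str
    median: float
    skewness: float
    n: int


# ---------------------------------------------------------------------------


def alpha_oe_ratio(gfp: GFPSeries, oe_gfp: GFPSeries) -> AlphaOESeries:
    """Reference the GFP series to the eyes-open maximum."""
    if len(oe_gfp) == 0:
        raise ValueError("empty eyes-open baseline")
    oe_max = oe_gfp.max
    if not oe_max > 0:
        raise ValueError("degenerate eyes-open baseline: max GFP is zero")
    return AlphaOESeries(
        gfp.values / oe_max,
        gfp.times_s,
        list(gfp.condition),
        oe_max,
        gfp.epoch_len_s,
    )


def compute_threshold(
    ratio_ref: AlphaOESeries,
    condition: str | None = None,
    ddof: int = 0,
    n_std: float = 3.0,
) -> DrowsinessThreshold:
    """Individual threshold from the reference condition's ratio values.

    Uses the population (n-denominator) standard deviation by default;
    ``ddof=1`` gives the sample variant.
    """
    if condition is not None:
        ratio_ref = ratio_ref.where_condition(condition)
    vals = ratio_ref.values
    if vals.size < 2:
        raise ValueError(
            f"need >= 2 reference values to form a threshold, got {vals.size}"
        )
    mean = float(vals.mean())
    std = float(vals.std(ddof=ddof))
    label = condition if condition is not None else (
        ratio_ref.condition[0] if ratio_ref.condition else "reference"
    )
    return DrowsinessThreshold(mean + n_std * std, label, mean, std)


# -- peak detection ---------------------------------------------------------


def _contiguous_runs(times: np.ndarray, step: float) -> list[np.ndarray]:
    """Indices of maximal runs of consecutively spaced samples."""
    if times.size == 0:
        return []
    breaks = np.flatnonzero(np.abs(np.diff(times) - step) > step * 1e-6)
    return [np.arange(a, b + 1) for a, b in
            zip(np.r_[0, breaks + 1], np.r_[breaks, times.size - 1])]


def _local_extrema(x: np.ndarray) -> tuple[list[int], list[int]]:
    """Interior local maxima and minima of ``x``, plateau-aware.

    A maximal flat segment strictly above (below) both neighbours is a
    maximum (minimum); its first sample is the representative index.
    Endpoints are never extrema (run boundaries are handled by the caller).
    """
    n = x.size
    maxima: list[int] = []
    minima: list[int] = []
    i = 1
    while i < n - 1:
        if x[i] == x[i - 1]:
            i += 1
            continue
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        if j >= n - 1:
            break
        if x[i] > x[i - 1] and x[j + 1] < x[i]:
            maxima.append(i)
        elif x[i] < x[i - 1] and x[j + 1] > x[i]:
            minima.append(i)
        i = j + 1
    return maxima, minima


def detect_peaks(
    ratio: AlphaOESeries,
    thr: DrowsinessThreshold,
    conditions: list[str] | None = None,
) -> tuple[list[Peak], dict[str, PeakSummary]]:
    """Supra-threshold local maxima within each contiguous clean run.

    Returns the peak list and per-condition summaries with
    ``rate = n_peaks / clean minutes in that condition``. ``conditions``
    restricts the summary (and the peak list) to the given labels.
    """
    peaks: list[Peak] = []
    step = ratio.epoch_len_s
    for run in _contiguous_runs(ratio.times_s, step):
        x = ratio.values[run]
        t = ratio.times_s[run]
        maxima, minima = _local_extrema(x)
        min_set = np.array(sorted(set(minima) | {0, x.size - 1}))
        for m in maxima:
            if x[m] <= thr.value:
                continue
            before = min_set[min_set < m]
            after = min_set[min_set > m]
            onset = t[before[-1]] if before.size else t[0]
            offset = t[after[0]] if after.size else t[-1]
            peaks.append(
                Peak(
                    t_max_s=float(t[m]),
                    amplitude=float(x[m] - thr.value),
                    onset_s=float(onset),
                    offset_s=float(offset),
                    condition=ratio.condition[run[m]],
                )
            )

    if conditions is None:
        conditions = list(dict.fromkeys(ratio.condition))
    else:
        peaks = [p for p in peaks if p.condition in conditions]

    summaries: dict[str, PeakSummary] = {}
    for cond in conditions:
        cond_peaks = [p for p in peaks if p.condition == cond]
        n_clean = sum(c == cond for c in ratio.condition)
        minutes = n_clean * step / 60.0
        summaries[cond] = PeakSummary(
            condition=cond,
            n_peaks=len(cond_peaks),
            rate_per_min=len(cond_peaks) / minutes if minutes > 0 else 0.0,
            mean_amplitude=(
                float(np.mean([p.amplitude for p in cond_peaks])) if cond_peaks else None
            ),
            mean_duration_s=(
                float(np.mean([p.duration_s for p in cond_peaks])) if cond_peaks else None
            ),
        )
    return peaks, summaries


# -- the index --------------------------------------------------------------


def compute_mdrow(
    ratio: AlphaOESeries,
    thr: DrowsinessThreshold,
    window_s: float = 30.0,
    causal: bool = False,
    span: tuple[float, float] | None = None,
) -> MDrowSeries:
    """Moving average of the rectified excess over the threshold.

    The series is evaluated on the full uniform epoch grid covering ``span``
    (default: the ratio's own extent); missing (rejected) epochs contribute
    zero excess but stay in the grid and in the nonzero-percentage
    denominator. The window is centered; for even window lengths the extra
    sample sits on the trailing (past) side, i.e. epoch t averages the excess
    over [t - L/2, t + L/2 - 1] epochs. ``causal=True`` uses a fully trailing
    window instead (the online variant).
    """
    step = ratio.epoch_len_s
    L = int(round(window_s / step))
    if L < 2:
        raise ValueError(f"window of {window_s} s spans fewer than 2 epochs")

    if span is None:
        if len(ratio) == 0:
            raise ValueError("empty ratio series and no span given")
        t0, t1 = float(ratio.times_s.min()), float(ratio.times_s.max()) + step
    else:
        t0, t1 = span
    n = int(round((t1 - t0) / step))
    grid = t0 + np.arange(n) * step

    excess = np.zeros(n)
    present = np.zeros(n, dtype=bool)
    idx = np.round((ratio.times_s - t0) / step).astype(int)
    ok = (idx >= 0) & (idx < n)
    excess[idx[ok]] = np.maximum(ratio.values[ok] - thr.value, 0.0)
    present[idx[ok]] = True

    kernel = np.ones(L) / L
    if causal:
        values = np.convolve(excess, kernel, mode="full")[:n]
    else:
        values = np.convolve(excess, kernel, mode="same")
    values = np.maximum(values, 0.0)

    nonzero_pct = 100.0 * float((values > 0).sum()) / n if n else 0.0
    return MDrowSeries(
        values, grid, window_s, nonzero_pct, float(present.mean()) if n else 0.0, step
    )


def distribution_stats(ratio: AlphaOESeries, condition: str) -> DistributionStats:
    """Median and adjusted Fisher-Pearson skewness of one condition's values."""
    vals = ratio.where_condition(condition).values
    if vals.size < 3:
        raise ValueError(f"need >= 3 values in {condition!r}, got {vals.size}")
    return DistributionStats(
        condition=condition,
        median=float(np.median(vals)),
        skewness=float(sstats.skew(vals, bias=False)),
        n=int(vals.size),
    )
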