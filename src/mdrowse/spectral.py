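"""Individual alpha frequency and alpha-band Global Field Power.

The alpha band is anchored to the subject: the Individual Alpha Frequency
(IAF) is the peak of the eyes-open resting spectrum within 7-13 Hz after
removal of the 1/f background, and the "strict" alpha band is IAF +- 1 Hz.

Per-epoch band power ("GFP" in the drowsiness-index sense) is computed from
Hann-windowed 1-s spectra: each parietal channel's demeaned segment is
windowed, Fourier-transformed, converted to a one-sided power spectrum with
window-power compensation, summed over the bins whose centre frequency falls
inside the band (inclusive at both edges, 1 Hz resolution for 1-s epochs),
and the band powers are averaged across the channel set. The classic
topographic variant (spatial standard deviation of the band-filtered signal)
is available as ``variant="spatial"`` for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .preprocess import EpochArray

__all__ = [
    "PARIETAL_CHANNELS",
    "PARIETO_OCCIPITAL_CHANNELS",
    "IAFEstimate",
    "GFPSeries",
    "estimate_iaf",
    "compute_gfp",
]

#: The nine 10-10 parietal-row electrodes used by default.
PARIETAL_CHANNELS = ("P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8")
#: Optional parieto-occipital extension.
PARIETO_OCCIPITAL_CHANNELS = ("PO7", "PO3", "POz", "PO4", "PO8")


@dataclass(frozen=True)
class IAFEstimate:
    """Peak alpha frequency and the strict band it induces."""

    iaf_hz: float
    search_range_hz: tuple[float, float]
    channels_used: tuple[str, ...]
    quality: float  # relative excess of the peak over the 1/f background (0 = fallback)

    @property
    def band_lo_hz(self) -> float:
        return self.iaf_hz - 1.0

    @property
    def band_hi_hz(self) -> float:
        return self.iaf_hz + 1.0

    @property
    def band(self) -> tuple[float, float]:
        return (self.band_lo_hz, self.band_hi_hz)


@dataclass
class GFPSeries:
    """One non-negative alpha-band power value (uV^2) per clean epoch."""

    values: np.ndarray
    times_s: np.ndarray
    condition: list[str]
    band: tuple[float, float]
    channels: tuple[str, ...]
    epoch_len_s: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.values.shape != self.times_s.shape:
            raise ValueError("values and times must align")
        if (self.values < 0).any():
            raise ValueError("band power cannot be negative")

    def __len__(self) -> int:
        return self.values.size

    @property
    def max(self) -> float:
        return float(self.values.max())


def _pick_channels(ep: EpochArray, channels) -> tuple[list[int], tuple[str, ...]]:
    want = set(channels)
    missing = want - set(ep.labels)
    if missing:
        raise KeyError(f"channels not in epoch array: {sorted(missing)}")
    idx = [i for i, lab in enumerate(ep.labels) if lab in want]
    return idx, tuple(ep.labels[i] for i in idx)


def hann_band_power(
    x: np.ndarray, rate: float, band: tuple[float, float]
) -> np.ndarray:
    """One-sided Hann-windowed band power of each row of ``x`` (uV^2).

    Demeans each row, applies a periodic Hann window, compensates for the
    window power (so the result estimates the signal's variance within the
    band), and sums the PSD bins with lo <= f <= hi inclusive.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    w = signal.windows.hann(n, sym=False)
    xd = x - x.mean(axis=-1, keepdims=True)
    X = np.fft.rfft(xd * w, axis=-1)
    psd = (np.abs(X) ** 2) / (rate * np.sum(w**2))
    if n % 2 == 0:
        psd[..., 1:-1] *= 2.0
    else:
        psd[..., 1:] *= 2.0
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    df = rate / n
    mask = (freqs >= band[0] - 1e-9) & (freqs <= band[1] + 1e-9)
    return psd[..., mask].sum(axis=-1) * df


def compute_gfp(
    ep: EpochArray,
    band: tuple[float, float],
    channels=PARIETAL_CHANNELS,
    variant: str = "spectral",
) -> GFPSeries:
    """Alpha-band GFP per clean epoch, averaged over the channel set.

    Only clean (unflagged) epochs contribute; rejected epochs leave gaps in
    the returned series. ``variant="spatial"`` instead averages the squared
    spatial standard deviation of the band-filtered signal over the epoch.
    """
    if not len(tuple(channels)):
        raise ValueError("empty channel set")
    if not (0 < band[0] < band[1] < ep.rate / 2):
        raise ValueError(f"band {band} outside (0, Nyquist)")
    idx, used = _pick_channels(ep, channels)
    keep = ep.clean_mask
    x = ep.epochs[keep][:, idx, :]  # (n_clean, n_ch, n_samp)

    if variant == "spectral":
        values = hann_band_power(x, ep.rate, band).mean(axis=1)
    elif variant == "spatial":
        sos = signal.butter(4, band, btype="bandpass", fs=ep.rate, output="sos")
        xb = signal.sosfiltfilt(sos, x, axis=-1)
        gfp_t = xb.std(axis=1, ddof=0)          # spatial SD per sample
        values = (gfp_t**2).mean(axis=-1)       # mean squared GFP over the epoch
    else:
        raise ValueError(f"unknown GFP variant {variant!r}")

    return GFPSeries(
        values,
        ep.start_times_s[keep],
        [c for c, k in zip(ep.condition, keep) if k],
        (float(band[0]), float(band[1])),
        used,
        ep.epoch_len_s,
    )


def estimate_iaf(
    oe: EpochArray,
    channels=PARIETAL_CHANNELS,
    search_range: tuple[float, float] = (7.0, 13.0),
    fallback_hz: float = 10.0,
    quality_floor: float = 0.5,
) -> IAFEstimate:
    """Estimate the individual alpha frequency from eyes-open epochs.

    Welch spectrum (2-s Hann windows, 50% overlap -> 0.5 Hz resolution) over
    the clean epochs of ``oe``, averaged across ``channels``; a log-log linear
    fit to the spectrum outside the search range models the 1/f background,
    and the IAF is the frequency of the largest residual peak inside the
    search range. If no peak exceeds the background by ``quality_floor``
    (relative excess), falls back to ``fallback_hz`` with quality 0.
    """
    idx, used = _pick_channels(oe, channels)
    keep = oe.clean_mask
    if not keep.any():
        raise ValueError("no clean eyes-open epochs to estimate the IAF from")
    if keep.sum() < 30:
        warnings.warn(
            f"only {int(keep.sum())} clean eyes-open epochs; "
            "IAF estimate may be unstable (30+ recommended)",
            stacklevel=2,
        )
    # Concatenate clean epochs per channel; residual seams are negligible for
    # a Welch average.
    x = np.concatenate(list(oe.epochs[keep][:, idx, :].transpose(1, 0, 2)), axis=-1)
    x = x.reshape(len(idx), -1)
    nper = min(int(2 * oe.rate), x.shape[1])
    freqs, psd = signal.welch(
        x, fs=oe.rate, window="hann", nperseg=nper, noverlap=nper // 2, axis=-1
    )
    psd = psd.mean(axis=0)

    lo, hi = search_range
    eps = psd.max() * 1e-15 + 1e-30
    logf = np.log10(freqs + 1e-12)
    logp = np.log10(psd + eps)
    fit_mask = (freqs >= 2.0) & (freqs <= 30.0) & ~((freqs >= lo) & (freqs <= hi))
    if fit_mask.sum() >= 2:
        coef = np.polyfit(logf[fit_mask], logp[fit_mask], 1)
        background = np.polyval(coef, logf)
    else:
        background = np.full_like(logp, np.median(logp))

    in_range = (freqs >= lo) & (freqs <= hi)
    residual = logp[in_range] - background[in_range]
    k = int(np.argmax(residual))
    quality = float(10.0 ** residual[k] - 1.0)
    if quality < quality_floor:
        warnings.warn(
            "no alpha peak rises above the 1/f background; "
            f"falling back to IAF = {fallback_hz} Hz",
            stacklevel=2,
        )
        return IAFEstimate(float(fallback_hz), (lo, hi), used, 0.0)
    return IAFEstimate(float(freqs[in_range][k]), (lo, hi), used, quality)
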