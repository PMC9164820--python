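"""Continuous-signal conditioning and epoch-level artifact screening.

The chain mirrors standard drowsiness-EEG practice: a mains notch plus a
2-40 Hz band-pass (both zero-phase so spindle timing is preserved), optional
removal of ocular/muscular components via an external decomposition, cutting
into fixed 1-s epochs, and flagging artifactual epochs by three rules:

* *threshold* — any sample beyond +-80 uV,
* *trend* — the least-squares line fit to the epoch has |slope| > 20 uV/s,
* *sample_to_sample* — any consecutive-sample jump larger than 25 uV.

An epoch is rejected when any channel violates any criterion; rejected epochs
leave gaps in every downstream series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io import Recording

__all__ = [
    "FilterSpec",
    "RejectionCriteria",
    "EpochArray",
    "apply_filters",
    "segment_epochs",
    "reject_artifacts",
    "decompose_and_remove_artifact_components",
    "correlation_selector",
]

FLAG_THRESHOLD = "threshold"
FLAG_TREND = "trend"
FLAG_STEP = "sample_to_sample"
ALL_FLAGS = frozenset({FLAG_THRESHOLD, FLAG_TREND, FLAG_STEP})


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase filter bank: mains notch + Butterworth band-pass.

    Defaults follow common ambulatory-EEG practice: 50 Hz notch (quality 30),
    2 Hz high-pass, 40 Hz low-pass, 4th-order band-pass applied
    forward-backward.
    """

    notch_hz: float = 50.0
    band_lo_hz: float = 2.0
    band_hi_hz: float = 40.0
    notch_q: float = 30.0
    order: int = 4

    def validate(self, rate: float) -> None:
        nyq = rate / 2.0
        if not (0 < self.band_lo_hz < self.band_hi_hz < nyq):
            raise ValueError(
                f"need 0 < lo < hi < Nyquist ({nyq} Hz); "
                f"got band {self.band_lo_hz}-{self.band_hi_hz} Hz"
            )
        if not (0 < self.notch_hz < nyq):
            raise ValueError(f"notch {self.notch_hz} Hz outside (0, {nyq})")


@dataclass(frozen=True)
class RejectionCriteria:
    """Bounds for the three artifact rules, in microvolt units."""

    amp_uv: float = 80.0
    slope_uv_per_s: float = 20.0
    step_uv: float = 25.0

    def __post_init__(self) -> None:
        if min(self.amp_uv, self.slope_uv_per_s, self.step_uv) <= 0:
            raise ValueError("all rejection bounds must be strictly positive")


@dataclass
class EpochArray:
    """Fixed-length epochs cut from a recording.

    Attributes
    ----------
    epochs : ndarray, shape (n_epochs, n_channels, n_samples)
        Epoch tensor in microvolts.
    rate : float
    epoch_len_s : float
    start_times_s : ndarray of epoch start times (seconds from recording start).
    condition : list of per-epoch condition labels ('unassigned' if none).
    flags : list of per-epoch frozensets drawn from the three rejection tags.
    labels : channel labels.
    """

    epochs: np.ndarray
    rate: float
    epoch_len_s: float
    start_times_s: np.ndarray
    condition: list[str]
    labels: list[str]
    flags: list[frozenset] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.start_times_s = np.asarray(self.start_times_s, dtype=float)
        if not self.flags:
            self.flags = [frozenset()] * self.n_epochs
        n_samp = int(round(self.epoch_len_s * self.rate))
        if self.epochs.ndim != 3 or self.epochs.shape[2] != n_samp:
            raise ValueError("every epoch must have epoch_len_s * rate samples")
        for f in self.flags:
            if not f <= ALL_FLAGS:
                raise ValueError(f"unknown rejection tags {set(f) - ALL_FLAGS}")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def clean_mask(self) -> np.ndarray:
        return np.array([not f for f in self.flags], dtype=bool)

    @property
    def clean_fraction(self) -> float:
        return float(self.clean_mask.mean()) if self.n_epochs else float("nan")

    def subset(self, mask) -> "EpochArray":
        idx = np.flatnonzero(np.asarray(mask)) if np.asarray(mask).dtype == bool \
            else np.asarray(mask, dtype=int)
        return EpochArray(
            self.epochs[idx],
            self.rate,
            self.epoch_len_s,
            self.start_times_s[idx],
            [self.condition[i] for i in idx],
            list(self.labels),
            [self.flags[i] for i in idx],
        )

    def where_condition(self, label: str) -> "EpochArray":
        return self.subset(np.array([c == label for c in self.condition]))


# ---------------------------------------------------------------------------


def apply_filters(rec: Recording, spec: FilterSpec | None = None) -> Recording:
    """Notch + band-pass the recording, zero-phase (forward-backward)."""
    spec = spec or FilterSpec()
    spec.validate(rec.rate)
    b_notch, a_notch = signal.iirnotch(spec.notch_hz, spec.notch_q, fs=rec.rate)
    sos = signal.butter(
        spec.order,
        [spec.band_lo_hz, spec.band_hi_hz],
        btype="bandpass",
        fs=rec.rate,
        output="sos",
    )
    out = signal.filtfilt(b_notch, a_notch, rec.data, axis=1)
    out = signal.sosfiltfilt(sos, out, axis=1)
    meta = dict(rec.meta)
    meta["filters"] = (
        f"notch {spec.notch_hz} Hz (Q={spec.notch_q}), "
        f"band-pass {spec.band_lo_hz}-{spec.band_hi_hz} Hz order {spec.order}, zero-phase"
    )
    return Recording(out, rec.rate, list(rec.labels), list(rec.annotations), meta)


def segment_epochs(rec: Recording, epoch_len_s: float = 1.0) -> EpochArray:
    """Cut non-overlapping consecutive epochs from t = 0.

    The trailing partial epoch is discarded. Each epoch's condition is the
    annotation whose half-open interval contains its start time.
    """
    n_samp = int(round(epoch_len_s * rec.rate))
    n_ep = rec.n_samples // n_samp
    if n_ep < 1:
        raise ValueError(
            f"recording of {rec.duration_s:.3f} s shorter than one {epoch_len_s}-s epoch"
        )
    cut = rec.data[:, : n_ep * n_samp]
    epochs = cut.reshape(rec.n_channels, n_ep, n_samp).transpose(1, 0, 2).copy()
    starts = np.arange(n_ep) * epoch_len_s
    condition = [rec.condition_at(t) for t in starts]
    return EpochArray(epochs, rec.rate, epoch_len_s, starts, condition, list(rec.labels))


def reject_artifacts(ep: EpochArray, crit: RejectionCriteria | None = None) -> EpochArray:
    """Flag epochs by the three criteria (union over channels).

    Returns a new EpochArray; data are untouched. The clean fraction is
    available as ``result.clean_fraction``.
    """
    crit = crit or RejectionCriteria()
    x = ep.epochs  # (n_ep, n_ch, n_samp)
    n_samp = x.shape[2]

    over_amp = np.abs(x).max(axis=2) > crit.amp_uv                  # (n_ep, n_ch)

    t = np.arange(n_samp) / ep.rate
    tc = t - t.mean()
    denom = (tc**2).sum()
    slope = (x * tc).sum(axis=2) / denom                            # OLS slope, uV/s
    over_trend = np.abs(slope) > crit.slope_uv_per_s

    over_step = (
        np.abs(np.diff(x, axis=2)).max(axis=2) > crit.step_uv
        if n_samp > 1
        else np.zeros(over_amp.shape, dtype=bool)
    )

    flags = []
    for i in range(ep.n_epochs):
        tags = set()
        if over_amp[i].any():
            tags.add(FLAG_THRESHOLD)
        if over_trend[i].any():
            tags.add(FLAG_TREND)
        if over_step[i].any():
            tags.add(FLAG_STEP)
        flags.append(frozenset(tags))

    return EpochArray(
        ep.epochs,
        ep.rate,
        ep.epoch_len_s,
        ep.start_times_s,
        list(ep.condition),
        list(ep.labels),
        flags,
    )


# ---------------------------------------------------------------------------
# component removal (delegated decomposition)
# ---------------------------------------------------------------------------


def correlation_selector(reference: np.ndarray, min_abs_corr: float = 0.5):
    """Selector choosing components correlated with a reference trace.

    Returns a callable ``(sources) -> list[int]`` picking every component whose
    absolute Pearson correlation with ``reference`` exceeds ``min_abs_corr``;
    if none exceeds it, the single most-correlated component is selected.
    """
    ref = np.asarray(reference, dtype=float)

    def select(sources: np.ndarray) -> list[int]:
        corrs = []
        for s in sources:
            sd = s.std()
            corrs.append(0.0 if sd == 0 else abs(np.corrcoef(s, ref)[0, 1]))
        corrs = np.asarray(corrs)
        chosen = np.flatnonzero(corrs > min_abs_corr)
        if chosen.size == 0:
            chosen = np.array([int(np.argmax(corrs))])
        return list(chosen)

    return select


def decompose_and_remove_artifact_components(
    rec: Recording,
    component_selector,
    seed: int = 0,
    n_components: int | None = None,
) -> Recording:
    """Decompose into independent components, zero the selected ones, rebuild.

    ``component_selector`` is either an explicit list of component indices or
    a callable ``(sources) -> indices`` (see :func:`correlation_selector`).
    The decomposition (FastICA) is deterministic given ``seed``, which is
    recorded in the result's ``meta``.
    """
    from sklearn.decomposition import FastICA

    if rec.n_channels < 2:
        raise ValueError("need at least 2 channels to decompose")
    ica = FastICA(
        n_components=n_components,
        random_state=seed,
        whiten="unit-variance",
        max_iter=2000,
    )
    sources = ica.fit_transform(rec.data.T)  # (n_samples, n_comp)

    if callable(component_selector):
        drop = list(component_selector(sources.T))
    else:
        drop = list(component_selector)
    n_comp = sources.shape[1]
    if len(set(drop)) >= n_comp:
        raise ValueError("refusing to drop all components")

    sources[:, drop] = 0.0
    rebuilt = ica.inverse_transform(sources).T
    meta = dict(rec.meta)
    meta["ica"] = {"seed": seed, "dropped": sorted(set(drop)), "n_components": n_comp}
    return Recording(rebuilt, rec.rate, list(rec.labels), list(rec.annotations), meta)
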