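"""Recording container and readers/writers for the supported dialects.

A :class:`Recording` is a channels-by-samples matrix in microvolts with a
sampling rate, ordered unique channel labels (10-10 nomenclature for EEG;
"ECG"/"EOG" allowed), condition annotations, and free-form metadata.

Supported on-disk dialects:

* **CSV** — first column ``time_s``, one column per channel, header row of
  labels. Values are microvolts. Lossless round-trip.
* **EDF/EDF+** — read through MNE, written by the minimal writer in
  :mod:`mdrowse._edf` (16-bit, so round-trip is exact to the quantization step).
* **BrainVision** (.vhdr/.vmrk/.eeg) — read-only, through MNE.

Condition annotations for CSV/EDF live in a sidecar TSV named
``<stem>.events.tsv`` with columns ``label``, ``start_s``, ``end_s``
(half-open intervals, seconds from recording start). BrainVision markers map
marker description -> condition label; a zero-duration marker opens a segment
that ends at the next marker (or the end of the recording).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _edf

__all__ = [
    "ConditionAnnotation",
    "Recording",
    "load_recording",
    "save_recording",
]

#: EDF physical-dimension declarations we know how to convert to microvolts.
_UNIT_TO_UV = {"uv": 1.0, "µv": 1.0, "μv": 1.0, "mv": 1e3, "v": 1e6}


class FormatError(ValueError):
    """Raised for unreadable or ill-formed recording files."""


class UnitError(ValueError):
    """Raised when a file declares no unit or one we refuse to rescale silently."""


@dataclass(frozen=True)
class ConditionAnnotation:
    """A labelled half-open interval [start_s, end_s) of the recording."""

    label: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not (0 <= self.start_s < self.end_s):
            raise ValueError(
                f"annotation {self.label!r}: need 0 <= start < end, "
                f"got [{self.start_s}, {self.end_s})"
            )

    def contains(self, t: float) -> bool:
        return self.start_s <= t < self.end_s


@dataclass
class Recording:
    """Continuous multichannel signal in microvolts.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    rate : float
        Sampling frequency in Hz.
    labels : list of str
        Unique channel names, one per row of ``data``.
    annotations : list of ConditionAnnotation
        Condition intervals; must lie within the recording.
    meta : dict
        Free-form provenance (source file, processing seeds, ...).
    """

    data: np.ndarray
    rate: float
    labels: list[str]
    annotations: list[ConditionAnnotation] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        self.labels = list(self.labels)
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        dur = self.duration_s
        for ann in self.annotations:
            if ann.end_s > dur + 1e-9:
                raise ValueError(
                    f"annotation {ann.label!r} [{ann.start_s}, {ann.end_s}) "
                    f"exceeds recording duration {dur:.3f} s"
                )

    # -- basic geometry -------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate

    # -- channel access -------------------------------------------------
    def channel(self, label: str) -> np.ndarray:
        """Return one channel as a 1-D array (a view)."""
        try:
            return self.data[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"no channel {label!r}") from None

    def pick(self, labels) -> "Recording":
        """Sub-recording with the given channels, in *this* recording's order.

        Selection is order-independent: the returned channel order is the
        canonical order of the parent recording, whatever order is requested.
        """
        want = set(labels)
        missing = want - set(self.labels)
        if missing:
            raise KeyError(f"no such channels: {sorted(missing)}")
        keep = [i for i, lab in enumerate(self.labels) if lab in want]
        return Recording(
            self.data[keep].copy(),
            self.rate,
            [self.labels[i] for i in keep],
            list(self.annotations),
            dict(self.meta),
        )

    def condition_spans(self, label: str) -> list[tuple[float, float]]:
        return [(a.start_s, a.end_s) for a in self.annotations if a.label == label]

    def condition_at(self, t: float) -> str:
        """Label of the first annotation containing time ``t``, else 'unassigned'."""
        for ann in self.annotations:
            if ann.contains(t):
                return ann.label
        return "unassigned"


# ---------------------------------------------------------------------------
# events sidecar
# ---------------------------------------------------------------------------

def events_sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix("").with_name(Path(path).stem + ".events.tsv")


def _load_events_tsv(path: Path) -> list[ConditionAnnotation]:
    df = pd.read_csv(path, sep="\t")
    needed = {"label", "start_s", "end_s"}
    if not needed <= set(df.columns):
        raise FormatError(f"{path}: events TSV must have columns {sorted(needed)}")
    return [
        ConditionAnnotation(str(r.label), float(r.start_s), float(r.end_s))
        for r in df.itertuples()
    ]


def _save_events_tsv(annotations: list[ConditionAnnotation], path: Path) -> None:
    pd.DataFrame(
        {
            "label": [a.label for a in annotations],
            "start_s": [a.start_s for a in annotations],
            "end_s": [a.end_s for a in annotations],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix == ".edf":
        return "edf"
    if suffix == ".vhdr":
        return "brainvision"
    raise FormatError(f"cannot infer dialect from suffix {suffix!r} of {path}")


def load_recording(
    path: str | Path,
    format: str | None = None,
    events: str | Path | None = None,
) -> Recording:
    """Load a recording (CSV / EDF / BrainVision) into microvolts.

    Annotations come from ``events`` if given, else from the ``.events.tsv``
    sidecar for CSV/EDF, else from embedded BrainVision markers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)

    if fmt == "csv":
        rec = _load_csv(path)
    elif fmt == "edf":
        rec = _load_edf(path)
    elif fmt == "brainvision":
        rec = _load_brainvision(path)
    else:
        raise FormatError(f"unknown format {fmt!r}")

    if events is not None:
        rec.annotations = _load_events_tsv(Path(events))
    elif fmt in ("csv", "edf"):
        sidecar = events_sidecar_path(path)
        if sidecar.exists():
            rec.annotations = _load_events_tsv(sidecar)
    rec.__post_init__()  # re-validate with annotations attached
    return rec


def _load_csv(path: Path) -> Recording:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2 or df.columns[0] != "time_s":
        raise FormatError(f"{path}: CSV dialect needs a leading 'time_s' column")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: need at least 2 samples to infer the rate")
    rate = (len(t) - 1) / (t[-1] - t[0])
    rate = round(rate, 6)
    labels = [str(c) for c in df.columns[1:]]
    data = df.iloc[:, 1:].to_numpy(dtype=float).T
    return Recording(data, rate, labels, meta={"source": str(path), "format": "csv"})


def _load_edf(path: Path) -> Recording:
    import mne

    dims = _edf.read_physical_dimensions(path)
    factors = []
    for d in dims:
        key = d.strip().lower()
        if key not in _UNIT_TO_UV:
            raise UnitError(
                f"{path}: physical dimension {d!r} is not a declared voltage unit "
                f"(accepted: uV, mV, V); refusing to rescale silently"
            )
        factors.append(_UNIT_TO_UV[key])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    # MNE scales recognised voltage dimensions to volts; convert back to uV.
    data = raw.get_data() * 1e6
    return Recording(
        data,
        float(raw.info["sfreq"]),
        list(raw.ch_names),
        meta={"source": str(path), "format": "edf"},
    )


def _load_brainvision(path: Path) -> Recording:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        except Exception as exc:  # mne raises various types for bad headers
            raise FormatError(f"{path}: unreadable BrainVision triplet: {exc}") from exc
    data = raw.get_data() * 1e6
    duration = data.shape[1] / float(raw.info["sfreq"])

    marks = [
        (float(on), float(du), str(desc))
        for on, du, desc in zip(
            raw.annotations.onset, raw.annotations.duration, raw.annotations.description
        )
        if str(desc).lower() != "new segment/"
    ]
    annotations: list[ConditionAnnotation] = []
    for i, (onset, dur, desc) in enumerate(marks):
        label = desc.split("/", 1)[1].strip() if "/" in desc else desc.strip()
        if dur > 0:
            end = onset + dur
        else:  # point marker: segment runs to the next marker or the end
            end = marks[i + 1][0] if i + 1 < len(marks) else duration
        if end > onset:
            annotations.append(ConditionAnnotation(label, onset, min(end, duration)))
    return Recording(
        data,
        float(raw.info["sfreq"]),
        list(raw.ch_names),
        annotations,
        meta={"source": str(path), "format": "brainvision"},
    )


# ---------------------------------------------------------------------------
# saving
# ---------------------------------------------------------------------------

def save_recording(rec: Recording, path: str | Path, format: str | None = None) -> None:
    """Write a recording as CSV (lossless) or EDF (16-bit quantized).

    A non-empty annotation list is written to the ``.events.tsv`` sidecar;
    an empty list writes no sidecar.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        df = pd.DataFrame(rec.data.T, columns=rec.labels)
        df.insert(0, "time_s", np.arange(rec.n_samples) / rec.rate)
        df.to_csv(path, index=False)
    elif fmt == "edf":
        _edf.write_edf(path, rec.data, rec.rate, rec.labels)
    else:
        raise FormatError(f"cannot write format {fmt!r} (csv and edf are supported)")
    if rec.annotations:
        _save_events_tsv(rec.annotations, events_sidecar_path(path))
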