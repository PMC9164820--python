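"""Session-level model object tying the pipeline together.

Follows the model/results convention of statistical packages: build a
:class:`DrowsinessModel` from a :class:`~mdrowse.io.Recording` (or from
files), call :meth:`~DrowsinessModel.fit`, and read everything off the
returned :class:`DrowsinessResults` — the individual alpha frequency, the
individual threshold, the peak inventory, the per-condition MDrow series and
distribution statistics, the autonomic comparison metrics, and a
``summary()`` table.

The fit is an estimation pass in the ordinary sense: the eyes-open baseline
fixes the alpha band and the normalization constant, the reference driving
segment fixes the exceedance threshold, and the scored conditions are then
evaluated under those fitted constants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import core, spectral
from .autonomic import BlinkSeries, HeartMetrics, detect_blinks, pan_tompkins
from .io import Recording, load_recording
from .preprocess import (
    EpochArray,
    FilterSpec,
    RejectionCriteria,
    apply_filters,
    correlation_selector,
    decompose_and_remove_artifact_components,
    reject_artifacts,
    segment_epochs,
)

__all__ = ["DrowsinessModel", "DrowsinessResults"]


class DrowsinessModel:
    """EEG drowsiness-index model for one recorded session.

    Parameters
    ----------
    recording : Recording
        Continuous multichannel data in microvolts with condition annotations
        covering at least the eyes-open baseline and the reference segment.
    oe_condition, reference_condition : str
        Labels of the eyes-open baseline (normalization) and the
        "normal driving" segment (threshold).
    score_conditions : list of str, optional
        Conditions to score; default: every annotated label except the
        baseline and the reference (the reference defines the threshold and
        is excluded from scoring).
    gfp_channels : tuple of str
        Channel set for the alpha-band GFP (default: the nine parietal
        electrodes present in the recording).
    rejection_scope : {"all", "analysis"}
        Whether the three artifact criteria consider every EEG channel or
        only the GFP channel set.
    ica : bool
        Remove the component most correlated with the blink channel before
        epoching (delegated decomposition; off by default — enable for real
        recordings with ocular contamination of the analysis channels).
    """

    def __init__(
        self,
        recording: Recording,
        *,
        oe_condition: str = "OE",
        reference_condition: str = "WUP",
        score_conditions: list[str] | None = None,
        gfp_channels=None,
        gfp_variant: str = "spectral",
        filter_spec: FilterSpec | None = None,
        rejection: RejectionCriteria | None = None,
        rejection_scope: str = "all",
        epoch_len_s: float = 1.0,
        window_s: float = 30.0,
        causal: bool = False,
        iaf_search: tuple[float, float] = (7.0, 13.0),
        iaf_fallback_hz: float = 10.0,
        iaf_quality_floor: float = 0.5,
        threshold_ddof: int = 0,
        ecg_channel: str = "ECG",
        blink_channel: str = "Fpz",
        ica: bool = False,
        ica_seed: int = 0,
    ) -> None:
        self.recording = recording
        self.oe_condition = oe_condition
        self.reference_condition = reference_condition
        labels = {a.label for a in recording.annotations}
        if score_conditions is None:
            seen = dict.fromkeys(a.label for a in recording.annotations)
            score_conditions = [
                c for c in seen if c not in (oe_condition, reference_condition)
            ]
        self.score_conditions = score_conditions
        for needed in (oe_condition, reference_condition):
            if needed not in labels:
                raise ValueError(f"recording has no {needed!r} annotation")
        if gfp_channels is None:
            gfp_channels = tuple(
                c for c in spectral.PARIETAL_CHANNELS if c in recording.labels
            )
        if not gfp_channels:
            raise ValueError("no parietal channels found; pass gfp_channels explicitly")
        self.gfp_channels = tuple(gfp_channels)
        self.gfp_variant = gfp_variant
        self.filter_spec = filter_spec or FilterSpec()
        self.rejection = rejection or RejectionCriteria()
        if rejection_scope not in ("all", "analysis"):
            raise ValueError("rejection_scope must be 'all' or 'analysis'")
        self.rejection_scope = rejection_scope
        self.epoch_len_s = epoch_len_s
        self.window_s = window_s
        self.causal = causal
        self.iaf_search = iaf_search
        self.iaf_fallback_hz = iaf_fallback_hz
        self.iaf_quality_floor = iaf_quality_floor
        self.threshold_ddof = threshold_ddof
        self.ecg_channel = ecg_channel
        self.blink_channel = blink_channel
        self.ica = ica
        self.ica_seed = ica_seed

    @classmethod
    def from_files(
        cls,
        eeg_path: str | Path,
        events_path: str | Path | None = None,
        format: str | None = None,
        **kwargs,
    ) -> "DrowsinessModel":
        rec = load_recording(eeg_path, format=format, events=events_path)
        return cls(rec, **kwargs)

    # ------------------------------------------------------------------
    def fit(self) -> "DrowsinessResults":
        rec = self.recording
        eeg_labels = [c for c in rec.labels if c != self.ecg_channel]
        eeg = rec.pick(eeg_labels)

        filtered = apply_filters(eeg, self.filter_spec)

        if self.ica and self.blink_channel in filtered.labels:
            reference = rec.channel(self.blink_channel)
            filtered = decompose_and_remove_artifact_components(
                filtered, correlation_selector(reference), seed=self.ica_seed
            )

        epochs = segment_epochs(filtered, self.epoch_len_s)
        if self.rejection_scope == "analysis":
            scope = [c for c in epochs.labels if c in self.gfp_channels]
            flags = reject_artifacts(
                EpochArray(
                    epochs.epochs[:, [epochs.labels.index(c) for c in scope], :],
                    epochs.rate, epochs.epoch_len_s, epochs.start_times_s,
                    list(epochs.condition), scope,
                ),
                self.rejection,
            ).flags
            epochs.flags = flags
        else:
            epochs = reject_artifacts(epochs, self.rejection)

        iaf = spectral.estimate_iaf(
            epochs.where_condition(self.oe_condition),
            channels=self.gfp_channels,
            search_range=self.iaf_search,
            fallback_hz=self.iaf_fallback_hz,
            quality_floor=self.iaf_quality_floor,
        )

        gfp = spectral.compute_gfp(
            epochs, iaf.band, channels=self.gfp_channels, variant=self.gfp_variant
        )
        oe_mask = np.array([c == self.oe_condition for c in gfp.condition])
        oe_gfp = spectral.GFPSeries(
            gfp.values[oe_mask], gfp.times_s[oe_mask],
            [self.oe_condition] * int(oe_mask.sum()),
            gfp.band, gfp.channels, gfp.epoch_len_s,
        )
        ratio = core.alpha_oe_ratio(gfp, oe_gfp)
        threshold = core.compute_threshold(
            ratio, self.reference_condition, ddof=self.threshold_ddof
        )
        peaks, peak_summaries = core.detect_peaks(
            ratio, threshold, conditions=self.score_conditions
        )

        mdrow: dict[str, core.MDrowSeries] = {}
        stats: dict[str, core.DistributionStats] = {}
        for cond in self.score_conditions + [self.reference_condition]:
            spans = rec.condition_spans(cond)
            if not spans:
                continue
            start, end = spans[0]
            # epoch grid aligned to the global t=0 epoching
            g0 = np.ceil(start / self.epoch_len_s) * self.epoch_len_s
            g1 = np.floor(end / self.epoch_len_s) * self.epoch_len_s
            sub = ratio.where_condition(cond)
            mdrow[cond] = core.compute_mdrow(
                sub, threshold, self.window_s, causal=self.causal, span=(g0, g1)
            )
            if len(sub) >= 3:
                stats[cond] = core.distribution_stats(ratio, cond)

        blinks: BlinkSeries | None = None
        heart: HeartMetrics | None = None
        if self.blink_channel in rec.labels:
            blinks = detect_blinks(
                rec.channel(self.blink_channel), rec.rate, annotations=rec.annotations
            )
        if self.ecg_channel in rec.labels:
            heart = pan_tompkins(
                rec.channel(self.ecg_channel), rec.rate, annotations=rec.annotations
            )

        return DrowsinessResults(
            model=self,
            iaf=iaf,
            threshold=threshold,
            ratio=ratio,
            peaks=peaks,
            peak_summaries=peak_summaries,
            mdrow=mdrow,
            stats=stats,
            clean_fraction=epochs.clean_fraction,
            epochs=epochs,
            blinks=blinks,
            heart=heart,
        )


@dataclass
class DrowsinessResults:
    """Fitted quantities and diagnostics for one session."""

    model: DrowsinessModel
    iaf: spectral.IAFEstimate
    threshold: core.DrowsinessThreshold
    ratio: core.AlphaOESeries
    peaks: list[core.Peak]
    peak_summaries: dict[str, core.PeakSummary]
    mdrow: dict[str, core.MDrowSeries]
    stats: dict[str, core.DistributionStats]
    clean_fraction: float
    epochs: EpochArray = field(repr=False)
    blinks: BlinkSeries | None = None
    heart: HeartMetrics | None = None

    # -- autonomic, baselined ------------------------------------------
    def autonomic_table(self) -> pd.DataFrame:
        """Raw and eyes-open-primed EBR/HR/SDNN/RMSSD per condition."""
        oe = self.model.oe_condition
        rows = []
        conds = [oe, self.model.reference_condition] + self.model.score_conditions
        for cond in conds:
            row: dict[str, float | str] = {"condition": cond}
            if self.blinks is not None:
                row["ebr_per_min"] = self.blinks.ebr_per_min.get(cond, float("nan"))
            if self.heart is not None:
                hm = self.heart.by_condition.get(cond, {})
                row["hr_bpm"] = hm.get("hr_bpm", float("nan"))
                row["sdnn_ms"] = hm.get("sdnn_ms", float("nan"))
                row["rmssd_ms"] = hm.get("rmssd_ms", float("nan"))
            rows.append(row)
        df = pd.DataFrame(rows).set_index("condition")
        for col in df.columns:
            df[col + "_primed"] = df[col] - df.loc[oe, col]
        return df

    # -- frames ---------------------------------------------------------
    def epoch_frame(self) -> pd.DataFrame:
        """Per-epoch series: time, condition, alpha-OE ratio, MDrow index."""
        df = pd.DataFrame(
            {
                "time_s": self.ratio.times_s,
                "condition": self.ratio.condition,
                "alpha_oe": self.ratio.values,
            }
        )
        md = pd.concat(
            [
                pd.DataFrame({"time_s": s.times_s, "mdrow": s.values})
                for s in self.mdrow.values()
            ]
        ) if self.mdrow else pd.DataFrame(columns=["time_s", "mdrow"])
        return df.merge(md, on="time_s", how="left")

    def peaks_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_max_s": [p.t_max_s for p in self.peaks],
                "amplitude": [p.amplitude for p in self.peaks],
                "onset_s": [p.onset_s for p in self.peaks],
                "offset_s": [p.offset_s for p in self.peaks],
                "duration_s": [p.duration_s for p in self.peaks],
                "condition": [p.condition for p in self.peaks],
            }
        )

    def condition_table(self) -> pd.DataFrame:
        rows = []
        for cond in [self.model.reference_condition] + self.model.score_conditions:
            st = self.stats.get(cond)
            ps = self.peak_summaries.get(cond)
            ms = self.mdrow.get(cond)
            rows.append(
                {
                    "condition": cond,
                    "n_epochs": st.n if st else 0,
                    "ratio_median": st.median if st else float("nan"),
                    "ratio_skewness": st.skewness if st else float("nan"),
                    "peak_rate_per_min": ps.rate_per_min if ps else float("nan"),
                    "peak_amplitude": (
                        ps.mean_amplitude if ps and ps.mean_amplitude is not None
                        else float("nan")
                    ),
                    "peak_duration_s": (
                        ps.mean_duration_s if ps and ps.mean_duration_s is not None
                        else float("nan")
                    ),
                    "mdrow_mean": float(ms.values.mean()) if ms else float("nan"),
                    "mdrow_median": float(np.median(ms.values)) if ms else float("nan"),
                    "mdrow_nonzero_pct": ms.nonzero_pct if ms else float("nan"),
                }
            )
        return pd.DataFrame(rows).set_index("condition")

    # -- reporting ------------------------------------------------------
    def summary(self) -> str:
        m = self.model
        lines = [
            "Drowsiness index results",
            "=" * 64,
            f"IAF: {self.iaf.iaf_hz:.2f} Hz (quality {self.iaf.quality:.2f}); "
            f"alpha band {self.iaf.band_lo_hz:.2f}-{self.iaf.band_hi_hz:.2f} Hz",
            f"GFP channels: {', '.join(self.iaf.channels_used)}",
            f"Clean epochs: {100 * self.clean_fraction:.1f}%",
            f"Threshold ({m.reference_condition}): {self.threshold.value:.4f} "
            f"(mean {self.threshold.mean_ref:.4f} + 3 x std {self.threshold.std_ref:.4f})",
            "",
            self.condition_table().to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        if self.blinks is not None or self.heart is not None:
            lines += ["", "Autonomic metrics (primed = condition - eyes-open):",
                      self.autonomic_table().to_string(
                          float_format=lambda v: f"{v:.4g}")]
        return "\n".join(lines)

    def summary_dict(self) -> dict:
        out = {
            "iaf_hz": self.iaf.iaf_hz,
            "iaf_quality": self.iaf.quality,
            "alpha_band_hz": list(self.iaf.band),
            "threshold": {
                "value": self.threshold.value,
                "reference_condition": self.threshold.ref_condition,
                "mean_ref": self.threshold.mean_ref,
                "std_ref": self.threshold.std_ref,
            },
            "clean_fraction": self.clean_fraction,
            "conditions": {},
        }
        for cond, row in self.condition_table().iterrows():
            out["conditions"][cond] = {
                k: (None if pd.isna(v) else float(v)) for k, v in row.items()
            }
        if self.blinks is not None or self.heart is not None:
            out["autonomic"] = {
                cond: {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
                for cond, row in self.autonomic_table().iterrows()
            }
        return out

    def save(self, outdir: str | Path) -> None:
        """Write the per-epoch CSV, the peaks CSV, and the JSON summary."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.epoch_frame().to_csv(outdir / "series.csv", index=False)
        self.peaks_frame().to_csv(outdir / "peaks.csv", index=False)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2)

    def plot(self, ax=None):
        """Ratio, threshold, and the index over time (matplotlib axes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        ax.plot(self.ratio.times_s, self.ratio.values, color="0.6", lw=0.5,
                label="Alpha-OE ratio")
        ax.axhline(self.threshold.value, color="k", ls="--", lw=1, label="threshold")
        for i, (cond, s) in enumerate(self.mdrow.items()):
            ax.plot(s.times_s, s.values, lw=1.5,
                    label=f"MDrow ({cond})" if i < 4 else None)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("ratio / index")
        ax.legend(loc="upper left", fontsize=8)
        return ax
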