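"""Filtering, epoching, and the three-criteria artifact screen."""

import numpy as np
import pytest

from mdrowse.preprocess import (
    EpochArray,
    FilterSpec,
    RejectionCriteria,
    apply_filters,
    correlation_selector,
    decompose_and_remove_artifact_components,
    reject_artifacts,
    segment_epochs,
)

from conftest import make_epochs, make_recording

RATE = 250.0


def _band_rms(x: np.ndarray, rate: float, lo: float, hi: float) -> float:
    """FFT-based RMS of the [lo, hi] band of a 1-D signal."""
    X = np.fft.rfft(x - x.mean())
    f = np.fft.rfftfreq(x.size, 1 / rate)
    sel = (f >= lo) & (f <= hi)
    power = 2 * np.abs(X[sel]) ** 2 / x.size**2
    return float(np.sqrt(power.sum()))


def _central_8s(x: np.ndarray, rate: float) -> np.ndarray:
    pad = int(rate)  # drop 1 s from each end of a 10-s signal
    return x[pad:-pad]


class TestFilters:
    def setup_method(self):
        self.t = np.arange(int(10 * RATE)) / RATE

    def test_mains_component_attenuated_40db(self):
        x = 10 * np.sin(2 * np.pi * 50 * self.t)
        out = apply_filters(make_recording(x, RATE)).data[0]
        rms_in = _band_rms(_central_8s(x, RATE), RATE, 49, 51)
        rms_out = _band_rms(_central_8s(out, RATE), RATE, 49, 51)
        assert 20 * np.log10(rms_in / rms_out) >= 40

    def test_alpha_band_passes_within_1db(self):
        x = 10 * np.sin(2 * np.pi * 10 * self.t)
        out = apply_filters(make_recording(x, RATE)).data[0]
        rms_in = _band_rms(_central_8s(x, RATE), RATE, 9, 11)
        rms_out = _band_rms(_central_8s(out, RATE), RATE, 9, 11)
        assert abs(20 * np.log10(rms_out / rms_in)) <= 1

    def test_dc_offset_removed(self):
        x = np.full(self.t.size, 100.0)
        out = apply_filters(make_recording(x, RATE)).data[0]
        assert abs(_central_8s(out, RATE).mean()) < 0.5

    def test_cutoff_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            apply_filters(
                make_recording(np.zeros(2500), RATE),
                FilterSpec(band_hi_hz=130.0),
            )

    def test_annotations_and_labels_survive(self):
        rec = make_recording(
            np.zeros((2, 2500)), RATE, ["Pz", "P3"], [("OE", 0, 5)]
        )
        out = apply_filters(rec)
        assert out.labels == rec.labels
        assert out.annotations == rec.annotations


class TestSegmentEpochs:
    def test_partial_trailing_epoch_dropped(self):
        rec = make_recording(np.zeros((1, int(10.6 * RATE))), RATE)
        ep = segment_epochs(rec)
        assert ep.n_epochs == 10
        assert ep.epochs.shape == (10, 1, 250)

    def test_condition_labels_half_open(self):
        rec = make_recording(np.zeros((1, 2500)), RATE, annotations=[("WUP", 2, 5)])
        ep = segment_epochs(rec)
        assert ep.condition == ["unassigned"] * 2 + ["WUP"] * 3 + ["unassigned"] * 5

    def test_no_annotations_all_unassigned(self):
        ep = segment_epochs(make_recording(np.zeros((1, 1000)), RATE))
        assert set(ep.condition) == {"unassigned"}

    def test_concatenation_consistency(self, rng):
        a = rng.normal(size=(2, 1000))  # 4 whole epochs
        b = rng.normal(size=(2, 700))
        ep_a = segment_epochs(make_recording(a, RATE))
        ep_ab = segment_epochs(make_recording(np.concatenate([a, b], axis=1), RATE))
        np.testing.assert_array_equal(ep_ab.epochs[:4], ep_a.epochs)


def _oracle_flags(epoch: np.ndarray, rate: float, crit: RejectionCriteria) -> frozenset:
    """Straightforward per-sample reimplementation of the three criteria."""
    tags = set()
    t = np.arange(epoch.shape[1]) / rate
    for ch in epoch:
        if any(abs(v) > crit.amp_uv for v in ch):
            tags.add("threshold")
        slope = np.polyfit(t, ch, 1)[0]
        if abs(slope) > crit.slope_uv_per_s:
            tags.add("trend")
        if any(abs(ch[i + 1] - ch[i]) > crit.step_uv for i in range(len(ch) - 1)):
            tags.add("sample_to_sample")
    return frozenset(tags)


class TestRejection:
    def test_spike_trips_threshold_and_step(self):
        ep = np.zeros((1, 1, 250))
        ep[0, 0, 125] = 100.0  # mid-epoch: negligible trend
        out = reject_artifacts(make_epochs(ep))
        assert out.flags[0] == {"threshold", "sample_to_sample"}

    def test_linear_ramp_trips_trend_only(self):
        ramp = np.linspace(0, 30, 250)[None, None, :]  # 30 uV/s, max step 0.12 uV
        out = reject_artifacts(make_epochs(ramp))
        assert out.flags[0] == {"trend"}

    def test_quiet_epoch_unflagged(self):
        out = reject_artifacts(make_epochs(np.zeros((1, 2, 250))))
        assert out.flags[0] == frozenset()
        assert out.clean_fraction == 1.0

    def test_flags_match_bruteforce_oracle(self, rng):
        crit = RejectionCriteria()
        n_ep = 300
        eps = rng.normal(0, 30, size=(n_ep, 2, 250))
        slopes = rng.uniform(-40, 40, size=(n_ep, 2))
        t = np.arange(250) / RATE
        eps += slopes[:, :, None] * t  # add random linear trends
        jumps = rng.random(n_ep) < 0.3
        eps[jumps, 0, 100] += rng.uniform(-60, 60, size=jumps.sum())
        out = reject_artifacts(make_epochs(eps), crit)
        for i in range(n_ep):
            assert out.flags[i] == _oracle_flags(eps[i], RATE, crit), f"epoch {i}"

    def test_permuting_epochs_permutes_flags(self, rng):
        eps = rng.normal(0, 50, size=(50, 1, 250))
        out = reject_artifacts(make_epochs(eps))
        perm = rng.permutation(50)
        out_p = reject_artifacts(make_epochs(eps[perm]))
        assert [out.flags[i] for i in perm] == list(out_p.flags)

    def test_amplitude_scaling_only_adds_flags(self, rng):
        eps = rng.normal(0, 40, size=(50, 1, 250))
        base = reject_artifacts(make_epochs(eps)).flags
        scaled = reject_artifacts(make_epochs(eps * 1.7)).flags
        for f0, f1 in zip(base, scaled):
            assert f0 <= f1

    def test_bounds_must_be_positive(self):
        with pytest.raises(ValueError, match="positive"):
            RejectionCriteria(amp_uv=-1.0)


class TestComponentRemoval:
    def _mixture(self, rng):
        t = np.arange(int(20 * RATE)) / RATE
        alpha = np.sin(2 * np.pi * 10 * t)
        blink = np.zeros_like(t)
        for start in (2.0, 6.5, 11.0, 15.5):  # 300-ms raised-cosine blinks
            w = int(0.3 * RATE)
            a = int(start * RATE)
            blink[a:a + w] += 0.5 * (1 - np.cos(2 * np.pi * np.arange(w) / w))
        mixing = rng.uniform(0.5, 2.0, size=(4, 2))
        data = mixing @ np.vstack([alpha, blink])
        data += rng.normal(0, 0.01, size=data.shape)
        return make_recording(data, RATE), blink

    def test_empty_selection_is_identity(self, rng):
        rec, _ = self._mixture(rng)
        out = decompose_and_remove_artifact_components(rec, [], seed=0)
        assert np.abs(out.data - rec.data).max() < 1e-6

    def test_blink_component_removal(self, rng):
        rec, blink = self._mixture(rng)
        out = decompose_and_remove_artifact_components(
            rec, correlation_selector(blink), seed=0
        )
        for ch in out.data:
            assert abs(np.corrcoef(ch, blink)[0, 1]) < 0.2

    def test_deterministic_given_seed(self, rng):
        rec, blink = self._mixture(rng)
        sel = correlation_selector(blink)
        a = decompose_and_remove_artifact_components(rec, sel, seed=7)
        b = decompose_and_remove_artifact_components(rec, sel, seed=7)
        np.testing.assert_array_equal(a.data, b.data)

    def test_refuses_to_drop_everything(self, rng):
        rec, _ = self._mixture(rng)
        with pytest.raises(ValueError, match="all components"):
            decompose_and_remove_artifact_components(rec, [0, 1, 2, 3], seed=0)
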