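# Methods

This note records the model implemented by `mdrowse`, the choices made where
the method description left room, and what the synthetic-data tests do and do
not demonstrate.

## The drowsiness index

Drowsiness at the wheel appears episodically as *alpha spindles*: brief
(0.5–2 s) bursts of alpha-band activity, most prominent over parietal sites.
The index tracks the degree of parietal alpha synchronization relative to the
individual's own resting level and flags epochs where it exceeds the
individual's "normal driving" variability.

Per 1-s epoch `t` and condition `i`:

```
Alpha-OE(t) = AlphaGFP_i(t) / max(AlphaGFP_OE)
Threshold   = mean(Alpha-OE_ref) + 3 * std(Alpha-OE_ref)        (ref = WUP)
MDrow(t)    = [ (Alpha-OE - Threshold)+ * box(30 s) ](t)
```

where `AlphaGFP` is the alpha-band power per epoch averaged over the parietal
electrodes, `OE` is a one-minute eyes-open baseline (alpha assumed maximal at
rest, so the ratio is ≤ ~1 in alert states and individual scales cancel),
`(x)+` is the rectified excess over the threshold, and `box(30 s)` is a
rectangular window normalized to unit area — i.e. a 30-s moving average of
the excess. Nonzero index values flag drowsiness episodes; a condition is
summarized by the percentage of nonzero samples, and epochs-level peaks
(local maxima of the ratio above the threshold) are summarized per condition
by rate, mean amplitude (max − threshold) and mean duration (interval between
the flanking local minima).

## Pipeline and parameter choices

**Filtering.** 50 Hz notch (IIR, Q = 30) and 2–40 Hz 4th-order Butterworth
band-pass, both applied forward–backward. Only cut-offs are prescribed by the
method; zero-phase realization was chosen so that filtering cannot displace
spindle events relative to the epoch grid.

**Artifact screen.** Per 1-s epoch and channel: absolute amplitude > 80 µV
(*threshold*), least-squares trend slope > 20 µV/s (*trend*), or any
consecutive-sample step > 25 µV (*sample-to-sample*). An epoch is rejected if
any channel violates any rule (whole-epoch removal); rejected epochs leave
gaps — no interpolation. The trend rule is realized as an ordinary
least-squares line fit per channel, the natural estimator of a within-epoch
linear trend. By default all EEG channels are screened
(`rejection_scope="all"`); the parietal-only variant is available because the
set of screened channels is not prescribed.

**Ocular/muscular components.** Component removal is delegated to FastICA
behind a pluggable selector (explicit indices, or highest correlation with a
blink reference trace), deterministic given a seed. It is off by default for
synthetic sessions (blinks are injected only on Fpz) and is cited
methodology, not the contribution.

**IAF.** Welch spectrum (2-s Hann windows, 50 % overlap → 0.5 Hz bins) of the
clean eyes-open epochs, averaged over the parietal set; a log–log linear fit
over 2–30 Hz excluding the 7–13 Hz search range models the 1/f background;
the IAF is the largest background-exceeding peak in the range. If no peak
exceeds the background by 50 % (`quality_floor = 0.5`), the estimate falls
back to 10 Hz with quality 0 and a warning. The strict alpha band is
IAF ± 1 Hz.

**GFP variant.** The per-epoch "GFP" is realized spectrally: demean each
parietal channel's 1-s segment, apply a periodic Hann window, form the
one-sided window-compensated power spectrum, sum the bins whose centre lies
in [IAF−1, IAF+1] **inclusive** (three bins at 1 Hz resolution for integer
IAF), and average across channels. The mean (not the sum) keeps the value
scale-free in the channel count; the classic topographic variant (spatial SD
of the band-filtered signal) is available as `gfp.variant = "spatial"` for
comparison but is not the default, because the source description is
spectral, not topographic.

**Threshold.** Population (n-denominator) standard deviation by default —
the threshold is a descriptive moment of the full reference segment — with
`ddof` exposed. The threshold is computed per session.

**Excess, not mask.** "Above the threshold" is realized as the rectified
excess `(ratio − threshold)+` rather than the raw ratio masked above
threshold: the index is then continuous in the data, exactly zero in the
normal state, and integrates the same amplitude information the peak
analysis reports.

**Convolution.** Window length 30 s normalized to unit area, evaluated on
the full epoch grid of the scored condition with zeros at rejected epochs
and zero padding at the edges. Centering convention: for the even 30-epoch
window the extra sample sits on the trailing side (epoch `t` averages
`[t−15, t+14]`). A fully trailing (causal) variant is provided for online
use. The nonzero percentage uses all epochs of the condition as denominator
(comparable across conditions); the clean-epoch fraction is reported
separately as `coverage`.

**Peaks.** Within each maximal run of consecutive clean epochs: a local
maximum is a sample strictly greater than both neighbours; the first sample
of a flat top counts, later equal samples do not (determinism); run
boundaries act as minima for onset/offset. Rates use clean minutes per
condition. Summaries with zero peaks report missing means, never zeros.

**Scored conditions.** The reference condition (WUP) defines the threshold
and is excluded from the scored set by default, matching the original
analysis protocol; it still appears in the summary tables.

**Autonomic branch.** Blinks: low-pass < 8 Hz, median-centred, positive
deflections above 6×MAD with a 0.25-s refractory period — a transparent
threshold detector with the same contract as the proprietary blink-isolation
methods used in this literature, which are out of scope. QRS: the classic
Pan–Tompkins chain (5–15 Hz band-pass, derivative, squaring, 150-ms
integration, adaptive dual thresholds with 200-ms refractory and RR-based
searchback), with polarity auto-detection and R-time refinement on the
band-passed trace. RR correction: intervals < 0.3 s merge (the later peak is
dropped); intervals > 2 s are treated as gaps and excluded from the
statistics. HRV is summarized as SDNN (sample SD of RR, ms) with RMSSD also
reported, one value per condition span. All autonomic metrics are baselined
by subtracting the eyes-open value (EBR′, HR′, HRV′).

## The synthetic-session generator

`simulate_session` emulates the statistical structure the method assumes —
not the biophysics. Each session is: 1/f background (spectrally shaped
Gaussian noise, exponent 1, RMS 10 µV) per channel; a sustained alpha
sinusoid at the configured IAF on the parietal channels with
condition-dependent amplitude; Hann-enveloped alpha-spindle bursts with
Poisson arrivals, coherent across the parietal set with ±10 % per-channel
gain jitter (the method reads regional synchronization, so ground-truth
events must synchronize the region); raised-cosine blink templates on Fpz;
and a PQRST-template ECG from an RR model with condition-dependent mean HR
and jitter. Overlapping spindle draws are merged (so at high rates realized
interval counts follow the merged-cluster expectation
`λT·E[exp(−λD)]`, not the raw Poisson mean, and merged intervals can exceed
the single-event duration range). All randomness flows from one seed;
identical seeds give identical sessions within one environment.

### Preset conditions

The `paper` preset mirrors a full protocol timeline — OE 60 s, then WUP 780,
PERFO 700, TAV 760, DROW 1470 s (two laps per condition at the reported mean
lap times). The `fast` preset scales the four driving conditions to one
tenth but keeps the 60-s OE baseline, which the IAF estimator needs
(≥ 30 clean eyes-open epochs).

Event rates and amplitudes encode the directional physiology the index is
meant to detect, and were fixed once by a design analysis before the test
suite was frozen:

| parameter | OE | WUP/PERFO/TAV | DROW | rationale |
|---|---|---|---|---|
| tonic alpha (µV) | 4.0 | 2.0 | 2.25 | alpha maximal at rest; mildly elevated tonic alpha in drowsiness carries the median contrast (≈ 4 SE of the median at fast-preset length) while keeping the alert-referenced threshold above the drowsy baseline |
| spindle rate (/min) | 0 | 0.5 | 6 | episodic drowsy events vs rare spurious alert-state synchronization |
| spindle amplitude (µV) | — | 4 | 15 | drowsy spindles are markedly stronger; 4 µV keeps a single alert outlier's sample skewness (~1) below the drowsy segment's (~2.5–3.5) |
| spindle duration (s) | — | U(0.5, 1.0) | U(1.5, 2.0) | drowsy spindles are longer, within the 0.5–2 s phenomenology |
| blink rate (/min) | 12 | 10 | 20 | blink rate rises with drowsiness |
| heart rate (bpm) | 72 | 75–78 | 60 | HR and HRV fall in drowsiness |
| RR jitter (s) | 0.05 | 0.05 | 0.02 | lower SDNN in drowsiness |

### What passing tests show — and what they do not

The generator provides exact ground truth, so the tests demonstrate that the
implementation recovers what it is defined to recover: injected IAF to
±0.5 Hz, injected spindles as supra-threshold index regions (event
sensitivity and precision ≈ 1 at 15-s tolerance on the presets), injected
blinks and R peaks to tens of milliseconds, and the expected ordering of all
condition summaries between drowsy and alert segments. They do **not** show
performance on real EEG: real recordings have non-stationary backgrounds,
ocular and muscular contamination of parietal channels, drifting IAF,
non-Poisson event statistics and imperfect condition annotations, none of
which the generator emulates.

One contrast is fragile *by construction* rather than by implementation: the
mean peak **duration**. With 1-s epochs, the flanking-local-minima duration
of any isolated peak is the sum of two roughly geometric(1/2) extrema
distances of an i.i.d. series — about 4 ± 2 s whatever its cause — so a
single spurious alert-state peak can out-last the drowsy-segment mean, and a
strict per-session ordering of mean durations cannot be guaranteed at any
event-rate setting. At the default presets the drowsy segment has the larger
mean duration in about three quarters of sessions; rate, amplitude, median,
skewness and nonzero percentage order correctly in essentially all of them.

## Numerical conventions and degenerate inputs

* Internal unit is microvolts; readers convert from declared units and
  refuse undeclared ones. Time is seconds from recording start; intervals
  are half-open `[start, end)`; epochs are cut from t = 0 and a trailing
  partial epoch is dropped.
* CSV round-trips are bit-exact (`float_precision="round_trip"` on read);
  EDF round-trips are exact to the 16-bit quantization step of the written
  physical range.
* Degenerate cases raise rather than guess: zero eyes-open maximum, fewer
  than two reference values for the threshold, fewer than three values for
  skewness, windows shorter than two epochs, flat traces in the blink
  detector (warning + empty result), empty decompositions, selectors that
  would drop every component.
* Problem sizes in the shipped tests (20 fast-preset sessions, 100 IAF
  runs, 1000-series oracles) keep the full suite around ten seconds on one
  CPU while leaving every stage's check statistically meaningful.
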