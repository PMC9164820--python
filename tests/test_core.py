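"""Ratio, threshold, peak detection, the index, and its equivariances."""

import numpy as np
import pytest

from mdrowse.core import (
    AlphaOESeries,
    DrowsinessThreshold,
    alpha_oe_ratio,
    compute_mdrow,
    compute_threshold,
    detect_peaks,
    distribution_stats,
)
from mdrowse.spectral import GFPSeries


def series(values, times=None, condition=None, oe_max=1.0):
    values = np.asarray(values, dtype=float)
    if times is None:
        times = np.arange(values.size, dtype=float)
    if condition is None:
        condition = ["X"] * values.size
    return AlphaOESeries(values, np.asarray(times, float), condition, oe_max)


def gfp(values, condition="OE"):
    values = np.asarray(values, dtype=float)
    return GFPSeries(
        values, np.arange(values.size, dtype=float),
        [condition] * values.size, (9.0, 11.0), ("Pz",),
    )


class TestAlphaOERatio:
    def test_constant_at_baseline_max_gives_one(self):
        out = alpha_oe_ratio(gfp([5.0, 5.0, 5.0], "WUP"), gfp([2.0, 5.0, 3.0]))
        np.testing.assert_array_equal(out.values, [1.0, 1.0, 1.0])
        assert out.oe_max == 5.0

    def test_zero_signal_gives_zero_ratio(self):
        out = alpha_oe_ratio(gfp([0.0, 0.0]), gfp([1.0, 4.0]))
        np.testing.assert_array_equal(out.values, [0.0, 0.0])

    def test_double_the_baseline_max_gives_two(self):
        out = alpha_oe_ratio(gfp([8.0]), gfp([1.0, 4.0]))
        assert out.values[0] == 2.0

    def test_degenerate_baseline_is_an_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            alpha_oe_ratio(gfp([1.0]), gfp([0.0, 0.0]))


class TestThreshold:
    def test_constant_reference_gives_itself(self):
        thr = compute_threshold(series([3.5, 3.5, 3.5]))
        assert thr.value == 3.5
        assert thr.std_ref == 0.0

    def test_two_point_arithmetic(self):
        thr = compute_threshold(series([0.0, 2.0]))
        assert thr.value == 4.0  # mean 1, population std 1

    def test_five_point_arithmetic(self):
        thr = compute_threshold(series([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert thr.value == pytest.approx(3.0 + 3.0 * np.sqrt(2.0), rel=1e-12)

    def test_sample_std_variant(self):
        thr = compute_threshold(series([0.0, 2.0]), ddof=1)
        assert thr.value == pytest.approx(1.0 + 3.0 * np.sqrt(2.0), rel=1e-12)

    def test_too_few_values_is_an_error(self):
        with pytest.raises(ValueError, match=">= 2"):
            compute_threshold(series([1.0]))

    def test_condition_restriction(self):
        s = series([0.0, 2.0, 9.0], condition=["WUP", "WUP", "DROW"])
        assert compute_threshold(s, "WUP").value == 4.0


# -- peak oracle ------------------------------------------------------------


def oracle_peaks(x, t, thr):
    """Enumerate extrema from the definitions, sample by sample.

    A (plateau-aware) local maximum is the first index i of a maximal flat
    segment with a strictly smaller sample on each side; endpoints are never
    maxima. Minima are symmetric; run boundaries act as minima for
    onset/offset.
    """
    n = len(x)

    def flat_end(i):
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        return j

    maxima, minima = [], []
    i = 0
    while i < n:
        j = flat_end(i)
        if i > 0 and j < n - 1:
            if x[i - 1] < x[i] and x[j + 1] < x[i]:
                maxima.append(i)
            if x[i - 1] > x[i] and x[j + 1] > x[i]:
                minima.append(i)
        i = j + 1
    out = []
    mins = sorted(set(minima) | {0, n - 1})
    for m in maxima:
        if x[m] <= thr:
            continue
        onset = max([k for k in mins if k < m], default=0)
        offset = min([k for k in mins if k > m], default=n - 1)
        out.append((t[m], x[m] - thr, t[onset], t[offset]))
    return out


class TestPeaks:
    def test_subthreshold_series_has_no_peaks(self):
        peaks, summ = detect_peaks(series([1, 2, 1, 2, 1]), DrowsinessThreshold(5, "X", 0, 0))
        assert peaks == []
        assert summ["X"].n_peaks == 0
        assert summ["X"].rate_per_min == 0.0
        assert summ["X"].mean_amplitude is None  # never zero-filled

    def test_triangular_bump(self):
        peaks, summ = detect_peaks(
            series([0, 1, 5, 1, 0]), DrowsinessThreshold(4, "X", 0, 0)
        )
        assert len(peaks) == 1
        p = peaks[0]
        assert p.t_max_s == 2.0
        assert p.amplitude == 1.0
        assert p.onset_s == 0.0 and p.offset_s == 4.0
        assert p.duration_s == 4.0
        assert summ["X"].n_peaks == 1

    def test_plateau_first_sample_wins(self):
        peaks, _ = detect_peaks(series([0, 3, 3, 1]), DrowsinessThreshold(2, "X", 0, 0))
        assert len(peaks) == 1
        assert peaks[0].t_max_s == 1.0

    def test_matches_bruteforce_oracle_on_random_walks(self, rng):
        for trial in range(200):
            n = int(rng.integers(3, 60))
            x = np.cumsum(rng.normal(size=n))
            x = np.round(x, 1)  # provoke plateaus and ties
            thr_v = float(rng.normal())
            got, _ = detect_peaks(series(x), DrowsinessThreshold(thr_v, "X", 0, 0))
            want = oracle_peaks(x, np.arange(n, dtype=float), thr_v)
            assert [
                (p.t_max_s, p.amplitude, p.onset_s, p.offset_s) for p in got
            ] == pytest.approx(want), f"trial {trial}"

    def test_gap_splits_runs(self):
        # 5 above threshold right at a gap boundary: boundaries act as minima
        s = series([0, 5, 0, 0, 5, 0], times=[0, 1, 2, 10, 11, 12])
        peaks, _ = detect_peaks(s, DrowsinessThreshold(3, "X", 0, 0))
        assert [(p.t_max_s, p.onset_s, p.offset_s) for p in peaks] == [
            (1.0, 0.0, 2.0),
            (11.0, 10.0, 12.0),
        ]

    def test_rate_uses_clean_minutes_per_condition(self):
        x = [0, 5, 0] * 10
        s = series(x, condition=["DROW"] * 30)
        _, summ = detect_peaks(s, DrowsinessThreshold(3, "X", 0, 0))
        assert summ["DROW"].n_peaks == 10
        assert summ["DROW"].rate_per_min == pytest.approx(10 / 0.5)


# -- the index --------------------------------------------------------------


def oracle_sliding_mean(excess, L):
    """Centered moving average with zero padding, from the definition.

    For even window lengths the extra sample sits on the trailing (past)
    side: the window covers [i - L//2, i + (L-1)//2].
    """
    n = len(excess)
    out = np.zeros(n)
    left = L // 2
    for i in range(n):
        acc = 0.0
        for m in range(L):
            j = i - left + m
            if 0 <= j < n:
                acc += excess[j]
        out[i] = acc / L
    return out


class TestMdrow:
    def test_all_below_threshold_is_zero(self):
        md = compute_mdrow(series([1.0] * 40), DrowsinessThreshold(2, "X", 0, 0))
        assert (md.values == 0).all()
        assert md.nonzero_pct == 0.0

    def test_single_impulse_makes_a_plateau(self):
        x = np.ones(90)
        x[45] = 5.0  # excess 3 over threshold 2
        md = compute_mdrow(series(x), DrowsinessThreshold(2, "X", 0, 0), window_s=30)
        nz = md.values[md.values > 0]
        assert nz.size == 30
        np.testing.assert_allclose(nz, 0.1, rtol=1e-12)
        assert md.nonzero_pct == pytest.approx(100 * 30 / 90)

    def test_matches_sliding_mean_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(35, 150))
            x = rng.normal(1.0, 1.0, size=n)
            thr = DrowsinessThreshold(float(rng.uniform(0.5, 2.5)), "X", 0, 0)
            md = compute_mdrow(series(x), thr, window_s=30)
            want = oracle_sliding_mean(np.maximum(x - thr.value, 0.0), 30)
            np.testing.assert_allclose(md.values, want, atol=1e-12)

    def test_missing_epochs_contribute_zero_excess(self):
        # epochs 3..5 rejected: excess only at t=1 (value 4 -> excess 2)
        s = series([1, 4, 1, 1], times=[0, 1, 2, 6])
        md = compute_mdrow(s, DrowsinessThreshold(2, "X", 0, 0), window_s=4)
        assert md.values.size == 7
        assert md.coverage == pytest.approx(4 / 7)
        want = oracle_sliding_mean([0, 2, 0, 0, 0, 0, 0], 4)
        np.testing.assert_allclose(md.values, want, atol=1e-12)

    def test_positive_iff_excess_within_half_window(self):
        x = np.ones(120)
        x[60] = 9.0
        md = compute_mdrow(series(x), DrowsinessThreshold(2, "X", 0, 0), window_s=30)
        for i, t in enumerate(md.times_s):
            near = abs(t - 60.0) <= 15.0
            assert (md.values[i] > 0) == near or abs(abs(t - 60.0) - 15.0) <= 1.0

    def test_causal_variant_trails(self):
        x = np.ones(90)
        x[45] = 5.0
        md = compute_mdrow(
            series(x), DrowsinessThreshold(2, "X", 0, 0), window_s=30, causal=True
        )
        nz = np.flatnonzero(md.values > 0)
        assert nz[0] == 45 and nz[-1] == 74

    def test_short_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            compute_mdrow(series([1.0] * 40), DrowsinessThreshold(0, "X", 0, 0), window_s=1)


class TestDistributionStats:
    def test_symmetric_three_points(self):
        st = distribution_stats(series([1.0, 2.0, 3.0]), "X")
        assert st.median == 2.0
        assert st.skewness == pytest.approx(0.0, abs=1e-12)
        assert st.n == 3

    def test_mirror_antisymmetry(self, rng):
        x = rng.gamma(2.0, size=50)
        mirrored = 2 * x.mean() - x
        a = distribution_stats(series(x), "X")
        b = distribution_stats(series(mirrored), "X")
        assert a.skewness == pytest.approx(-b.skewness, rel=1e-9)

    def test_adjusted_fisher_pearson_formula(self):
        x = np.array([0.0, 0.0, 0.0, 1.0])
        n = 4
        m = x.mean()
        m2 = ((x - m) ** 2).mean()
        m3 = ((x - m) ** 3).mean()
        g1 = m3 / m2**1.5
        want = g1 * np.sqrt(n * (n - 1)) / (n - 2)  # adjusted (sample) skewness
        st = distribution_stats(series(x), "X")
        assert st.skewness == pytest.approx(want, rel=1e-12)
        assert st.skewness > 0

    def test_too_few_values_is_an_error(self):
        with pytest.raises(ValueError, match=">= 3"):
            distribution_stats(series([1.0, 2.0]), "X")


class TestEquivariances:
    def _chain(self, x, ref, thr_shift=0.0):
        s = series(np.concatenate([ref, x]),
                   condition=["WUP"] * len(ref) + ["DROW"] * len(x))
        thr = compute_threshold(s, "WUP")
        peaks, summ = detect_peaks(s, thr, conditions=["DROW"])
        md = compute_mdrow(s.where_condition("DROW"), thr, window_s=10)
        return thr, peaks, summ["DROW"], md

    def test_shift_equivariance(self, rng):
        ref = rng.normal(1.0, 0.2, size=40)
        x = rng.normal(1.0, 0.8, size=60)
        c = 2.34
        thr0, p0, s0, m0 = self._chain(x, ref)
        thr1, p1, s1, m1 = self._chain(x + c, ref + c)
        assert thr1.value == pytest.approx(thr0.value + c, rel=1e-12)
        assert len(p1) == len(p0)
        for a, b in zip(p0, p1):
            assert b.amplitude == pytest.approx(a.amplitude, rel=1e-9)
            assert b.duration_s == a.duration_s
            assert b.t_max_s == a.t_max_s
        np.testing.assert_allclose(m1.values, m0.values, atol=1e-12)
        assert m1.nonzero_pct == m0.nonzero_pct

    def test_scale_equivariance(self, rng):
        ref = rng.normal(1.0, 0.2, size=40)
        x = rng.normal(1.0, 0.8, size=60)
        c = 3.7
        thr0, p0, s0, m0 = self._chain(x, ref)
        thr1, p1, s1, m1 = self._chain(c * x, c * ref)
        assert thr1.value == pytest.approx(c * thr0.value, rel=1e-12)
        assert len(p1) == len(p0)
        for a, b in zip(p0, p1):
            assert b.amplitude == pytest.approx(c * a.amplitude, rel=1e-9)
            assert b.duration_s == a.duration_s
        np.testing.assert_allclose(m1.values, c * m0.values, rtol=1e-9, atol=1e-12)
        assert m1.nonzero_pct == m0.nonzero_pct
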