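"""Background, noise, smoothing, and threshold peak detection."""

from __future__ import annotations

import numpy as np
import pytest

from difc import (
    AnalysisConfig,
    DegenerateNoiseError,
    PreprocessedChannel,
    detect_peaks,
    estimate_background,
    estimate_noise,
    preprocess_channel,
    smooth,
)
from difc.trace_io import AnalysisError

from conftest import inject_gaussian

RATE = 2000.0


def brute_force_moving_median(x: np.ndarray, w: int) -> np.ndarray:
    """Independent reference: median over a reflect-padded window, per sample."""
    if w % 2 == 0:
        w += 1
    half = w // 2
    padded = np.pad(x, half, mode="reflect")
    return np.array([np.median(padded[i:i + w]) for i in range(x.size)])


def brute_force_detect(x: np.ndarray, noise_sd: float, cfg: AnalysisConfig,
                       rate: float) -> list[tuple[int, int, int]]:
    """Independent sample-by-sample scan: (start, stop, apex) per peak.

    Walks the series building threshold runs, merges close runs, and applies
    the same FWHM floor via direct half-height crossing search.
    """
    thr = cfg.threshold_factor * noise_sd
    runs = []
    in_run = False
    for i, v in enumerate(x):
        if v >= thr and not in_run:
            start, in_run = i, True
        elif v < thr and in_run:
            runs.append((start, i))
            in_run = False
    if in_run:
        runs.append((start, x.size))

    gap = max(1, int(round(cfg.merge_gap_s * rate)))
    merged = []
    for run in runs:
        if merged and run[0] - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)

    out = []
    for start, stop in merged:
        apex = start
        for i in range(start, stop):
            if x[i] > x[apex]:
                apex = i
        half = x[apex] / 2.0
        left = 0.0
        for i in range(apex, -1, -1):
            if x[i] < half:
                left = i + (half - x[i]) / (x[i + 1] - x[i])
                break
        right = float(x.size - 1)
        for i in range(apex, x.size):
            if x[i] < half:
                right = i - 1 + (x[i - 1] - half) / (x[i - 1] - x[i])
                break
        if (right - left) / rate >= cfg.min_peak_width_s:
            out.append((start, stop, apex))
    return out


class TestBackground:
    def test_constant_series_is_its_own_background(self):
        x = np.full(10_000, 5.0)
        np.testing.assert_allclose(estimate_background(x, 0.5, RATE), 5.0)

    def test_linear_ramp_recovered_away_from_edges(self):
        x = np.linspace(0.0, 10.0, 8000)
        bg = estimate_background(x, 0.25, RATE)
        w = int(0.25 * RATE)
        inner = slice(w, -w)
        np.testing.assert_allclose(bg[inner], x[inner], atol=1e-9)

    def test_robust_to_sparse_tall_transient(self):
        x = np.full(12_000, 10.0)
        inject_gaussian(x, RATE, t0=3.0, amp=100.0, fwhm_s=0.01)  # <1% of window
        bg = estimate_background(x, 2.5, RATE)
        np.testing.assert_allclose(bg, 10.0, atol=0.1)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_moving_median(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 600) + np.linspace(0, 3, 600)
        w = int(0.05 * RATE)  # 100 samples: exact path
        got = estimate_background(x, 0.05, RATE, stride=1)
        np.testing.assert_allclose(got, brute_force_moving_median(x, w), atol=1e-12)

    def test_strided_evaluation_tracks_exact_median(self):
        rng = np.random.default_rng(0)
        t = np.arange(60_000) / RATE
        x = 10 + np.sin(2 * np.pi * t / 10) + rng.normal(0, 1, t.size)
        exact = estimate_background(x, 2.5, RATE, stride=1)
        fast = estimate_background(x, 2.5, RATE)
        assert np.max(np.abs(fast - exact)) < 0.1  # ~2% of the 5-sigma threshold

    def test_window_longer_than_trace_raises(self):
        with pytest.raises(AnalysisError, match="longer than the trace"):
            estimate_background(np.ones(100), 1.0, RATE)


class TestNoise:
    def test_alternating_unit_residual_has_unit_sd(self):
        x = np.tile([1.0, -1.0], 500)
        assert estimate_noise(x, "plain_sd") == pytest.approx(1.0)

    def test_constant_residual_has_zero_noise(self):
        assert estimate_noise(np.full(100, 3.3), "plain_sd") == 0.0
        assert estimate_noise(np.full(100, 3.3), "robust") == 0.0

    def test_seeded_gaussian_sd_recovered(self):
        x = np.random.default_rng(42).normal(0.0, 2.0, 120_000)
        assert 1.97 <= estimate_noise(x, "plain_sd") <= 2.03

    def test_robust_estimate_ignores_sparse_peaks(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 50_000)
        x[::1000] += 50.0  # 0.1% contamination
        plain = estimate_noise(x, "plain_sd")
        robust = estimate_noise(x, "robust")
        assert plain > 1.5
        assert robust == pytest.approx(1.0, abs=0.05)

    def test_too_short_series_raises(self):
        with pytest.raises(AnalysisError):
            estimate_noise(np.array([1.0]))


class TestSmooth:
    def test_one_sample_window_is_identity(self, rng):
        x = rng.normal(0, 1, 500)
        np.testing.assert_array_equal(smooth(x, 1.0 / RATE, RATE), x)

    def test_constant_series_unchanged(self):
        x = np.full(300, 7.0)
        np.testing.assert_allclose(smooth(x, 0.005, RATE), 7.0)

    def test_matches_brute_force_windowed_mean(self, rng):
        x = rng.normal(0, 1, 100)
        got = smooth(x, 5.0 / RATE, RATE)  # 5-sample window
        expect = np.array(
            [np.mean(np.pad(x, 2, mode="reflect")[i:i + 5]) for i in range(100)]
        )
        np.testing.assert_allclose(got, expect, atol=1e-12)


def make_channel(residual: np.ndarray, noise_sd: float) -> PreprocessedChannel:
    return PreprocessedChannel(
        residual=residual,
        background=np.zeros_like(residual),
        noise_sd=noise_sd,
        smoothing_applied=False,
    )


class TestDetectPeaks:
    def test_all_zero_residual_yields_no_peaks(self, cfg):
        chan = make_channel(np.zeros(10_000), 0.0)
        assert detect_peaks(chan, cfg, RATE) == []

    def test_zero_noise_with_signal_is_degenerate(self, cfg):
        x = np.zeros(1000)
        x[500] = 1.0
        with pytest.raises(DegenerateNoiseError):
            detect_peaks(make_channel(x, 0.0), cfg, RATE)

    def test_single_transit_recovered(self, cfg):
        rng = np.random.default_rng(11)
        raw = rng.normal(100.0, 1.0, int(10 * RATE))
        inject_gaussian(raw, RATE, t0=5.0, amp=10.0, fwhm_s=0.02)
        chan = preprocess_channel(raw, cfg, RATE)
        peaks = detect_peaks(chan, cfg, RATE)
        assert len(peaks) == 1
        (p,) = peaks
        assert p.apex_time_s == pytest.approx(5.0, abs=0.005)
        assert 8.0 <= p.amplitude <= 12.0  # smoothed apex of a 10-unit transit
        assert p.snr >= 5.0
        assert p.width_s == pytest.approx(0.02, rel=0.3)

    def test_transit_below_five_sigma_rejected(self, cfg):
        # Criterion boundary on a unit-noise channel: a 4x transient is below
        # the five-times threshold; the same transient at 6x is above it.
        x = np.zeros(int(10 * RATE))
        inject_gaussian(x, RATE, t0=5.0, amp=4.0, fwhm_s=0.02)
        assert detect_peaks(make_channel(x, 1.0), cfg, RATE) == []
        x6 = np.zeros(int(10 * RATE))
        inject_gaussian(x6, RATE, t0=5.0, amp=6.0, fwhm_s=0.02)
        assert len(detect_peaks(make_channel(x6, 1.0), cfg, RATE)) == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_scan(self, cfg, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1.0, 20_000)
        for t0 in rng.uniform(0.5, 9.5, 8):
            inject_gaussian(x, RATE, t0=t0, amp=rng.uniform(3, 15), fwhm_s=0.02)
        sd = float(np.std(x))
        peaks = detect_peaks(make_channel(x, sd), cfg, RATE)
        oracle = brute_force_detect(x, sd, cfg, RATE)
        assert len(peaks) == len(oracle)
        for p, (start, stop, apex) in zip(peaks, oracle):
            assert p.apex_time_s == pytest.approx(apex / RATE, abs=1e-9)
            assert p.start_time_s == pytest.approx(start / RATE, abs=1e-9)

    def test_every_peak_satisfies_snr_threshold(self, cfg, rng):
        x = rng.normal(0, 1.0, 50_000)
        for t0 in rng.uniform(1, 24, 20):
            inject_gaussian(x, RATE, t0=t0, amp=rng.uniform(2, 20), fwhm_s=0.02)
        chan = make_channel(x, float(np.std(x)))
        for p in detect_peaks(chan, cfg, RATE):
            assert p.snr >= cfg.threshold_factor
            assert p.start_time_s <= p.apex_time_s <= p.end_time_s
            assert p.width_s > 0

    def test_raising_threshold_never_adds_peaks(self, rng):
        x = rng.normal(0, 1.0, 40_000)
        for t0 in rng.uniform(1, 19, 15):
            inject_gaussian(x, RATE, t0=t0, amp=rng.uniform(3, 12), fwhm_s=0.02)
        chan = make_channel(x, float(np.std(x)))
        counts = []
        for factor in (3.0, 4.0, 5.0, 6.0, 8.0):
            cfg = AnalysisConfig(threshold_factor=factor)
            counts.append(len(detect_peaks(chan, cfg, RATE)))
        assert counts == sorted(counts, reverse=True)

    def test_narrow_electronic_spike_rejected(self, cfg):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1.0, 20_000)
        sd = float(np.std(x))
        x[10_000] = 50.0 * sd  # single-sample spike
        peaks = detect_peaks(make_channel(x, sd), cfg, RATE)
        assert all(abs(p.apex_time_s - 10_000 / RATE) > 0.001 for p in peaks)


class TestPreprocess:
    def test_residual_plus_background_reconstructs_raw(self, cfg, rng):
        raw = rng.normal(50.0, 1.0, 30_000) + np.linspace(0, 5, 30_000)
        chan = preprocess_channel(raw, cfg, RATE)
        np.testing.assert_allclose(chan.residual + chan.background, raw, atol=1e-9)
        assert chan.smoothing_applied

    def test_noise_sd_zero_iff_constant(self, cfg):
        flat = np.full(30_000, 4.0)
        chan = preprocess_channel(flat, cfg, RATE)
        assert chan.noise_sd == 0.0

    def test_smoothing_skipped_for_subsample_window(self, rng):
        cfg = AnalysisConfig(smoothing_window_s=1e-5)  # <1 sample at 2 kHz
        raw = rng.normal(0, 1, 30_000)
        chan = preprocess_channel(raw, cfg, RATE)
        assert not chan.smoothing_applied
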