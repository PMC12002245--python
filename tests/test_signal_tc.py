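"""Unit tests for preprocessing, high-gamma power and the TC statistic."""

import numpy as np
import pytest
from scipy import signal as sps

from neurotc import (
    BAND_SCHEME,
    Recording,
    TcParams,
    band_powers,
    dfa_hurst,
    highgamma_power,
    preprocess,
    subsample_compare,
    surrogate_tc,
    tc_from_acf,
    tc_from_power,
    windowed_acf,
)


def _ar1(rng, n, phi, sd=1.0):
    x = np.empty(n)
    x[0] = rng.standard_normal() * sd
    eps = rng.standard_normal(n) * sd * np.sqrt(1 - phi ** 2)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t]
    return x


class TestPreprocess:
    def test_downsample_length(self, rng):
        T = 512 * 100
        rec = Recording(rng.standard_normal((1, T)), rate=512.0)
        out = preprocess(rec)
        assert out.rate == 256.0
        assert out.n_samples == T // 2

    def test_notch_attenuates_line_noise(self, rng):
        t = np.arange(256 * 60) / 256.0
        x = np.sin(2 * np.pi * 50.0 * t) + 0.01 * rng.standard_normal(t.size)
        raw = Recording(x[None, :], rate=256.0)
        out = preprocess(raw)
        f, p_raw = sps.welch(raw.samples[0], fs=256, nperseg=2048)
        _, p_out = sps.welch(out.samples[0], fs=256, nperseg=2048)
        band = (f >= 49) & (f <= 51)
        atten_db = 10 * np.log10(p_raw[band].sum() / p_out[band].sum())
        assert atten_db >= 20.0

    def test_seizure_mask_padding(self, rng):
        rec = Recording(
            rng.standard_normal((1, 256 * 2000)),
            rate=256.0,
            seizures=[(1000.0, 1060.0)],
        )
        out = preprocess(rec)
        t = np.arange(out.n_samples) / 256.0
        masked = out.time_mask
        assert masked[(t > 400.0) & (t < 1660.0)].all()
        assert not masked[t < 399.0].any()
        assert not masked[t > 1661.0].any()

    def test_bad_channel_flags(self, rng):
        n = 256 * 60
        good = rng.standard_normal(n)
        flat = np.zeros(n)
        t = np.arange(n) / 256.0
        peaky = 0.05 * rng.standard_normal(n) + np.sin(2 * np.pi * 33.0 * t)
        out = preprocess(Recording(np.vstack([good, flat, peaky]), rate=256.0))
        assert not out.bad_channels[0]
        assert out.bad_channels[1]
        assert out.bad_channels[2]

    def test_low_rate_rejected(self, rng):
        with pytest.raises(ValueError):
            preprocess(Recording(rng.standard_normal((1, 1000)), rate=128.0))


class TestHighGammaPower:
    def test_bin_count(self, rng):
        rec = Recording(rng.standard_normal((1, int(256 * 12.5))), rate=256.0)
        ps = highgamma_power(rec)
        assert ps.n_bins == 100

    def test_matches_periodogram_oracle(self, rng):
        x = rng.standard_normal(32 * 50)
        rec = Recording(x[None, :], rate=256.0)
        ps = highgamma_power(rec)
        expected = np.empty(50)
        for b in range(50):
            f, pxx = sps.periodogram(
                x[32 * b : 32 * (b + 1)], fs=256.0, window="hann", nfft=32,
                detrend=False,
            )
            sel = (f >= 56) & (f <= 96)
            expected[b] = np.log10(np.median(pxx[sel]))
        np.testing.assert_allclose(ps.values[0], expected, rtol=1e-10)

    def test_constant_window_marked_invalid(self, rng):
        x = rng.standard_normal(3200)
        x[0:32] = 5.0  # one flat bin
        ps = highgamma_power(Recording(x[None, :], rate=256.0))
        assert not ps.valid[0, 0]
        assert ps.valid[0, 1:].all()

    def test_masked_time_invalidates_bins(self, rng):
        x = rng.standard_normal(3200)
        mask = np.zeros(3200, dtype=bool)
        mask[40:50] = True  # inside bin 1
        rec = Recording(x[None, :], rate=256.0, time_mask=mask)
        ps = highgamma_power(rec)
        assert not ps.valid[0, 1]
        assert ps.valid[0, 0] and ps.valid[0, 2:].all()


class TestWindowedAcf:
    def test_window_count_300s(self, rng):
        vals = rng.standard_normal(300 * 8)
        acfs = windowed_acf(vals)
        assert acfs.shape == (7, 480)

    def test_acfs_bounded(self, rng):
        acfs = windowed_acf(_ar1(rng, 2400, 0.9))
        assert np.all(acfs <= 1.0 + 1e-12) and np.all(acfs >= -1.0 - 1e-12)

    def test_ar1_matches_full_series_oracle(self, rng):
        phi = 0.8
        vals = _ar1(rng, 960 * 8, phi)
        acfs = windowed_acf(vals)
        mean_acf = acfs.mean(axis=0)
        for k in (1, 2, 4, 8):
            assert mean_acf[k - 1] == pytest.approx(phi ** k, abs=0.08)

    def test_invalid_bins_skip_windows(self, rng):
        vals = rng.standard_normal(960 * 2)
        valid = np.ones(vals.size, dtype=bool)
        valid[100] = False  # kills windows covering bin 100
        full = windowed_acf(vals)
        masked = windowed_acf(vals, valid)
        assert masked.shape[0] < full.shape[0]

    def test_constant_series_gives_empty_set(self):
        assert windowed_acf(np.ones(2000)).shape[0] == 0


class TestTcRule:
    def test_hand_example(self):
        # ACF(1)=0.8, baseline 0, first drop below 0.4 at lag 5 -> tc = 0.5 s
        acf = np.zeros(480)
        acf[:5] = [0.8, 0.7, 0.6, 0.5, 0.3]
        tv = tc_from_acf(acf)
        assert tv.tc == pytest.approx(0.5)
        assert not tv.capped

    def test_slow_decay_crosses_inside_baseline_band(self):
        # the median baseline guarantees a crossing at or before the 40-60 s
        # band: at least half of those lags lie at or below the median, which
        # sits strictly under the threshold whenever ACF(1) > baseline
        # linear decay 0.95 -> 0.5: baseline = value at the middle 40-60 s lag
        # (index 399) = 0.5752, threshold = 0.7626, first crossing at lag 201
        # -> tc = 200 bins = 25 s
        acf = np.linspace(0.95, 0.5, 480)
        tv = tc_from_acf(acf)
        assert tv.tc == pytest.approx(25.0)
        assert not tv.capped

    def test_degenerate_first_lag_pins_floor(self):
        acf = np.zeros(480)
        acf[320:] = 0.5  # baseline above ACF(1)
        tv = tc_from_acf(acf)
        assert tv.tc == 0.125 and tv.degenerate

    def test_window_order_irrelevant(self, rng):
        acfs = windowed_acf(_ar1(rng, 960 * 6, 0.9))
        shuffled = acfs[rng.permutation(acfs.shape[0])]
        assert tc_from_acf(acfs).tc == tc_from_acf(shuffled).tc

    def test_amplitude_affine_invariance(self, rng):
        x = rng.standard_normal(256 * 400)
        env = np.repeat(np.exp(_ar1(rng, 3200, 0.9, 0.4)), 32)
        sig = x * env
        rec_a = Recording(sig[None, :], rate=256.0)
        rec_b = Recording((5.0 * sig + 2.0)[None, :], rate=256.0)
        tc_a = tc_from_power(highgamma_power(rec_a).values[0])
        tc_b = tc_from_power(highgamma_power(rec_b).values[0])
        assert tc_a.tc == tc_b.tc


class TestSurrogates:
    def test_permutation_preserves_values(self, rng):
        vals = _ar1(rng, 960 * 3, 0.9)
        surr = surrogate_tc(vals, n=2, seed=0)
        assert len(surr) == 2  # pipeline ran on both permutations

    def test_shuffling_destroys_correlations(self, rng):
        # correlated series with tc ~ 1.5 s; its surrogates sit at the floor
        phi = np.exp(-0.125 / 2.0)
        vals = _ar1(rng, 1600 * 8, phi)
        assert tc_from_power(vals).tc > 1.0
        surr = [s.tc for s in surrogate_tc(vals, n=31, seed=1)]
        assert np.median(surr) == 0.125
        assert np.mean(np.asarray(surr) == 0.125) >= 0.7

    def test_zero_surrogates_rejected(self, rng):
        with pytest.raises(ValueError):
            surrogate_tc(rng.standard_normal(2000), n=0)


class TestSubsampleCompare:
    def test_equal_sizes_deterministic(self, rng):
        a = windowed_acf(_ar1(rng, 960 * 4, 0.9))
        ta, tb = subsample_compare(a, a, seed=0)
        assert ta == tb

    def test_majority_subsampled(self, rng):
        a = windowed_acf(_ar1(rng, 960 * 4, 0.9))
        b = windowed_acf(_ar1(rng, 960 * 12, 0.9))
        assert b.shape[0] > a.shape[0]
        ta, tb = subsample_compare(a, b, n_rep=20, seed=0)
        assert ta > 0 and tb > 0

    def test_identical_sets_symmetric(self, rng):
        a = windowed_acf(_ar1(rng, 960 * 8, 0.85))
        ta, tb = subsample_compare(a, a.copy(), n_rep=10, seed=3)
        assert ta == pytest.approx(tb)

    def test_empty_set_rejected(self, rng):
        a = windowed_acf(_ar1(rng, 960 * 4, 0.9))
        with pytest.raises(ValueError):
            subsample_compare(a, np.empty((0, 480)))


class TestBandPowers:
    def test_alpha_sine_dominates(self):
        t = np.arange(256 * 240) / 256.0
        x = np.sin(2 * np.pi * 10.0 * t) + 0.01 * np.random.default_rng(0).standard_normal(t.size)
        bp = band_powers(Recording(x[None, :], rate=256.0))
        row = bp.iloc[0]
        others = [row[b] for b in BAND_SCHEME if b != "alpha"]
        assert row["alpha"] > 50 * max(others)

    def test_segment_count(self, rng):
        bp = band_powers(Recording(rng.standard_normal((1, 256 * 600)), rate=256.0))
        assert len(bp) == 5

    def test_white_noise_bands_ordered_by_bandwidth(self, rng):
        # integrated power under a flat spectrum scales with bandwidth, and
        # per-band values match a direct Welch-integral oracle
        x = rng.standard_normal(256 * 240)
        bp = band_powers(Recording(x[None, :], rate=256.0))
        row = bp.iloc[0]
        widths = {b: hi - lo for b, (lo, hi) in BAND_SCHEME.items()}
        order_by_power = sorted(BAND_SCHEME, key=lambda b: row[b])
        order_by_width = sorted(BAND_SCHEME, key=lambda b: widths[b])
        assert order_by_power == order_by_width
        f, pxx = sps.welch(x[: 256 * 120], fs=256.0, nperseg=512, window="hann")
        lo, hi = BAND_SCHEME["beta"]
        sel = (f >= lo) & (f <= hi)
        assert row["beta"] == pytest.approx(pxx[sel].sum() * (f[1] - f[0]))


class TestDfa:
    def test_white_noise_hurst_half(self, rng):
        assert dfa_hurst(rng.standard_normal(8192)) == pytest.approx(0.5, abs=0.05)

    def test_integrated_noise(self, rng):
        h = dfa_hurst(np.cumsum(rng.standard_normal(8192)))
        assert h == pytest.approx(1.5, abs=0.1)

    def test_monotone_in_ar_coefficient(self, rng):
        hs = [dfa_hurst(_ar1(rng, 8192, phi)) for phi in (0.5, 0.7, 0.9)]
        assert hs[0] < hs[1] < hs[2]

    def test_short_series_rejected(self, rng):
        with pytest.raises(ValueError):
            dfa_hurst(rng.standard_normal(100))
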