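"""Preprocessing of iEEG-like recordings and the temporal-correlation statistic.

The temporal correlation (TC) quantifies how long fluctuations of local
population firing persist.  It is computed from the high-gamma (56-96 Hz)
power envelope, the band whose amplitude most closely tracks local spike
rates: median high-gamma power in non-overlapping 125 ms windows, log10
transformed, autocorrelated in sliding 120 s windows (90 s overlap), the
window ACFs aggregated by an element-wise median, and the TC read off as the
half-width of the aggregated ACF measured from its lag-1 peak down to halfway
between the lag-1 value and a long-lag baseline (median ACF over 40-60 s).
Lag 0 is excluded (it is 1 by definition, independent of noise level), so the
smallest attainable TC is one bin, 0.125 s; ACFs never crossing the threshold
are capped at 60 s and flagged.

Shuffling the power bins in time destroys the correlations while preserving
the power distribution; TCs of shuffled series therefore serve as surrogate
controls pinned at the 0.125 s floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "Recording",
    "TcParams",
    "PowerSeries",
    "TcValue",
    "BAND_SCHEME",
    "VIGILANCE_BANDS",
    "preprocess",
    "highgamma_power",
    "windowed_acf",
    "tc_from_acf",
    "tc_from_power",
    "surrogate_tc",
    "subsample_compare",
    "band_powers",
    "dfa_hurst",
]

TARGET_RATE = 256.0

#: Canonical frequency bands (Hz) for the control band-power features.
BAND_SCHEME: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 45.0),
    "high_gamma": (55.0, 95.0),
}

#: Bands entering the vigilance index (theta+delta)/(alpha+beta_high+spindle).
#: spindle and beta_high edges are configurable interpretations (the source
#: band definitions are not printed); defaults: spindle 11-16, beta_high 20-30.
VIGILANCE_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "spindle": (11.0, 16.0),
    "beta_high": (20.0, 30.0),
}


@dataclass
class Recording:
    """Multichannel signal with annotations.

    ``samples`` is channels x time; ``seizures`` are (start_s, end_s)
    intervals; ``time_mask`` marks samples excluded from analysis;
    ``bad_channels`` flags channels rejected during preprocessing.
    """

    samples: np.ndarray
    rate: float
    channel_labels: list[str] = field(default_factory=list)
    seizures: list[tuple[float, float]] = field(default_factory=list)
    time_mask: np.ndarray | None = None
    bad_channels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.n_channels)]
        dur = self.duration_s
        for a, b in self.seizures:
            if not (0 <= a <= b <= dur):
                raise ValueError(f"seizure interval ({a}, {b}) outside recording span")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate


@dataclass(frozen=True)
class TcParams:
    """Tuning constants of the TC pipeline (all in seconds / Hz)."""

    power_window: float = 0.125
    hg_band: tuple[float, float] = (56.0, 96.0)
    acf_window: float = 120.0
    acf_overlap: float = 90.0
    max_lag: float = 60.0
    baseline_band: tuple[float, float] = (40.0, 60.0)

    def __post_init__(self) -> None:
        if self.acf_overlap >= self.acf_window:
            raise ValueError("acf_overlap must be smaller than acf_window")
        lo, hi = self.baseline_band
        if not (0.0 < lo < hi <= self.max_lag):
            raise ValueError("baseline_band must lie within (0, max_lag]")

    @property
    def bin_rate(self) -> float:
        return 1.0 / self.power_window

    @property
    def window_bins(self) -> int:
        return round(self.acf_window * self.bin_rate)

    @property
    def hop_bins(self) -> int:
        return round((self.acf_window - self.acf_overlap) * self.bin_rate)

    @property
    def max_lag_bins(self) -> int:
        return round(self.max_lag * self.bin_rate)


@dataclass
class PowerSeries:
    """Per-channel log10 high-gamma power at 8 bins per second."""

    values: np.ndarray  # (n_channels, n_bins)
    valid: np.ndarray  # (n_channels, n_bins) bool
    bin_rate: float = 8.0
    channel_labels: list[str] = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


@dataclass
class TcValue:
    tc: float  # seconds
    n_windows_aggregated: int
    capped: bool = False
    degenerate: bool = False


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def _notch(x: np.ndarray, rate: float, freq: float, q: float = 30.0) -> np.ndarray:
    b, a = sps.iirnotch(freq, q, fs=rate)
    return sps.filtfilt(b, a, x, axis=-1)


def preprocess(
    rec: Recording,
    seizure_pad_s: float = 600.0,
    reject_iqr_factor: float = 6.0,
) -> Recording:
    """Standardize a recording: notch, resample to 256 Hz, high-pass, reject
    bad channels, mask seizure intervals.

    Line noise is notched at 50 and 100 Hz; the signal is brought to the
    common 256 Hz rate with a polyphase antialiasing resampler (whose lowpass
    realizes the 128 Hz upper band edge); a 0.1 Hz Butterworth high-pass
    removes slow drifts.  Channels are flagged bad if constant, or if any
    Welch spectral value exceeds Q3 + ``reject_iqr_factor`` * IQR of that
    channel's own spectrum (abnormal frequency peak).  Seizure intervals are
    expanded by ``seizure_pad_s`` on both sides and masked.
    """
    if rec.rate < TARGET_RATE:
        raise ValueError(
            f"rate {rec.rate} Hz below the common target of {TARGET_RATE} Hz"
        )
    x = rec.samples
    n_in = x.shape[1]
    for f in (50.0, 100.0):
        x = _notch(x, rec.rate, f)
    if rec.rate != TARGET_RATE:
        from fractions import Fraction

        frac = Fraction(TARGET_RATE / rec.rate).limit_denominator(1000)
        x = sps.resample_poly(x, frac.numerator, frac.denominator, axis=-1)
        x = x[:, : int(n_in * TARGET_RATE / rec.rate)]
    sos = sps.butter(4, 0.1, btype="highpass", fs=TARGET_RATE, output="sos")
    x = sps.sosfiltfilt(sos, x, axis=-1)

    n_ch, n_samp = x.shape
    bad = np.zeros(n_ch, dtype=bool)
    for c in range(n_ch):
        if np.ptp(x[c]) == 0.0:
            bad[c] = True
            continue
        nper = min(4096, n_samp)
        _, pxx = sps.welch(x[c], fs=TARGET_RATE, nperseg=nper, average="median")
        q1, q3 = np.percentile(pxx, [25, 75])
        if np.any(pxx > q3 + reject_iqr_factor * (q3 - q1)):
            bad[c] = True

    mask = np.zeros(n_samp, dtype=bool)
    for a, b in rec.seizures:
        i0 = max(0, int((a - seizure_pad_s) * TARGET_RATE))
        i1 = min(n_samp, int(np.ceil((b + seizure_pad_s) * TARGET_RATE)))
        mask[i0:i1] = True

    return Recording(
        samples=x,
        rate=TARGET_RATE,
        channel_labels=list(rec.channel_labels),
        seizures=list(rec.seizures),
        time_mask=mask,
        bad_channels=bad,
    )


# ---------------------------------------------------------------------------
# high-gamma power extraction
# ---------------------------------------------------------------------------

def highgamma_power(rec: Recording, params: TcParams = TcParams()) -> PowerSeries:
    """Median log10 high-gamma power in non-overlapping 125 ms windows.

    Each 32-sample window is Hann-tapered and periodogram-transformed (8 Hz
    frequency resolution — a single Welch segment); power is the median over
    frequency bins inside the 56-96 Hz band, then log10.  Bins overlapping
    masked time, or with zero variance, are marked invalid rather than
    raising.
    """
    if rec.rate != TARGET_RATE:
        raise ValueError("highgamma_power expects a preprocessed 256 Hz recording")
    win_len = round(params.power_window * rec.rate)  # 32 samples
    n_bins = rec.n_samples // win_len
    if n_bins == 0:
        raise ValueError("recording shorter than one power window")
    window = sps.get_window("hann", win_len)
    scale = 1.0 / (rec.rate * (window ** 2).sum())
    freqs = np.fft.rfftfreq(win_len, d=1.0 / rec.rate)
    band = (freqs >= params.hg_band[0]) & (freqs <= params.hg_band[1])

    x = rec.samples[:, : n_bins * win_len].reshape(rec.n_channels, n_bins, win_len)
    variance = x.var(axis=-1)
    spec = np.abs(np.fft.rfft(x * window, axis=-1)) ** 2 * scale
    # one-sided periodogram: double everything except DC and Nyquist
    spec[..., 1:-1] *= 2.0
    med = np.median(spec[..., band], axis=-1)

    valid = variance > 0.0
    if rec.time_mask is not None:
        bin_masked = (
            rec.time_mask[: n_bins * win_len].reshape(n_bins, win_len).any(axis=-1)
        )
        valid &= ~bin_masked[None, :]
    values = np.full_like(med, np.nan)
    ok = valid & (med > 0.0)
    values[ok] = np.log10(med[ok])
    valid = ok
    return PowerSeries(
        values=values,
        valid=valid,
        bin_rate=params.bin_rate,
        channel_labels=list(rec.channel_labels),
    )


# ---------------------------------------------------------------------------
# windowed autocorrelation and the TC rule
# ---------------------------------------------------------------------------

def _acf_1d(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased (divide-by-n) sample autocorrelation, lags 1..max_lag."""
    n = x.size
    x = x - x.mean()
    c0 = float(np.dot(x, x)) / n
    if c0 == 0.0:
        raise ValueError("constant series: autocorrelation undefined")
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[1 : max_lag + 1] / n
    return acov / c0


def windowed_acf(
    values: np.ndarray,
    valid: np.ndarray | None = None,
    params: TcParams = TcParams(),
) -> np.ndarray:
    """Sample ACFs of a single-channel bin series in sliding 120 s windows.

    Windows start every ``acf_window - acf_overlap`` seconds (30 s); any
    window containing an invalid bin is skipped.  Returns an array of shape
    (n_windows, max_lag_bins); empty if no complete window exists.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if valid is None:
        valid = np.isfinite(values)
    else:
        valid = np.asarray(valid, dtype=bool).ravel() & np.isfinite(values)
    wlen, hop, nlag = params.window_bins, params.hop_bins, params.max_lag_bins
    out = []
    for start in range(0, values.size - wlen + 1, hop):
        seg_valid = valid[start : start + wlen]
        if not seg_valid.all():
            continue
        seg = values[start : start + wlen]
        try:
            out.append(_acf_1d(seg, nlag))
        except ValueError:
            continue  # constant window
    if not out:
        return np.empty((0, nlag))
    return np.vstack(out)


def tc_from_acf(acfs: np.ndarray, params: TcParams = TcParams()) -> TcValue:
    """Half-width TC from a set of window ACFs.

    The ACFs are aggregated by an element-wise median; the baseline is the
    median of the aggregated ACF over the 40-60 s lag band; the threshold is
    baseline + (ACF(lag 1) - baseline)/2; the TC is the width from the lag-1
    peak to the first lag (>= 2) falling below the threshold, in seconds.  No
    crossing caps the TC at ``max_lag``; a lag-1 value at or below the
    baseline is degenerate and pinned to the one-bin floor.
    """
    acfs = np.atleast_2d(acfs)
    if acfs.shape[0] < 1 or acfs.size == 0:
        raise ValueError("need at least one window ACF")
    agg = np.median(acfs, axis=0)
    bin_s = params.power_window
    lags_s = np.arange(1, agg.size + 1) * bin_s
    lo, hi = params.baseline_band
    baseline = float(np.median(agg[(lags_s >= lo) & (lags_s <= hi)]))
    first = float(agg[0])
    if first <= baseline:
        return TcValue(tc=bin_s, n_windows_aggregated=acfs.shape[0], degenerate=True)
    threshold = baseline + (first - baseline) / 2.0
    below = np.nonzero(agg[1:] < threshold)[0]
    if below.size:
        lag = int(below[0]) + 2
        return TcValue(tc=(lag - 1) * bin_s, n_windows_aggregated=acfs.shape[0])
    return TcValue(tc=params.max_lag, n_windows_aggregated=acfs.shape[0], capped=True)


def tc_from_power(
    values: np.ndarray,
    valid: np.ndarray | None = None,
    params: TcParams = TcParams(),
) -> TcValue:
    """Convenience: windowed ACFs then the TC rule, for one channel."""
    acfs = windowed_acf(values, valid, params)
    if acfs.shape[0] == 0:
        raise ValueError("no complete ACF window in series")
    return tc_from_acf(acfs, params)


def surrogate_tc(
    values: np.ndarray,
    valid: np.ndarray | None = None,
    params: TcParams = TcParams(),
    n: int = 100,
    seed: int | None = None,
) -> list[TcValue]:
    """TC distribution over time-shuffled copies of a bin series.

    Shuffling permutes the values among the valid bin positions, preserving
    the power distribution while destroying temporal structure; each
    surrogate runs through the full windowed-ACF TC pipeline.
    """
    if n < 1:
        raise ValueError("need at least one surrogate")
    values = np.asarray(values, dtype=np.float64).ravel()
    if valid is None:
        valid = np.isfinite(values)
    else:
        valid = np.asarray(valid, dtype=bool).ravel()
    rng = np.random.default_rng(seed)
    idx = np.nonzero(valid)[0]
    out = []
    for _ in range(n):
        shuffled = values.copy()
        shuffled[idx] = values[idx][rng.permutation(idx.size)]
        out.append(tc_from_power(shuffled, valid, params))
    return out


def subsample_compare(
    windows_a: np.ndarray,
    windows_b: np.ndarray,
    n_rep: int = 100,
    seed: int | None = None,
    params: TcParams = TcParams(),
) -> tuple[float, float]:
    """Size-matched TC comparison between two ACF-window sets.

    The majority set is repeatedly subsampled without replacement to the
    minority size; TCs are computed per repetition and averaged.  Equal sizes
    short-circuit to a single deterministic computation.
    """
    windows_a, windows_b = np.atleast_2d(windows_a), np.atleast_2d(windows_b)
    na, nb = windows_a.shape[0], windows_b.shape[0]
    if na == 0 or nb == 0:
        raise ValueError("both window sets must be non-empty")
    if na == nb:
        return tc_from_acf(windows_a, params).tc, tc_from_acf(windows_b, params).tc
    rng = np.random.default_rng(seed)
    m = min(na, nb)
    tcs_a, tcs_b = [], []
    for _ in range(n_rep):
        sub_a = windows_a if na == m else windows_a[rng.choice(na, m, replace=False)]
        sub_b = windows_b if nb == m else windows_b[rng.choice(nb, m, replace=False)]
        tcs_a.append(tc_from_acf(sub_a, params).tc)
        tcs_b.append(tc_from_acf(sub_b, params).tc)
    return float(np.mean(tcs_a)), float(np.mean(tcs_b))


# ---------------------------------------------------------------------------
# band powers and DFA
# ---------------------------------------------------------------------------

def band_powers(
    rec: Recording,
    scheme: dict[str, tuple[float, float]] | None = None,
    segment_s: float = 120.0,
    welch_nperseg: int = 512,
) -> pd.DataFrame:
    """Integrated Welch band power per non-overlapping segment per channel.

    Returns a tidy frame with columns (channel, segment_start_s, <band>...).
    Segments overlapping masked time are omitted.
    """
    scheme = scheme or BAND_SCHEME
    seg_len = round(segment_s * rec.rate)
    n_seg = rec.n_samples // seg_len
    freqs = None
    rows = []
    for s in range(n_seg):
        sl = slice(s * seg_len, (s + 1) * seg_len)
        if rec.time_mask is not None and rec.time_mask[sl].any():
            continue
        for c in range(rec.n_channels):
            if rec.bad_channels is not None and rec.bad_channels[c]:
                continue
            f, pxx = sps.welch(
                rec.samples[c, sl],
                fs=rec.rate,
                nperseg=min(welch_nperseg, seg_len),
                window="hann",
            )
            row = {
                "channel": rec.channel_labels[c],
                "segment_start_s": s * segment_s,
            }
            df = f[1] - f[0]
            for name, (lo, hi) in scheme.items():
                sel = (f >= lo) & (f <= hi)
                row[name] = float(pxx[sel].sum() * df)  # integrated band power
            rows.append(row)
    cols = ["channel", "segment_start_s", *scheme.keys()]
    return pd.DataFrame(rows, columns=cols)


def dfa_hurst(
    values: np.ndarray,
    min_scale: int = 4,
    n_scales: int = 12,
) -> float:
    """Hurst exponent via first-order detrended fluctuation analysis.

    The series is integrated (cumulative sum of deviations from the mean),
    split into non-overlapping windows of each scale, linearly detrended per
    window, and the log-log slope of the RMS fluctuation against the scale is
    returned.  White noise gives H ~ 0.5, integrated white noise H ~ 1.5.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    x = x[np.isfinite(x)]
    if x.size < 2 ** 8:
        raise ValueError("series too short for DFA (need >= 256 points)")
    y = np.cumsum(x - x.mean())
    max_scale = x.size // 4
    scales = np.unique(
        np.round(
            np.exp(np.linspace(np.log(min_scale), np.log(max_scale), n_scales))
        ).astype(int)
    )
    flucts = []
    t_full = np.arange(x.size, dtype=np.float64)
    for s in scales:
        n_win = y.size // s
        seg = y[: n_win * s].reshape(n_win, s)
        t = t_full[:s]
        # per-window linear detrend via least squares
        tm = t - t.mean()
        denom = float(np.dot(tm, tm))
        slope = seg @ tm / denom
        intercept = seg.mean(axis=1)
        resid = seg - intercept[:, None] - slope[:, None] * tm[None, :]
        flucts.append(np.sqrt((resid ** 2).mean()))
    coef = np.polyfit(np.log(scales), np.log(flucts), 1)
    return float(coef[0])
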