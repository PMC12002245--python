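"""Minimal European Data Format (EDF) 16-bit writer and reader.

Only the plain EDF profile needed here is supported: continuous recording,
one fixed sampling rate for all channels, 1-second data records.  Reading
prefers MNE's native EDF reader when available (the independent
cross-check used in tests) and falls back to a built-in parser.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np

__all__ = ["write_edf", "read_edf"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(
    path: str | Path,
    samples: np.ndarray,
    rate: float,
    channel_labels: list[str] | None = None,
) -> None:
    """Write a channels-x-time float array as 16-bit EDF.

    The sampling rate must be a whole number (samples per 1 s record).
    Physical min/max are taken per channel from the data, so the round-trip
    error is bounded by the 16-bit quantization step.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=np.float64))
    n_ch, n_samp = samples.shape
    if rate <= 0 or rate != int(rate):
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(rate)  # samples per 1-second record
    n_rec = n_samp // spr
    if n_rec == 0:
        raise ValueError("recording shorter than one 1-second data record")
    labels = channel_labels or [f"ch{i}" for i in range(n_ch)]

    phys_min = samples.min(axis=1)
    phys_max = samples.max(axis=1)
    # avoid a zero physical span for constant channels
    flat = phys_max <= phys_min
    phys_max = np.where(flat, phys_min + 1.0, phys_max)

    now = _dt.datetime(2000, 1, 1)
    header_bytes = 256 + 256 * n_ch
    head = b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),
            _field("Startdate X X X X", 80),
            _field(now.strftime("%d.%m.%y"), 8),
            _field(now.strftime("%H.%M.%S"), 8),
            _field(str(header_bytes), 8),
            _field("", 44),
            _field(str(n_rec), 8),
            _field("1", 8),
            _field(str(n_ch), 4),
        ]
    )

    def sig_fields(fmt, width):
        return b"".join(_field(fmt(i), width) for i in range(n_ch))

    head += sig_fields(lambda i: labels[i], 16)
    head += sig_fields(lambda i: "", 80)
    head += sig_fields(lambda i: "uV", 8)
    head += sig_fields(lambda i: f"{phys_min[i]:.8g}"[:8], 8)
    head += sig_fields(lambda i: f"{phys_max[i]:.8g}"[:8], 8)
    head += sig_fields(lambda i: str(_DIG_MIN), 8)
    head += sig_fields(lambda i: str(_DIG_MAX), 8)
    head += sig_fields(lambda i: "", 80)
    head += sig_fields(lambda i: str(spr), 8)
    head += sig_fields(lambda i: "", 32)

    # re-read the truncated 8-char physical bounds so scaling matches readers
    pmin = np.array([float(f"{v:.8g}"[:8]) for v in phys_min])
    pmax = np.array([float(f"{v:.8g}"[:8]) for v in phys_max])
    gain = (pmax - pmin) / (_DIG_MAX - _DIG_MIN)
    digital = np.round((samples - pmin[:, None]) / gain[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(head)
        for r in range(n_rec):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())


def read_edf(path: str | Path) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file, returning (samples, rate, channel_labels).

    Uses MNE when importable, otherwise a minimal built-in parser.
    """
    try:
        import mne

        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        # MNE converts presumed-uV data to volts; undo for physical units
        return raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names)
    except ImportError:
        pass
    with open(path, "rb") as fh:
        head = fh.read(256)
        n_rec = int(head[236:244].decode().strip())
        rec_dur = float(head[244:252].decode().strip())
        n_ch = int(head[252:256].decode().strip())
        sig = fh.read(256 * n_ch)

        def col(off, width):
            base = off * n_ch
            return [
                sig[base + i * width : base + (i + 1) * width].decode().strip()
                for i in range(n_ch)
            ]

        labels = col(0, 16)
        pmin = np.array([float(v) for v in col(16 + 80 + 8, 8)])
        pmax = np.array([float(v) for v in col(16 + 80 + 8 + 8, 8)])
        dmin = np.array([float(v) for v in col(16 + 80 + 8 + 16, 8)])
        dmax = np.array([float(v) for v in col(16 + 80 + 8 + 24, 8)])
        spr = np.array([int(v) for v in col(16 + 80 + 8 + 32 + 80, 8)])
        data = np.frombuffer(fh.read(), dtype="<i2")
    per_rec = int(spr.sum())
    data = data[: n_rec * per_rec].reshape(n_rec, per_rec)
    out = np.empty((n_ch, n_rec * spr[0]))
    offs = np.concatenate([[0], np.cumsum(spr)])
    gain = (pmax - pmin) / (dmax - dmin)
    for c in range(n_ch):
        chunk = data[:, offs[c] : offs[c + 1]].reshape(-1).astype(np.float64)
        out[c] = (chunk - dmin[c]) * gain[c] + pmin[c]
    rate = spr[0] / rec_dur
    return out, float(rate), labels
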