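"""Synthetic iEEG-like signals and cohort metadata with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage can be exercised and validated without patient data:

* signals: a 55-100 Hz Gaussian carrier amplitude-modulated by an
  exponentiated AR(1) envelope whose lag-1 coefficient at the 8 Hz power-bin
  rate is ``exp(-0.125 / envelope_tau)`` — so ``envelope_tau`` is the
  ground-truth high-gamma correlation time the TC estimator should recover —
  on top of a 1/f background, delta-band activity boosted during designated
  slow-wave epochs, stereotyped spike-wave IED transients, and optional
  50/100 Hz line sinusoids;
* cohorts: per-subject latent correlation times, multiday ASM schedules that
  shorten the correlation time on high-dose days, IED and slow-wave
  statistics, and cognitive test scores whose domain-impairment probability
  decreases with the subject's correlation time (logistic link in log tau).

Ground truth for every latent quantity is always emitted alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.special import expit

from .signal_tc import Recording

__all__ = ["SignalSpec", "CohortSpec", "CohortData", "gen_signal", "gen_cohort"]


@dataclass(frozen=True)
class SignalSpec:
    """Recipe for one multichannel synthetic recording."""

    duration_s: float = 600.0
    rate: float = 256.0
    n_channels: int = 1
    envelope_tau_s: float = 0.5
    envelope_log_sd: float = 0.5
    hg_amp: float = 1.0
    background_amp: float = 0.3
    delta_amp: float = 0.5
    sws_epochs: tuple[tuple[float, float], ...] = ()
    sws_boost_db: float = 10.0
    ied_rate_per_min: float = 0.0
    ied_amp: float = 8.0
    line_noise_amp: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.envelope_tau_s <= 0:
            raise ValueError("envelope_tau_s must be positive")
        for a, b in self.sws_epochs:
            if not (0 <= a < b <= self.duration_s):
                raise ValueError(f"SWS epoch ({a}, {b}) outside signal duration")


def _bandlimited_noise(rng, n, rate, lo, hi) -> np.ndarray:
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _pink_noise(rng, n) -> np.ndarray:
    """1/f-power background via spectral shaping."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    x = np.fft.irfft(spec / np.sqrt(f), n)
    return x / x.std()


def _ied_template(rate: float, amp: float) -> np.ndarray:
    """Stereotyped spike-wave: 70 ms sharp transient + 300 ms slow half-wave."""
    n_spike = round(0.070 * rate)
    n_wave = round(0.300 * rate)
    spike = amp * np.sin(np.linspace(0, np.pi, n_spike))
    wave = -0.35 * amp * np.sin(np.linspace(0, np.pi, n_wave))
    return np.concatenate([spike, wave])


def gen_signal(spec: SignalSpec) -> tuple[Recording, pd.DataFrame]:
    """Generate a recording per the spec; returns (Recording, truth table).

    The truth table has one row per channel with the latent envelope
    correlation time, the injected IED times (as a list) and the SWS epochs.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.rate))
    bins_per_s = 8
    bin_len = int(spec.rate // bins_per_s)  # 32 samples at 256 Hz
    n_bins = math.ceil(n / bin_len)
    phi = math.exp(-(1.0 / bins_per_s) / spec.envelope_tau_s)

    t = np.arange(n) / spec.rate
    sws_gain = np.ones(n)
    for a, b in spec.sws_epochs:
        sws_gain[(t >= a) & (t < b)] = 10.0 ** (spec.sws_boost_db / 20.0)

    data = np.empty((spec.n_channels, n))
    truth_rows = []
    for c in range(spec.n_channels):
        # AR(1) log-envelope at the bin rate, stationary sd = envelope_log_sd
        eps = rng.standard_normal(n_bins) * spec.envelope_log_sd * math.sqrt(
            1.0 - phi ** 2
        )
        logenv = np.empty(n_bins)
        logenv[0] = rng.standard_normal() * spec.envelope_log_sd
        for k in range(1, n_bins):
            logenv[k] = phi * logenv[k - 1] + eps[k]
        envelope = np.repeat(np.exp(logenv), bin_len)[:n]

        carrier = _bandlimited_noise(rng, n, spec.rate, 55.0, 100.0)
        x = spec.hg_amp * carrier * envelope
        x += spec.background_amp * _pink_noise(rng, n)
        x += spec.delta_amp * sws_gain * _bandlimited_noise(
            rng, n, spec.rate, 0.5, 4.0
        )
        if spec.line_noise_amp > 0:
            phase = rng.uniform(0, 2 * np.pi, size=2)
            x += spec.line_noise_amp * np.sin(2 * np.pi * 50.0 * t + phase[0])
            x += 0.5 * spec.line_noise_amp * np.sin(2 * np.pi * 100.0 * t + phase[1])

        ied_times: list[float] = []
        if spec.ied_rate_per_min > 0:
            n_ev = rng.poisson(spec.ied_rate_per_min * spec.duration_s / 60.0)
            template = _ied_template(spec.rate, spec.ied_amp)
            starts = np.sort(
                rng.uniform(0, spec.duration_s - len(template) / spec.rate, n_ev)
            )
            for s in starts:
                i0 = int(s * spec.rate)
                x[i0 : i0 + len(template)] += template
                ied_times.append(float(s))
        data[c] = x
        truth_rows.append(
            {
                "channel": f"ch{c}",
                "envelope_tau_s": spec.envelope_tau_s,
                "n_ied": len(ied_times),
                "ied_times": ied_times,
                "sws_epochs": list(spec.sws_epochs),
            }
        )
    rec = Recording(samples=data, rate=spec.rate)
    return rec, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

#: cognitive test battery: 14 tests over four domains
TEST_BATTERY: dict[str, int] = {
    "language": 4,
    "verbal_memory": 4,
    "working_memory": 3,
    "attention": 3,
}

CONTEXTS = ("first_day", "last_day", "low_asm_day", "high_asm_day")

CONTROL_FEATURES = (
    "pow_delta",
    "pow_theta",
    "pow_alpha",
    "pow_beta",
    "pow_gamma",
    "pow_high_gamma",
    "ied_rate",
    "sws_frac",
    "asm_load",
)


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic cohort.

    ``impairment_beta`` is the logistic slope of domain-impairment
    probability on the standardized negative log correlation time; 0 removes
    the link entirely.  ``asm_factor`` multiplies the correlation time on the
    highest-dose day (intermediate days interpolate in the exponent).
    """

    n_subjects: int = 80
    n_days: int = 5
    tau_log_mean: float = math.log(0.5)
    tau_log_sd: float = 0.4
    asm_factor: float = 0.7
    impairment_alpha: float = 0.0
    impairment_beta: float = 2.0
    tc_noise_sd: float = 0.12
    ied_rate_per_min: float = 2.5
    sws_frac_mean: float = 0.18
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if not 0 < self.asm_factor <= 1:
            raise ValueError("asm_factor must lie in (0, 1]")


@dataclass
class CohortData:
    """Generated cohort: features, metadata and full ground truth."""

    features: pd.DataFrame  # long form: subject, feature, context, value
    scores: pd.DataFrame  # subject, domain, test, score, norm_mean, norm_sd
    schedules: pd.DataFrame  # subject, day, drug, dose, defined_daily_dose
    truth: pd.DataFrame  # per-subject latent parameters
    day_truth: pd.DataFrame  # per subject-day tau and ASM load


def _tc_of_tau(tau: float) -> float:
    """Expected TC (s) of an AR(1) envelope with correlation time tau:
    half-width from the lag-1 peak, tau*ln2 + one bin."""
    return tau * math.log(2.0) + 0.125


def gen_cohort(spec: CohortSpec) -> CohortData:
    """Generate cohort metadata and feature tables with ground truth.

    Per subject a latent correlation time tau is drawn lognormally; a
    tapered multiday ASM schedule scales tau per day; observed TC features
    are the theoretical TC of the day's tau under multiplicative noise;
    surrogate-TC and all control features are generated independently of the
    impairment mechanism.  Cognitive scores are drawn so that impaired
    domains show >= 2 tests at or below one SD under the norm.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    tau0 = np.exp(rng.normal(spec.tau_log_mean, spec.tau_log_sd, size=n))
    z_tau = (np.log(tau0) - spec.tau_log_mean) / spec.tau_log_sd
    p_imp = expit(spec.impairment_alpha - spec.impairment_beta * z_tau)

    # tapered dose pattern: start high, taper to a minimum, partial re-up
    base_pattern = np.linspace(1.0, 0.2, spec.n_days)
    if spec.n_days >= 3:
        base_pattern[-1] = 0.5

    feat_rows, sched_rows, score_rows, truth_rows, day_rows = [], [], [], [], []
    for s in range(n):
        subject = f"S{s:03d}"
        doses = base_pattern * (1.0 + 0.1 * rng.standard_normal(spec.n_days))
        doses = np.clip(doses, 0.05, None)
        load = doses  # already DDD-normalized (single drug, DDD = 1)
        for d in range(spec.n_days):
            sched_rows.append(
                {
                    "subject": subject,
                    "day": d,
                    "drug": "levetiracetam",
                    "dose": float(doses[d]),
                    "defined_daily_dose": 1.0,
                }
            )
        rel = load / load.max()
        tau_day = tau0[s] * spec.asm_factor ** rel
        low_day = int(np.argmin(load))
        high_day = int(np.argmax(load))
        context_day = {
            "first_day": 0,
            "last_day": spec.n_days - 1,
            "low_asm_day": low_day,
            "high_asm_day": high_day,
        }
        for d in range(spec.n_days):
            day_rows.append(
                {
                    "subject": subject,
                    "day": d,
                    "asm_load": float(load[d]),
                    "tau_s": float(tau_day[d]),
                }
            )
        for ctx, d in context_day.items():
            tc = _tc_of_tau(tau_day[d]) * math.exp(
                rng.normal(0.0, spec.tc_noise_sd)
            )
            feat_rows.append(
                {"subject": subject, "feature": "tc", "context": ctx, "value": tc}
            )
            # subject-level surrogate TC: mean over many shuffled
            # channel-windows, i.e. continuous and just above the floor
            surr = 0.125 + 0.03 * rng.gamma(2.0, 1.0)
            feat_rows.append(
                {
                    "subject": subject,
                    "feature": "tc_surrogate",
                    "context": ctx,
                    "value": surr,
                }
            )
            for name in CONTROL_FEATURES:
                if name == "ied_rate":
                    v = rng.poisson(spec.ied_rate_per_min * 10) / 10.0
                elif name == "sws_frac":
                    v = float(np.clip(rng.normal(spec.sws_frac_mean, 0.07), 0, 1))
                elif name == "asm_load":
                    v = float(load[d]) * math.exp(rng.normal(0, 0.05))
                else:
                    v = math.exp(rng.normal(0.0, 0.5))
                feat_rows.append(
                    {"subject": subject, "feature": name, "context": ctx, "value": v}
                )

        impaired = {}
        for domain, n_tests in TEST_BATTERY.items():
            imp = bool(rng.random() < p_imp[s])
            impaired[domain] = imp
            for k in range(n_tests):
                z = rng.normal(-1.8, 0.5) if imp else rng.normal(0.3, 0.7)
                score_rows.append(
                    {
                        "subject": subject,
                        "domain": domain,
                        "test": f"{domain}_{k}",
                        "score": 100.0 + 15.0 * z,
                        "norm_mean": 100.0,
                        "norm_sd": 15.0,
                    }
                )
        truth_rows.append(
            {
                "subject": subject,
                "tau_s": float(tau0[s]),
                "p_impairment": float(p_imp[s]),
                "low_asm_day": low_day,
                "high_asm_day": high_day,
                **{f"impaired_{k}": v for k, v in impaired.items()},
            }
        )

    return CohortData(
        features=pd.DataFrame(feat_rows),
        scores=pd.DataFrame(score_rows),
        schedules=pd.DataFrame(sched_rows),
        truth=pd.DataFrame(truth_rows),
        day_truth=pd.DataFrame(day_rows),
    )
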