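# Methods

This note documents the models, estimators and design choices behind
`neurotc`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The temporal-correlation statistic

High-γ (56–96 Hz) power is used as a proxy for local population firing.
Per channel, median power over the six 8 Hz-spaced frequency bins inside
56–96 Hz is computed in non-overlapping 125 ms windows; a 32-sample Hann
periodogram at 256 Hz *is* the single-segment Welch estimate at 8 Hz
resolution (no sub-segmenting is possible at that resolution, so one taper
is used and documented as equivalent). Powers are log10-transformed, which
makes the downstream statistic invariant to affine rescaling of the raw
signal: amplitude scaling becomes an additive constant in log power and
cancels in the autocorrelation.

Sample ACFs (biased, divide-by-*n*, mean-subtracted — stable at long lags)
are computed at lags 0.125–60 s in sliding 120 s windows with 90 s overlap;
lag 0 is excluded because it equals one by construction and carries no
information about the decay. Windows containing masked or zero-variance bins
are skipped entirely rather than interpolated. Window ACFs are aggregated by
an element-wise median (robust to outlier windows and invariant to window
order), and the TC is the half-width from the lag-1 peak:

* baseline `b` = median aggregated ACF over 40–60 s lags,
* threshold = `b + (ACF(1) − b)/2`,
* TC = (first lag ≥ 2 below threshold − 1) × 0.125 s.

Measuring the width from the lag-1 peak makes the floor exactly one bin
(0.125 s); a first-crossing convention could not produce that floor. If
ACF(1) ≤ b the decay is degenerate (already at noise level) and the TC is
pinned to the floor and flagged.

**Cap semantics.** A "no crossing within 60 s → TC = 60 s, capped" branch is
retained defensively, but under the default parameters it is unreachable: at
least half of the 40–60 s lag values lie at or below their median `b`, which
sits strictly under the threshold whenever ACF(1) > b, so a crossing always
occurs at or before the baseline band. The practical ceiling of the
statistic is therefore set by where the ACF meets its long-lag noise floor.

**Surrogates.** Time-shuffling the power bins preserves the power
distribution while destroying temporal order; surrogate TCs sit at the
125 ms floor. Because the crossing rule compares noisy sample-ACF values
against a threshold midway between two near-zero quantities, a *single*
shuffled realization lands exactly on the floor with probability ≈ 0.8, not
1 (the lag-2 sample ACF falls below the midpoint threshold with roughly that
probability). The floor is therefore asserted on the *median* of a surrogate
distribution, which equals 0.125 s with overwhelming probability; tests
additionally require ≥ 70 % of individual surrogates at the floor.

**Size-matched comparisons.** When contrasting conditions with unequal
amounts of data, the majority ACF-window set is repeatedly (100×) subsampled
without replacement to the minority size and TCs are averaged, removing the
sample-size dependence of the median-aggregated ACF.

## Preprocessing

Recordings are notch-filtered at 50 and 100 Hz (IIR notch, Q = 30,
zero-phase), brought to the common 256 Hz rate with a polyphase antialiasing
resampler, and high-pass filtered at 0.1 Hz (4th-order Butterworth,
zero-phase). The nominal 0.1–128 Hz band's upper edge equals the Nyquist
frequency at 256 Hz and is realized by the resampler's antialiasing lowpass
rather than an explicit bandpass. Channels are rejected if constant or if
any value of their median-averaged Welch spectrum exceeds Q3 + 6·IQR of that
channel's own spectral values — the reference distribution for the
"abnormal peak" rule is a documented interpretation, configurable via
`reject_iqr_factor`. Seizure intervals are expanded by ±600 s and masked;
power bins overlapping masked time are invalidated, which in turn excludes
any 120 s ACF window touching them.

## Band powers, vigilance index and state labels

Control band powers (δ 0.5–4, θ 4–8, α 8–12, β 12–30, γ 30–45, high-γ
55–95 Hz) are *integrated* Welch power (PSD × bin width summed over the
band) per 120 s segment; integration, unlike a median over band bins,
preserves narrowband peaks and gives the expected bandwidth scaling under
flat spectra. Segments overlapping any masked sample are omitted —
conservative relative to the alternative of computing on partial data.

The vigilance index (θ+δ)/(α+β_high+spindle) is computed on 30 s windows;
spindle (11–16 Hz) and β_high (20–30 Hz) edges are configurable defaults,
as the originating band definitions are not fixed here. A 30 s window is
SWS when its index exceeds that day's mean by more than one population SD
(per-day thresholding makes the rule invariant to positive rescaling of a
day's indices; constant days label nothing; single-window days are
excluded). A 120 s TC window is SWS if any of its four 30 s constituents is.

IED events are taken as annotations (or synthetic ground truth); windows are
binned into "none" (0 events) and "5–30 events/min", with rates in (0,5) or
>30 excluded from the contrast, and a channel enters the IED analysis only
with ≥ 50 windows in each contrast bin. ASM load is the DDD-normalized dose
sum per day; days with rescue benzodiazepines are removed; the highest and
lowest remaining days define the high/low contrast, ties resolving to the
earliest day; a constant load profile (no tapering) excludes the subject.

## Network model

N = 1024 neurons by default (tests and the acceptance sweep use N = 256 for
single-CPU turnaround; the phase transition and perturbation phenomenology
are preserved at that size) on a periodic square grid. Weights are
`u_ij · exp(−r_ij²/(2σ²))` with `u_ij ~ U[0,1)`, σ = 4 grid units, torus
distances, zero diagonal; a random 20 % of neurons (205 of 1024, rounding
the fraction) have their outgoing weights negated. One global scalar rescale
sets the spectral radius (largest eigenvalue modulus; eigenvalues may be
complex) to λ, the control parameter.

Dynamics: at each of 5000 steps, every neuron independently activates with
probability equal to its weighted input sum clipped to [0, 1] — the
clipped-probability rule handles net-inhibitory input via the p = 0 branch —
then one uniformly chosen neuron is forced active (background drive).
Perturbation semantics, in order of application within a step: stochastic
update → drive → IED patch (center + ⌈0.2 N⌉ − 1 nearest torus neighbors,
ties by index) → off-step silencing. Silencing overrides the drive so that
p_off = 1 yields exact quiescence; off-periods are per-step events without
duration structure. The ASM factor f_exc scales excitatory rows *after* the
λ-rescale and the radius is deliberately not re-normalized — moving the
effective operating point is the mechanism. The model TC uses the same
half-width rule on the post-transient (first 500 steps discarded) population
activity, lags 1–500 steps, with baseline taken as the median ACF over the
last fifth of lags (the analog of the data pipeline's 40–60 s tail; fully
saturated supercritical runs have constant activity and an undefined TC,
recorded as NaN in sweeps). All randomness is drawn up-front from a seeded
generator, making runs bit-reproducible.

## Synthetic data generator

Signals are built at 256 Hz from: (i) a 55–100 Hz Gaussian carrier
amplitude-modulated by exp(AR(1)) with lag-1 coefficient
`exp(−0.125/τ)` at the 8 Hz bin rate and log-sd 0.5 — τ is the ground-truth
quantity the TC estimator should recover; under the half-width rule the
expected estimate is ≈ τ·ln 2 + 0.125 s, and periodogram estimation noise
rescales the measured ACF without moving its crossing lag; (ii) a 1/f
background; (iii) δ-band (0.5–4 Hz) noise raised by a configurable boost
(default +10 dB) during designated SWS epochs; (iv) a fixed spike-wave IED
template (70 ms sharp transient, 300 ms opposite slow half-wave) at Poisson
times — morphological realism is not a goal, detectability by rate-binning
is; (v) optional 50/100 Hz line sinusoids.

Cohorts (default n = 80 subjects, 5 days, matching the scale at which the
across-subject inference is exercised) draw a latent per-subject τ
lognormally (median 0.5 s, log-sd 0.4, in the range reported for human
iEEG); a tapered single-drug ASM schedule scales τ per day by
`asm_factor^(relative load)` with asm_factor = 0.7 (within reported taper
depths); observed TC features are the theoretical TC of the day's τ under
12 % multiplicative noise. Domain impairment is Bernoulli with logistic
probability in standardized −log τ (slope 2 by default; 0 removes the link
for null calibration). Impaired domains draw test z-scores around −1.8 so
that the two-tests-at-z≤−1 rule recovers the latent flag with small label
noise; the subject-level surrogate-TC feature is continuous just above the
0.125 s floor (a mean over many shuffled channel-windows), and all control
features (band powers, IED rate, SWS fraction, ASM load) are generated
independently of the impairment mechanism. What passing tests show is that
the pipeline recovers programmed correlation structure and group differences
under these idealized conditions; real iEEG adds nonstationarity, artifacts,
montage effects and correlated confounds that the generator deliberately
does not model.

## Inference

Within-subject contrasts use the two-sided Wilcoxon signed-rank test
(≥ 5 non-zero differences required; all-zero differences are an error).
Impaired-vs-non-impaired contrasts use the Brunner–Munzel test (t
approximation with Satterthwaite-type degrees of freedom; an exact
permutation variant is available for group sizes ≤ 10), with the relative
effect P(X<Y) + ½P(X=Y) computed from midranks — verified exactly against an
O(n²) pairwise-count oracle. Complete separation makes the rank variance
degenerate; the p-value is then NaN and flagged rather than fabricated. The
comparison grid spans feature × context (first, last and low-ASM day) ×
cognitive domain; cells need ≥ 5 subjects per group (the insufficient-sample
rule), BH correction at α = 0.05 spans all testable cells of a run, and each
feature family's cell p-values are KS-tested one-sidedly against
Uniform(0,1). Note that when one family carries strong effects, the BH
threshold rises and occasional null-family cells can cross it; family-level
conclusions therefore rest on the KS uniformity check, not on single cells.

## Problem sizes and numerical choices

Simulation-based checks use N = 256 neurons, 5000 steps, 50 repetitions per
grid point (100 for the supercritical excitability check), chosen as the
package's standard desk-scale configuration. Estimator-recovery checks use
600 s signals (17 ACF windows) per τ and 20 seeds. DFA uses first-order
detrending over ~12 log-spaced scales from 4 bins to a quarter of the
series. Spectral radius rescaling is exact to floating-point roundoff and is
validated at 1e-6 relative tolerance. All stochastic stages take explicit
seeds; pipeline stage seeds derive deterministically from one global seed,
and result CSVs are byte-reproducible for a fixed config.

## Known limitations

* Off-periods lack multi-step duration structure; the per-step
  simplification is documented rather than guessed at.
* The channel-rejection reference distribution and the vigilance-band edges
  are interpretations (configurable, defaults documented above).
* EDF support targets plain 16-bit continuous EDF with integer sampling
  rates; the built-in writer exists because no writer library is assumed,
  and round-trips are validated against an independent reader.
* The cohort generator emulates feature-level statistics; it does not model
  electrode geometry, sleep architecture or seizures.
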