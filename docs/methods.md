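# Methods

This note documents the models the package implements, the parameter
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices that matter.

## Experimental design

A session is a sequence of trials: 2-s CS, 15-s trace interval, then (in
acquisition, CS+ only) a 1-s electric US; recall sessions deliver no US but
play a startle probe 13 s after CS offset on every trial (2 s before the
would-be US). Inter-trial intervals are drawn uniformly from 30 ± 2 s. The
CS order is drawn uniformly over all sequences with the required
per-condition counts (20/20 acquisition, 15/15 recall) and no more than
three equal CS in a row, by rejection sampling of uniform shuffles —
unbiased among admissible sequences, at a modest rejection rate. The
ITI digit-stream task is represented only as an event timestamp (uniform
5–10 s after the actual or expected US offset; in recall we anchor on the
expected-US offset, since the probe has its own fixed latency and the task
exists to bridge the ITI, not the trace). US intensity calibration
interpolates a rating–intensity curve at a fraction (default 90%) of the
"clearly painful" anchor rating; non-monotone rating curves are first
projected onto a monotone fit by isotonic regression (real rating series
are noisy), and the target is never extrapolated outside the rated range.

## Response models and inversion

**Startle eyeblink.** Two quantification routes. *Peak scoring*: high-pass
30 Hz (4th-order Butterworth), 50-Hz notch (Q = 35), rectification, 20-ms
centered moving average; the amplitude is the envelope maximum 20–100 ms
after probe onset, endpoints inclusive on the sample grid. *GLM*: band-pass
50–470 Hz, notch, rectification, 4th-order low-pass at 1/(2π·3 ms) ≈ 53 Hz
(the standard first-order-equivalent reading of a smoothing time
constant); per trial, the envelope is regressed (with intercept) on a
canonical blink kernel (gamma density, mode 45 ms, SD ≈ 25 ms) shifted
over candidate onsets 0–100 ms in 1-ms steps, keeping the slope at the
RSS-minimizing onset. Amplitudes are normalized per subject by the CS−
mean, which removes gain factors such as electrode impedance; after
normalization the CS− mean is exactly 1.

**Skin conductance.** Preprocessing: causal first-order 0.0159–5 Hz
band-pass, anti-alias low-pass at 4 Hz, decimation to 10 Hz, and a missing
mask on [US − 0.2 s, US + 1.6 s) for the stimulation artifact (mask applied
after filtering, before modeling). The trial model superposes three
sudomotor bursts — unit-peak Gaussians of fixed dispersion σ = 0.3 s
convolved with a Bateman-type kernel (rise 0.75 s, decay 2.5 s, onset
delay 1 s, peak-normalized): one at CS onset + 1 s, one free within the
trace window (8 s after CS offset to 1 s before the nominal US; on recall
trials the window is anchored at the nominal US time, CS offset + 15 s),
and one at (nominal) US + 1 s. Amplitudes are constrained non-negative.
Inversion profiles the latency: at each candidate on a 0.5-s grid the
amplitudes and intercept are solved by bounded linear least squares
(BVLS), then the best latency is refined by bounded 1-D minimization; a
latency at its bound or a failed solve flags (but keeps) the trial. This
deterministic scheme replaces a variational inversion of the same burst
structure; it is testable by exact recovery on noiseless input. The fixed
burst latencies (1 s) and dispersion (0.3 s) are conventional values for
event-locked sudomotor activity; both are configuration fields of
`ScrTrialModel`. A trial AUC (trapezoid of the baseline-subtracted signal,
CS onset to US, missing samples interpolated) is provided as a model-free
summary.

**Pupil.** Validity filtering per eye: plausible range 1.5–9 mm; dilation
speed above median + 16·MAD of the two-sided inter-sample speed; 50-ms
padding around gaps ≥ 75 ms; deviation from a 0.3-s moving-average
trendline above median + 16·MAD (2 passes); valid islands shorter than
50 ms. Eyes are combined by averaging valid samples with one-eye fallback;
samples with gaze eccentricity beyond 5° are missing; for time-course use
the series is linearly interpolated and smoothed with a 1-s moving average
(edge-renormalized so constants pass through unchanged). Trials with
strictly more than 50% missing between CS onset and the US timepoint are
excluded. The threshold constants follow common robust pupil-preprocessing
practice and are all `PupilConfig` fields. Arbitrary-unit-to-mm conversion
is left as an identity map because the generator works in mm; a recording
adapter would supply the affine coefficients. Quantification is a
single-trial GLM on a CS-locked kernel (gamma, mode 2.5 s), with intercept,
linear drift, and a cosine high-pass basis (cutoff 100 s) absorbing slow
baseline wander; a session-specific kernel can instead be fitted from
trial-averaged CS+ curves (baseline-subtracted grand average, 1-s
smoothing, truncation to 0–17 s, peak normalization). Fitted kernels carry
their source dataset id and refuse evaluation on the same dataset unless
overridden — train/evaluate separation is enforced structurally.

**Heart period.** QRS detection follows the Pan–Tompkins chain (5–15 Hz
band-pass, derivative, squaring, 150-ms moving-window integration,
adaptive signal/noise thresholds with 200-ms refractory period and
search-back at half threshold when a gap exceeds 1.66× the running RR
mean), with final R times refined to the dominant raw deflection. Each
inter-beat interval is assigned to the later beat; IBIs outside
600–1200 ms are rejected; the accepted series is linearly interpolated on
a 10-Hz grid from t = 0 (edge-held) and band-pass filtered 0.015–0.5 Hz
(4th order, zero-phase). Quantification is a US-locked GLM on a biphasic
kernel peaking ~4 s (bradycardia) with a later recovery undershoot.

**Respiration.** Inspiration onsets are positive-going zero crossings of
the 0.04–1 Hz band-limited signal; each cycle's amplitude (max − min of
the detrended cycle) is assigned to the *next* cycle onset and
interpolated at 10 Hz with no further filtering. The early/late response
functions (gamma kernels, modes 4.5 s and 9.5 s) describe this *derived*
series: because of the assignment convention the measured response lags
the physiological amplitude modulation by roughly one breathing cycle, so
the kernels peak later than the underlying modulation (which the generator
models with a 2-s-peak kernel).

## Synthetic data

The generator is phenomenological: each channel is baseline + event-locked
kernel responses + noise + optional artifacts. Per-trial true amplitudes
share one structure across modalities: base amplitude × exponential
habituation exp(−λ·(trial−1)) × (1 + δ·[CS+]) × log-normal trial jitter
(SD 0.3), with λ = 0.04 and δ = 0.5 by default, and log-normal
between-subject scaling (SD 0.4) in cohorts. Defaults per channel: EMG
blink base 10 (arbitrary units) against band-limited 50–470 Hz baseline
noise of SD 1 — startle blinks are large relative to baseline EMG — with a
small 50-Hz mains component; SCR bursts 0.3/0.3/0.6 µS (CS/trace/US) on a
2-µS drifting baseline with <2 Hz noise of SD 0.03 µS (peak
signal-to-noise ≈ 10, a clean but realistic electrodermal recording), the
trace-burst latency uniform 8.5–13.5 s after CS offset, and a zero-mean
pulse-train artifact during the US; pupil responses 0.3 mm on a 4-mm
baseline with blinks (~8/min) and gaze excursions beyond 5° (~1/min);
heart-period lengthening 40 ms through the bradycardia kernel on a 0.8-s
baseline with respiratory sinus arrhythmia; respiration cycle-amplitude
modulation 30% at a 4-s period. The EMG blink burst is a deterministic
Gaussian-enveloped 127-Hz carrier whose gain is calibrated once per
sampling rate so that the peak-scoring chain recovers the true amplitude
exactly on noiseless input. Sampling rates: EMG 2 kHz (the band-pass needs
≥ 940 Hz), pupil/ECG 500 Hz, SCR and respiration 100 Hz (both signals are
band-limited far below that; generating at the acquisition hardware's
2 kHz would only cost time).

What the generator does *not* emulate: ECG morphology beyond a QRS-like
wavelet (no P/T waves), eye movements beyond artifact injection,
non-stationary noise, movement artifacts, electrode drift or detachment,
and any learning dynamics beyond monotone habituation — so passing
recovery tests demonstrate correctness of the estimators under the assumed
forward models, not robustness to every failure mode of real recordings.

For statistical calibration studies an estimate-level generator bypasses
signal synthesis entirely: subject i has gain s_i (log-normal) and
conditioned effect u_i ~ N(δ, σ_b²), and trial estimates are
s_i·h_t·(1 + u_i·[CS+] + ε) with ε ~ N(0, σ_w²). For the n-trial average,
the SD of the subject mean CS+/CS− difference after CS− normalization is
√(σ_b² + 2σ_w²/n) to first order, so δ can be chosen to hit a target
population effect size exactly (`delta_for_target_d`). The effect-size
recovery suite uses σ_b = σ_w = 0.5 (normalized-unit variability of the
size seen in startle data) and λ = 0, which keeps the calibration formula
exact.

## Statistics

**Cluster-level permutation test.** Input is subjects × trials ×
timepoints (default 0–17 s at 10 Hz, 170 points). The observed statistic
is the per-timepoint paired t over subject condition means; clusters are
maximal runs of same-sign t exceeding the two-tailed point-wise threshold
(cluster-forming α = .05 on the paired-t distribution — the threshold is a
free parameter of this family of tests and is config-exposed); the cluster
statistic is the mass Σ|t|. The null permutes trial labels within each
subject (preserving counts), recomputes the t time course, and records the
maximum cluster mass; p = (1 + #{null ≥ observed}) / (1 + n_perm), which
is strictly positive and valid for random permutations. The implementation
vectorizes all permutations per subject as a selection-matrix product and
accumulates only per-permutation sums and sums of squares across subjects,
so 1000 permutations on 20 × 30 × 170 run in well under a second.
Timepoints with identically zero differences across subjects give t = 0.

**Trial-averaging calibration.** For n = 1..15, per-subject means of the
first n trials per condition (presentation order within condition) enter a
paired t-test; Cohen's d = mean difference / SD of differences; Hedges'
g = d·(1 − 3/(4·df − 1)). The n maximizing |d| is selected, and a
confirmation mode re-evaluates only that n on an independent dataset —
selection and confirmation never share data. The 15 tests are deliberately
not multiplicity-corrected: the calibration selects by effect size, and
the independent confirmation is the error control. All-zero differences
give t = d = 0; zero-variance nonzero differences are flagged
(`zero_variance`) and excluded from selection.

**Habituation and mixed models.** The decay parameter is fitted by
ordinary least squares to all trials pooled across subjects — exponential
a·exp(−λ(trial−1)) via a λ grid (0–1, step 0.01) with profiled amplitude
and bounded local refinement, λ ≥ 0 with exact zero preferred on ties;
linear via the OLS slope — and then frozen (the model records its source
dataset). The condition test is a linear mixed model of amplitude on
trial-regressor × condition with a random intercept and (default) random
trial slope per subject, estimated by maximum likelihood; a singular or
non-convergent slope fit falls back to the intercept-only structure with a
logged warning, and the structure can be chosen by AIC on a training
dataset. Single-df fixed effects are tested by Wald F with denominator
df = n_obs − n_subjects − 3 (observations minus subject intercepts minus
the non-intercept fixed effects — the convention that reproduces the df
bookkeeping of standard mixed-model ANOVA tables on balanced data);
partial η² = F/(F + df_den).

**Power planning.** The smallest n with exact noncentral-t power ≥ the
target: paired, df = n − 1, ncp = d√n; two-sample 1:1, df = 2n − 2,
ncp = d·√(n/2), returning the total 2n. The normal approximation is never
used (it understates n by ~2 for d = 0.44).

**Printed-summary helpers.** Pooled-variance two-sample t and d from group
summaries, and the 2×2 chi-square with Yates continuity correction (the
continuity-corrected statistic is the default for 2×2 tables here).

## Numerical choices and problem sizes

Filters are designed as Butterworth second-order sections and applied with
`scipy.signal.sosfilt` (causal chains) or `sosfiltfilt` (zero-phase
chains); every design is cross-checked in the test suite against an
independently written per-sample direct-form II transposed biquad loop to
1e-9 on white noise. Decimation always low-pass filters at 4 Hz before
subsampling. Peak-scoring windows are closed intervals on the sample grid.
The SCR inversion treats masked samples by excluding them from the
objective rather than interpolating. Moving averages used for smoothing
and trendlines renormalize at the edges.

Validation problem sizes were chosen to give tight Monte-Carlo error at
interactive runtimes: 500 null cohorts × 1000 permutations for the
permutation-test error rate (binomial MC SD ≈ 0.01), 200 subjects for the
parameter-recovery suites, 500 cohorts of 26 subjects for the effect-size
calibration, and 10,000 seeded schedules for the design invariants.

## Known limitations

- The canonical kernels are parametric stand-ins with sensible modes and
  widths; absolute amplitude scales are therefore arbitrary, and all
  validation is by parameter recovery and CS−-normalized effect sizes, not
  kernel-shape fidelity. The fitted-kernel route is preferred when a
  training dataset exists.
- The LME denominator df convention is one of several defensible choices
  (residual vs Satterthwaite-type); it is configurable in the sense that
  the F and df are returned separately and can be re-referenced.
- The pupil pipeline expects gaze in degrees and diameter in mm; vendor
  unit conversion is out of scope.
- Reading vendor-native (Biopac/EyeLink/Matlab-container) files is not
  implemented; signals enter through the delimited-text container or the
  generator.
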