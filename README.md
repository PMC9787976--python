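# tracefear

Simulation, preprocessing, and model-based quantification of human trace
fear-conditioning psychophysiology.

In trace fear conditioning, a 2-s visual conditioned stimulus (CS+) is
separated from a ~1-s aversive electric stimulus (US) by a stimulus-free
15-s trace interval; a second stimulus (CS−) is never reinforced. Whether a
person has learned — and a week later still remembers — the CS–US
association is read out from conditioned anticipatory responses in
peripheral physiology. This package implements a complete measurement
pipeline for that readout across five channels:

- **startle eyeblink (SEBR)** — orbicularis oculi EMG responses to acoustic
  probes delivered 13 s after CS offset during recall, quantified by peak
  scoring (max of the rectified, 20-ms-smoothed envelope 20–100 ms
  post-probe) or by regression on a canonical blink kernel;
- **skin conductance (SCR)** — a per-trial three-burst forward model
  (CS-locked, free-latency trace-interval, US-locked sudomotor bursts, each
  a fixed-dispersion Gaussian driving a Bateman conductance kernel),
  inverted by bounded nonlinear least squares, plus a trial AUC summary;
- **pupil size** — validity filtering (range/speed/edge/trendline/island),
  binocular combination, ±5° gaze masking, and single-trial GLM on a
  canonical or data-fitted dilation kernel;
- **heart period** — Pan–Tompkins-style QRS detection, 600–1200 ms
  inter-beat-interval screening, 10-Hz interpolation, and a US-locked
  bradycardia GLM;
- **respiration amplitude** — inspiration-cycle detection with
  amplitude-to-next-cycle assignment and early/late response-function GLM.

Because no public dataset is needed to exercise any stage, a first-class
synthetic-data module generates full multi-channel sessions under the
experimental design (acquisition: 20 CS+ / 20 CS−, 100% reinforcement;
recall: 15/15 with startle probes; 30 ± 2 s ITIs; max 3 equal CS in a row)
with known per-trial ground truth, so every estimator is validated by
parameter recovery.

The statistics layer implements the study-level inference tools:

- cluster-level random permutation test on 0–17 s trial-averaged time
  courses (170 paired t-tests at 10 Hz; within-subject label shuffling;
  max-cluster-mass null; add-one p);
- retrodictive-validity calibration: paired t and Cohen's d / Hedges' g of
  the first-1..n trial averages (n = 1..15), selecting the n with maximal
  |d| and confirming it on an independent dataset;
- habituation-corrected linear mixed models (exponential-decay or linear
  trial regressor, fitted once and frozen; random intercept + trial slope
  per subject; Wald F tests and partial η²);
- exact noncentral-t power planning, e.g. the smallest n with
  `P(T' > t_crit(α, df)) ≥ power` where `T' ~ nct(df, d·√n)`.

## Worked example

Simulate an 8-subject recall cohort, score startle eyeblinks, normalize by
each subject's CS− mean, and run the trial-averaging calibration:

```
$ tracefear run --seed 7 --out demo_out --session recall \
      --modality emg --n-subjects 8
wrote results to demo_out
startle peak calibration: best n=15, d=1.507 (t=4.26, p=0.004)
```

`demo_out/` then holds the raw and CS−-normalized estimate tables (tidy
TSV, one row per subject × trial × component × method), the calibration
table, and a provenance JSON (config hash, seeds, version). The calibration
table reports, for each n, the paired t over subjects of the first-n CS+
vs CS− means; with the generator's default conditioned effect the effect
size grows with the number of averaged trials (d = 0.40 at n = 1 rising to
1.51 at n = 15 in this run — small simulated cohorts overshoot the
population effect easily, which is exactly why the calibration insists on
confirmation in a second dataset).

Power planning from the command line:

```
$ tracefear power --d 0.44
34 pairs
$ tracefear power --d 0.22 --design two_sample
514 participants total
```

The first is the sample size needed to demonstrate a d = 0.44 recall
effect (one-tailed paired t, α = .05, 80% power); the second is the total
across two equal arms needed to detect a 50% reduction of that effect
between intervention and placebo.

The same functionality is available as a library
(`tracefear.design`, `.synthdata`, `.preprocess`, `.respquant`, `.stats`,
`.pipeline`); see `docs/methods.md` for the models, parameter defaults,
and validation strategy.

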