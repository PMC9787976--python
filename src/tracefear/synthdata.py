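"""Synthetic multi-channel recordings with known ground truth.

Generators for the five modalities of the trace-conditioning design (startle
EMG, skin conductance, pupil + gaze, ECG, respiration belt), driven by a
shared :class:`GroundTruth` that fixes per-trial response amplitudes
(conditioned effect × exponential habituation × trial-level jitter), SCR
trace-burst latencies, and noise levels. Every generator is deterministic
given its seed, and at zero effect and zero noise yields analytically known
output, so each downstream stage can be tested by parameter recovery.

The generative model is intentionally phenomenological: each channel is a
baseline process plus event-locked kernel responses plus noise and optional
artifacts. See ``docs/methods.md`` for what it does and does not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .design import CS_PLUS, TrialSchedule, generate_schedule
from .respquant import ScrTrialModel, burst_response_shape, canonical_rf
from .signals import ContinuousSignal


def stats_gamma_pdf(grid: np.ndarray, mode: float, shape: float) -> np.ndarray:
    from scipy import stats as sst

    return sst.gamma.pdf(grid, shape, scale=mode / (shape - 1.0))

__all__ = [
    "TruthParams",
    "ModalityTruth",
    "GroundTruth",
    "SessionDataset",
    "make_ground_truth",
    "synth_emg",
    "synth_scr",
    "synth_pupil",
    "synth_ecg",
    "synth_respiration",
    "synth_session",
    "synth_cohort",
    "synth_estimate_cohort",
    "synth_null_timecourses",
    "delta_for_target_d",
]


@dataclass
class TruthParams:
    """Population-level parameters of the generative model.

    delta_mean
        CS+ minus CS− response amplitude, in units of the CS− mean.
    habituation_lambda
        Per-trial exponential decay rate of response amplitudes.
    trial_jitter_sd
        SD of the log-normal multiplicative trial-to-trial variability.
    base_amplitude / noise_sd
        Per-modality response scale and additive noise SD, in channel units
        (EMG arbitrary volts, SCR µS, pupil mm, heart period s, respiration
        peak-to-trough belt units).
    """

    delta_mean: float = 0.5
    habituation_lambda: float = 0.04
    habituation_form: str = "exponential"
    trial_jitter_sd: float = 0.3
    base_amplitude: dict = field(
        default_factory=lambda: {
            "emg": 10.0,
            "scr_cs": 0.3,
            "scr_trace": 0.3,
            "scr_us": 0.6,
            "pupil": 0.3,
            "heart_period": 0.04,
            "respiration": 0.3,
        }
    )
    noise_sd: dict = field(
        default_factory=lambda: {
            "emg": 1.0,
            "scr": 0.03,
            "pupil": 0.02,
            "heart_period": 0.01,
            "respiration": 0.01,
        }
    )


@dataclass
class ModalityTruth:
    """Realized per-trial truth for one modality.

    ``amplitude`` is the modality's primary component (SEBR peak, SCR trace
    burst, pupil CS-locked, heart-period / respiration US-locked).
    ``components`` holds all SCR bursts; ``latency`` the SCR trace-burst
    latency in seconds after CS offset.
    """

    amplitude: np.ndarray
    components: dict[str, np.ndarray] | None = None
    latency: np.ndarray | None = None


@dataclass
class GroundTruth:
    modalities: dict[str, ModalityTruth]
    params: TruthParams
    habituation: np.ndarray  # h(trial), multiplicative

    def __post_init__(self) -> None:
        for name, m in self.modalities.items():
            if name in ("emg", "scr") and np.any(m.amplitude < 0):
                raise ValueError(f"negative true amplitude for {name}")


@dataclass
class SessionDataset:
    schedule: TrialSchedule
    signals: dict[str, ContinuousSignal]
    ground_truth: GroundTruth
    subject_id: str = "s0"

    def __post_init__(self) -> None:
        need = self.schedule.trials[-1].nominal_us_onset + 20.0
        for name, sig in self.signals.items():
            if sig.duration < need:
                raise ValueError(f"signal {name} shorter than last event + 20 s")


def _habituation(params: TruthParams, n_trials: int) -> np.ndarray:
    k = np.arange(n_trials)
    if params.habituation_form == "exponential":
        return np.exp(-params.habituation_lambda * k)
    if params.habituation_form == "linear":
        return np.clip(1.0 - params.habituation_lambda * k, 0.0, None)
    raise ValueError(f"unknown habituation form {params.habituation_form!r}")


def make_ground_truth(
    schedule: TrialSchedule,
    params: TruthParams | None = None,
    seed: int = 0,
) -> GroundTruth:
    """Draw per-trial true amplitudes and latencies for every modality."""
    params = params or TruthParams()
    rng = np.random.default_rng(seed)
    n = len(schedule.trials)
    h = _habituation(params, n)
    plus = (schedule.conditions == CS_PLUS).astype(float)
    effect = 1.0 + params.delta_mean * plus

    def draw(base: float) -> np.ndarray:
        jitter = rng.lognormal(0.0, params.trial_jitter_sd, n)
        return base * h * effect * jitter

    ba = params.base_amplitude
    modalities = {
        "emg": ModalityTruth(amplitude=draw(ba["emg"])),
        "pupil": ModalityTruth(amplitude=draw(ba["pupil"])),
        "heart_period": ModalityTruth(amplitude=draw(ba["heart_period"])),
        "respiration": ModalityTruth(amplitude=draw(ba["respiration"])),
    }
    reinforced = np.array([t.us_onset is not None for t in schedule.trials])
    comp = {
        "cs": draw(ba["scr_cs"]),
        "trace": draw(ba["scr_trace"]),
        "us": np.where(reinforced, draw(ba["scr_us"]), 0.0),
    }
    latency = rng.uniform(8.5, 13.5, n)  # s after CS offset, inside trace window
    modalities["scr"] = ModalityTruth(
        amplitude=comp["trace"], components=comp, latency=latency
    )
    return GroundTruth(modalities=modalities, params=params, habituation=h)


# ---------------------------------------------------------------------------
# EMG
# ---------------------------------------------------------------------------

_PEAK_GAIN_CACHE: dict[float, float] = {}
_BURST_ENV_SD = 0.015  # s, Gaussian envelope of the blink burst
_BURST_CARRIER_HZ = 127.0


def _burst_waveform(fs: float) -> np.ndarray:
    """Deterministic unit blink burst: Gaussian-enveloped 127-Hz carrier."""
    half = 4.0 * _BURST_ENV_SD
    t = np.arange(-half, half + 0.5 / fs, 1.0 / fs)
    return np.exp(-0.5 * (t / _BURST_ENV_SD) ** 2) * np.sin(
        2.0 * np.pi * _BURST_CARRIER_HZ * t
    )


def _peak_gain(fs: float) -> float:
    """Scale factor so a unit-amplitude burst peak-scores as 1.

    Computed once per sampling rate by passing an isolated unit burst
    through the peak-scoring preprocessing chain.
    """
    if fs not in _PEAK_GAIN_CACHE:
        from .preprocess import emg_preprocess_peak

        pad = int(round(0.5 * fs))
        burst = _burst_waveform(fs)
        x = np.concatenate([np.zeros(pad), burst, np.zeros(pad)])
        env = emg_preprocess_peak(ContinuousSignal("emg", fs, x))
        _PEAK_GAIN_CACHE[fs] = 1.0 / float(np.max(env.samples))
    return _PEAK_GAIN_CACHE[fs]


def synth_emg(
    schedule: TrialSchedule,
    truth: GroundTruth,
    seed: int = 0,
    *,
    fs: float = 2000.0,
    mains_amplitude: float | None = None,
    latency_range: tuple[float, float] = (0.030, 0.080),
) -> ContinuousSignal:
    """Startle EMG: broadband baseline plus probe-locked blink bursts.

    The baseline is band-limited (50–470 Hz) Gaussian noise at the
    configured SD; each probe elicits a Gaussian-enveloped oscillatory
    burst at a latency drawn uniformly from ``latency_range``, scaled so
    that the peak-scoring chain recovers the trial's true amplitude.
    A 50-Hz mains component (default 10% of noise SD) exercises the notch.
    """
    if any(t.probe_onset is None for t in schedule.trials):
        raise ValueError("synth_emg requires probe onsets on every trial")
    rng = np.random.default_rng(seed)
    noise_sd = truth.params.noise_sd["emg"]
    if mains_amplitude is None:
        mains_amplitude = 0.1 * noise_sd
    n = int(np.ceil((schedule.trials[-1].nominal_us_onset + 20.0) * fs))
    if noise_sd > 0:
        white = rng.standard_normal(n)
        sos = sps.butter(4, (50.0, 470.0), btype="bandpass", fs=fs, output="sos")
        x = sps.sosfilt(sos, white)
        x *= noise_sd / np.std(x)
    else:
        x = np.zeros(n)
    if mains_amplitude:
        x += mains_amplitude * np.sin(2.0 * np.pi * 50.0 * np.arange(n) / fs)
    burst = _burst_waveform(fs) * _peak_gain(fs)
    half = len(burst) // 2
    amps = truth.modalities["emg"].amplitude
    for trial, amp in zip(schedule.trials, amps):
        lat = rng.uniform(*latency_range)
        c = int(round((trial.probe_onset + lat) * fs))
        x[c - half : c - half + len(burst)] += amp * burst
    return ContinuousSignal("emg", fs, x, None, "au")


# ---------------------------------------------------------------------------
# skin conductance
# ---------------------------------------------------------------------------

def synth_scr(
    schedule: TrialSchedule,
    truth: GroundTruth,
    seed: int = 0,
    *,
    fs: float = 100.0,
    model: ScrTrialModel | None = None,
    baseline_level: float = 2.0,
    drift_amplitude: float = 0.2,
    us_artifact_amplitude: float = 2.0,
) -> ContinuousSignal:
    """Skin conductance: drifting baseline plus per-trial sudomotor bursts.

    Bursts (CS-locked, trace-interval at the true latency, US-locked on
    reinforced trials) are unit-peak Gaussians convolved with the canonical
    conductance kernel — the same forward model the trial-model inversion
    assumes. Noise is band-limited (<2 Hz) Gaussian; a square stimulation
    artifact is injected over [US − 0.2 s, US + 1.6 s] when requested.
    """
    rng = np.random.default_rng(seed)
    model = model or ScrTrialModel()
    lags, shape = burst_response_shape(model)
    n = int(np.ceil((schedule.trials[-1].nominal_us_onset + 20.0) * fs))
    t = np.arange(n) / fs
    phase = rng.uniform(0, 2 * np.pi)
    x = baseline_level + drift_amplitude * np.sin(2 * np.pi * 0.002 * t + phase)
    m = truth.modalities["scr"]
    for k, trial in enumerate(schedule.trials):
        centers = {
            "cs": trial.cs_onset + model.delta_cs,
            "trace": trial.cs_offset + float(m.latency[k]),
            "us": trial.nominal_us_onset + model.delta_us,
        }
        for comp, mu in centers.items():
            a = float(m.components[comp][k])
            if a > 0:
                i0 = int(np.searchsorted(t, mu + lags[0]))
                i1 = int(np.searchsorted(t, mu + lags[-1]))
                x[i0:i1] += a * np.interp(t[i0:i1] - mu, lags, shape)
        if trial.us_onset is not None and us_artifact_amplitude:
            # electric pulse-train crosstalk: zero-mean fast oscillation
            art = (t >= trial.us_onset) & (t < trial.us_onset + 1.0)
            x[art] += us_artifact_amplitude * np.sign(
                np.sin(2 * np.pi * 41.5 * (t[art] - trial.us_onset))
            )
    noise_sd = truth.params.noise_sd["scr"]
    if noise_sd > 0:
        white = rng.standard_normal(n)
        sos = sps.butter(2, 2.0, btype="lowpass", fs=fs, output="sos")
        nz = sps.sosfilt(sos, white)
        x += noise_sd / np.std(nz) * nz
    return ContinuousSignal("scr", fs, x, None, "uS")


# ---------------------------------------------------------------------------
# pupil + gaze
# ---------------------------------------------------------------------------

def synth_pupil(
    schedule: TrialSchedule,
    truth: GroundTruth,
    seed: int = 0,
    *,
    fs: float = 500.0,
    baseline_mm: float = 4.0,
    blink_rate_per_min: float = 8.0,
    blink_duration: tuple[float, float] = (0.1, 0.3),
    excursion_rate_per_min: float = 1.0,
    excursion_duration: tuple[float, float] = (0.5, 2.0),
    excursion_deg: tuple[float, float] = (6.0, 10.0),
    gaze_noise_deg: float = 0.3,
    eye_noise_sd: float = 0.01,
) -> tuple[ContinuousSignal, ContinuousSignal, ContinuousSignal, ContinuousSignal]:
    """Binocular pupil diameter and gaze with injected artifacts.

    Both eyes share a common signal (baseline drift + CS-locked dilation
    kernel scaled by the per-trial truth + smooth noise) plus independent
    per-eye noise. Artifacts: blinks (diameter drops to 0 with fast ramps),
    and gaze excursions beyond the ±5° fixation limit.
    """
    rng = np.random.default_rng(seed)
    n = int(np.ceil((schedule.trials[-1].nominal_us_onset + 20.0) * fs))
    t = np.arange(n) / fs
    common = baseline_mm + 0.15 * np.sin(2 * np.pi * t / 120.0 + rng.uniform(0, 2 * np.pi))
    rf = canonical_rf("pupil_canonical", 10.0).resample(fs)
    amps = truth.modalities["pupil"].amplitude
    for trial, a in zip(schedule.trials, amps):
        i0 = int(round(trial.cs_onset * fs))
        j1 = min(n, i0 + len(rf.values))
        common[i0:j1] += a * rf.values[: j1 - i0]
    noise_sd = truth.params.noise_sd["pupil"]
    if noise_sd > 0:
        sos = sps.butter(2, 2.0, btype="lowpass", fs=fs, output="sos")
        nz = sps.sosfilt(sos, rng.standard_normal(n))
        common += noise_sd / np.std(nz) * nz

    def one_eye() -> np.ndarray:
        d = common + eye_noise_sd * rng.standard_normal(n)
        n_blinks = rng.poisson(blink_rate_per_min * t[-1] / 60.0)
        for _ in range(n_blinks):
            dur = rng.uniform(*blink_duration)
            c = rng.uniform(0, t[-1] - dur)
            i0, i1 = int(c * fs), int((c + dur) * fs)
            ramp = max(1, int(0.02 * fs))
            d[i0:i1] = 0.0
            d[max(0, i0 - ramp) : i0] *= np.linspace(1, 0, min(ramp, i0))
            d[i1 : i1 + ramp] *= np.linspace(0, 1, min(ramp, n - i1))
        return d

    pl = one_eye()
    pr = one_eye()
    gx = gaze_noise_deg * rng.standard_normal(n)
    gy = gaze_noise_deg * rng.standard_normal(n)
    n_exc = rng.poisson(excursion_rate_per_min * t[-1] / 60.0)
    for _ in range(n_exc):
        dur = rng.uniform(*excursion_duration)
        c = rng.uniform(0, t[-1] - dur)
        i0, i1 = int(c * fs), int((c + dur) * fs)
        gx[i0:i1] += rng.choice([-1, 1]) * rng.uniform(*excursion_deg)
    return (
        ContinuousSignal("pupil_l", fs, pl, None, "mm"),
        ContinuousSignal("pupil_r", fs, pr, None, "mm"),
        ContinuousSignal("gaze_x", fs, gx, None, "deg"),
        ContinuousSignal("gaze_y", fs, gy, None, "deg"),
    )


# ---------------------------------------------------------------------------
# ECG
# ---------------------------------------------------------------------------

def synth_ecg(
    schedule: TrialSchedule,
    truth: GroundTruth,
    seed: int = 0,
    *,
    fs: float = 500.0,
    base_period_s: float = 0.8,
    rsa_amplitude_s: float = 0.015,
    noise_sd: float | None = None,
    anomalies: list[tuple[float, float]] | None = None,
    clip_period: bool = True,
) -> ContinuousSignal:
    """Synthetic ECG: QRS-like impulse train with modulated heart period.

    The instantaneous heart period is a baseline plus respiratory sinus
    arrhythmia plus a US-locked bradycardia kernel scaled by the per-trial
    truth (seconds of period lengthening). Beat times integrate the period;
    each beat places a biphasic ~40-ms QRS wavelet. ``anomalies`` is a list
    of (time, ibi_s) forcing one inter-beat interval of the given length —
    e.g. an ectopic pause — and disables period clipping at those beats.
    """
    rng = np.random.default_rng(seed)
    dur = schedule.trials[-1].nominal_us_onset + 20.0
    grid = np.arange(0.0, dur, 0.1)
    period = base_period_s + rsa_amplitude_s * np.sin(2 * np.pi * 0.25 * grid)
    rf = canonical_rf("hpr_us_locked", 10.0)
    for trial, a in zip(schedule.trials, truth.modalities["heart_period"].amplitude):
        i0 = int(round(trial.nominal_us_onset * 10))
        j1 = min(len(grid), i0 + len(rf.values))
        period[i0:j1] += a * rf.values[: j1 - i0]
    if clip_period:
        period = np.clip(period, 0.62, 1.18)

    anomalies = sorted(anomalies or [])
    beats = [0.3]
    while beats[-1] < dur - 1.5:
        tcur = beats[-1]
        if anomalies and tcur >= anomalies[0][0]:
            beats.append(tcur + anomalies.pop(0)[1])
            continue
        beats.append(tcur + float(np.interp(tcur, grid, period)))
    beat_times = np.array(beats)

    n = int(np.ceil(dur * fs)) + 1
    x = np.zeros(n)
    # QRS-like Ricker wavelet: dominant R deflection at the beat time
    tw = np.arange(-0.04, 0.04, 1.0 / fs)
    qrs = (1.0 - (tw / 0.01) ** 2) * np.exp(-0.5 * (tw / 0.01) ** 2)
    qrs /= np.max(np.abs(qrs))
    half = len(qrs) // 2
    for bt in beat_times:
        i0 = int(round(bt * fs)) - half
        j0, j1 = max(i0, 0), min(i0 + len(qrs), n)
        x[j0:j1] += qrs[j0 - i0 : j1 - i0]
    sd = truth.params.noise_sd["heart_period"] if noise_sd is None else noise_sd
    if sd > 0:
        x += sd * rng.standard_normal(n)
    return ContinuousSignal("ecg", fs, x, None, "au")


# ---------------------------------------------------------------------------
# respiration
# ---------------------------------------------------------------------------

def synth_respiration(
    schedule: TrialSchedule,
    truth: GroundTruth,
    seed: int = 0,
    *,
    fs: float = 100.0,
    period_s: float = 4.0,
    base_amplitude: float = 1.0,
    period_drift: float = 0.0,
) -> ContinuousSignal:
    """Quasi-sinusoidal belt signal with cycle-amplitude modulation.

    ``base_amplitude`` is the unmodulated peak-to-trough cycle amplitude;
    per-trial truth scales it through a US-locked kernel (relative change).
    """
    rng = np.random.default_rng(seed)
    dur = schedule.trials[-1].nominal_us_onset + 20.0
    n = int(np.ceil(dur * fs)) + 1
    t = np.arange(n) / fs
    period = period_s + period_drift * np.sin(2 * np.pi * t / 97.0)
    phase = np.cumsum(2 * np.pi / (period * fs))
    # physiological modulation kernel (instantaneous depth change, ~2 s
    # peak); the derived cycle-amplitude series lags it by ~1 cycle
    kgrid = np.arange(0.0, 10.0, 1.0 / fs)
    kern = stats_gamma_pdf(kgrid, mode=2.0, shape=4.0)
    kern /= kern.max()
    mod = np.zeros(n)
    for trial, a in zip(schedule.trials, truth.modalities["respiration"].amplitude):
        i0 = int(round(trial.nominal_us_onset * fs))
        j1 = min(n, i0 + len(kern))
        mod[i0:j1] += a * kern[: j1 - i0]
    amp = np.clip(base_amplitude * (1.0 + mod), 0.05, None)
    x = 0.5 * amp * np.sin(phase)
    sd = truth.params.noise_sd["respiration"]
    if sd > 0:
        x += sd * rng.standard_normal(n)
    return ContinuousSignal("respiration", fs, x, None, "au")


# ---------------------------------------------------------------------------
# sessions and cohorts
# ---------------------------------------------------------------------------

ALL_MODALITIES = ("emg", "scr", "pupil", "ecg", "respiration")


def synth_session(
    session: str,
    seed: int,
    *,
    modalities: tuple[str, ...] = ALL_MODALITIES,
    params: TruthParams | None = None,
    subject_id: str = "s0",
) -> SessionDataset:
    """One subject's full session: schedule, ground truth, and signals."""
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(8)
    schedule = generate_schedule(session, int(seeds[0]) % 2**31)
    truth = make_ground_truth(schedule, params, int(seeds[1]) % 2**31)
    signals: dict[str, ContinuousSignal] = {}
    if "emg" in modalities and session == "recall":
        signals["emg"] = synth_emg(schedule, truth, int(seeds[2]) % 2**31)
    if "scr" in modalities:
        signals["scr"] = synth_scr(schedule, truth, int(seeds[3]) % 2**31)
    if "pupil" in modalities:
        pl, pr, gx, gy = synth_pupil(schedule, truth, int(seeds[4]) % 2**31)
        signals.update({"pupil_l": pl, "pupil_r": pr, "gaze_x": gx, "gaze_y": gy})
    if "ecg" in modalities:
        signals["ecg"] = synth_ecg(schedule, truth, int(seeds[5]) % 2**31)
    if "respiration" in modalities:
        signals["respiration"] = synth_respiration(
            schedule, truth, int(seeds[6]) % 2**31
        )
    return SessionDataset(schedule, signals, truth, subject_id)


def synth_cohort_iter(
    n_subjects: int,
    session: str,
    seed: int,
    *,
    modalities: tuple[str, ...] = ALL_MODALITIES,
    params: TruthParams | None = None,
    subject_scale_sd: float = 0.4,
):
    """Lazily yield cohort subjects (memory-light for large cohorts)."""
    params = params or TruthParams()
    ss = np.random.SeedSequence(seed)
    subj_seeds = ss.generate_state(n_subjects + 1)
    rng = np.random.default_rng(int(subj_seeds[-1]) % 2**31)
    for i in range(n_subjects):
        scale = float(rng.lognormal(0.0, subject_scale_sd))
        p = replace(
            params,
            base_amplitude={k: v * scale for k, v in params.base_amplitude.items()},
        )
        yield synth_session(
            session,
            int(subj_seeds[i]) % 2**31,
            modalities=modalities,
            params=p,
            subject_id=f"s{i:03d}",
        )


def synth_cohort(
    n_subjects: int,
    session: str,
    seed: int,
    *,
    modalities: tuple[str, ...] = ALL_MODALITIES,
    params: TruthParams | None = None,
    subject_scale_sd: float = 0.4,
) -> list[SessionDataset]:
    """A cohort with log-normal between-subject response scaling."""
    return list(
        synth_cohort_iter(
            n_subjects, session, seed,
            modalities=modalities, params=params,
            subject_scale_sd=subject_scale_sd,
        )
    )


# ---------------------------------------------------------------------------
# estimate-level and null generators for the statistics layer
# ---------------------------------------------------------------------------

def delta_for_target_d(
    d_target: float, between_sd: float, within_sd: float, n_avg: int
) -> float:
    """Mean CS+/CS− difference yielding a population effect size ``d_target``
    for the ``n_avg``-trial average (paired d on subject condition-means).

    With subject effects u_i ~ N(δ, σ_b²) and trial noise σ_w², the SD of
    the subject mean difference is sqrt(σ_b² + 2 σ_w²/n_avg).
    """
    return d_target * float(np.sqrt(between_sd**2 + 2 * within_sd**2 / n_avg))


def synth_estimate_cohort(
    n_subjects: int,
    n_trials_per_cond: int,
    seed: int,
    *,
    delta: float = 0.5,
    between_sd: float = 0.5,
    within_sd: float = 0.5,
    habituation_lambda: float = 0.0,
    subject_scale_sd: float = 0.4,
    modality: str = "sebr",
    method: str = "peak",
    session: str = "recall",
):
    """Raw (un-normalized) trial-estimate table for a simulated cohort.

    Direct generation at the estimate level — bypassing signal synthesis —
    for statistical calibration studies. Subject i has gain s_i (log-normal)
    and conditioned effect u_i ~ N(delta, between_sd²); trial t of condition
    c yields amplitude s_i · h_t · (1 + u_i·[CS+] + ε), ε ~ N(0, within_sd²),
    with h_t the exponential habituation factor in presentation order.
    """
    import pandas as pd

    from .respquant import ESTIMATE_COLUMNS  # noqa: F401  (schema reference)

    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        s_i = rng.lognormal(0.0, subject_scale_sd)
        u_i = rng.normal(delta, between_sd)
        order = generate_schedule(
            session, int(rng.integers(2**31)), n_per_condition=n_trials_per_cond
        ).conditions
        h = np.exp(-habituation_lambda * np.arange(len(order)))
        eps = rng.normal(0.0, within_sd, len(order))
        for t, (cond, ht, e) in enumerate(zip(order, h, eps), start=1):
            amp = s_i * ht * (1.0 + (u_i if cond == CS_PLUS else 0.0) + e)
            rows.append(
                {
                    "subject": f"s{i:03d}",
                    "session": session,
                    "trial_index": t,
                    "condition": cond,
                    "modality": modality,
                    "method": method,
                    "component": "probe",
                    "amplitude": amp,
                    "latency": np.nan,
                    "normalized": False,
                    "flag": "",
                }
            )
    return pd.DataFrame(rows)


def synth_null_timecourses(
    n_subjects: int,
    n_trials: int,
    n_timepoints: int,
    seed: int,
    *,
    smooth_sd: float = 3.0,
):
    """Exchangeable null time courses for permutation-test calibration.

    Trials are i.i.d. smooth (Gaussian-filtered white noise) curves within
    each subject; condition labels are balanced and carry no information.
    Returns (data[n_subjects, n_trials, n_timepoints], labels[n_subjects,
    n_trials] bool CS+).
    """
    from scipy.ndimage import gaussian_filter1d

    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_subjects, n_trials, n_timepoints))
    if smooth_sd > 0:
        data = gaussian_filter1d(data, smooth_sd, axis=-1)
    labels = np.zeros((n_subjects, n_trials), dtype=bool)
    half = n_trials // 2
    for s in range(n_subjects):
        idx = rng.permutation(n_trials)[:half]
        labels[s, idx] = True
    return data, labels
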