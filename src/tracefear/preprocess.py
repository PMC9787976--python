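"""Per-modality preprocessing chains.

Each chain turns a raw :class:`~tracefear.signals.ContinuousSignal` into an
analysis-ready series:

- EMG (two variants): band-pass / high-pass Butterworth filtering, 50-Hz
  notch, rectification, and smoothing — producing the envelope scored or
  regressed for startle eyeblinks.
- Skin conductance: causal first-order band-pass (0.0159–5 Hz), decimation
  to 10 Hz, and masking of the electric-stimulation artifact window.
- Pupil: validity filtering (range, speed, edge, trendline, isolated
  samples), binocular combination, gaze-based masking, interpolation and
  1-s smoothing, and per-trial exclusion bookkeeping.
- ECG: Pan–Tompkins-style QRS detection, inter-beat-interval screening
  (600–1200 ms), 10-Hz interpolation, zero-phase band-pass.
- Respiration: inspiration-cycle detection and cycle-amplitude series.

All filters are Butterworth designs applied as second-order sections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .design import TrialSchedule
from .signals import ContinuousSignal

log = logging.getLogger(__name__)

#: EMG quality-control chain (GLM route) band edges, Hz
EMG_BAND = (50.0, 470.0)
#: first-order-equivalent cutoff of a 3-ms smoothing time constant, Hz
EMG_SMOOTH_CUTOFF = 1.0 / (2.0 * np.pi * 0.003)
#: notch frequency and quality factor for mains removal
NOTCH_FREQ, NOTCH_Q = 50.0, 35.0
#: accepted inter-beat-interval range, ms
IBI_RANGE_MS = (600.0, 1200.0)


# ---------------------------------------------------------------------------
# filter designs (exposed so tests can verify them against a reference)
# ---------------------------------------------------------------------------

def design_emg_bandpass(fs: float) -> np.ndarray:
    return sps.butter(4, EMG_BAND, btype="bandpass", fs=fs, output="sos")

def design_emg_highpass(fs: float) -> np.ndarray:
    return sps.butter(4, 30.0, btype="highpass", fs=fs, output="sos")

def design_notch(fs: float) -> np.ndarray:
    b, a = sps.iirnotch(NOTCH_FREQ, NOTCH_Q, fs=fs)
    return sps.tf2sos(b, a)

def design_emg_smoother(fs: float) -> np.ndarray:
    return sps.butter(4, EMG_SMOOTH_CUTOFF, btype="lowpass", fs=fs, output="sos")

def design_scr_bandpass(fs: float) -> np.ndarray:
    return sps.butter(1, (0.0159, 5.0), btype="bandpass", fs=fs, output="sos")

def design_antialias(fs: float, cutoff: float = 4.0) -> np.ndarray:
    return sps.butter(4, cutoff, btype="lowpass", fs=fs, output="sos")

def design_heart_period_bandpass(fs: float = 10.0) -> np.ndarray:
    return sps.butter(4, (0.015, 0.5), btype="bandpass", fs=fs, output="sos")

def design_respiration_detrend(fs: float) -> np.ndarray:
    return sps.butter(2, (0.04, 1.0), btype="bandpass", fs=fs, output="sos")


# ---------------------------------------------------------------------------
# EMG
# ---------------------------------------------------------------------------

def emg_preprocess_glm(emg: ContinuousSignal) -> ContinuousSignal:
    """EMG envelope for GLM-based startle quantification.

    Band-pass 50–470 Hz (4th order) → 50-Hz notch → rectification →
    4th-order low-pass with a 3-ms time constant (cutoff 1/(2πτ) ≈ 53 Hz).
    """
    fs = emg.sampling_rate
    if fs < 2 * EMG_BAND[1]:
        raise ValueError(f"sampling rate {fs} Hz below 2x{EMG_BAND[1]} Hz")
    y = sps.sosfilt(design_emg_bandpass(fs), emg.samples)
    y = sps.sosfilt(design_notch(fs), y)
    y = sps.sosfilt(design_emg_smoother(fs), np.abs(y))
    return ContinuousSignal("emg", fs, y, emg.missing_mask.copy(), emg.units)


def emg_preprocess_peak(emg: ContinuousSignal) -> ContinuousSignal:
    """EMG envelope for peak scoring.

    High-pass 30 Hz (4th order) → 50-Hz notch → rectification → centered
    20-ms moving average.
    """
    fs = emg.sampling_rate
    y = sps.sosfilt(design_emg_highpass(fs), emg.samples)
    y = sps.sosfilt(design_notch(fs), y)
    w = max(1, int(round(0.020 * fs)))
    y = np.convolve(np.abs(y), np.ones(w) / w, mode="same")
    return ContinuousSignal("emg", fs, y, emg.missing_mask.copy(), emg.units)


# ---------------------------------------------------------------------------
# skin conductance
# ---------------------------------------------------------------------------

def scr_preprocess(
    scr: ContinuousSignal,
    schedule: TrialSchedule | None = None,
    *,
    target_fs: float = 10.0,
    us_mask: tuple[float, float] = (0.2, 1.6),
) -> ContinuousSignal:
    """Filter, decimate to 10 Hz, and mask the US stimulation artifact.

    A causal (forward-only) first-order 0.0159–5 Hz band-pass, an
    anti-aliasing low-pass at 4 Hz, then subsampling onto the 10-Hz grid.
    For every reinforced trial, samples with ``us_onset - 0.2 <= t <
    us_onset + 1.6`` (seconds) are marked missing.
    """
    fs = scr.sampling_rate
    step = fs / target_fs
    if abs(step - round(step)) > 1e-9:
        raise ValueError("sampling rate must be an integer multiple of 10 Hz")
    y = sps.sosfilt(design_scr_bandpass(fs), scr.samples)
    if fs > target_fs:
        y = sps.sosfilt(design_antialias(fs), y)
        y = y[:: int(round(step))]
    mask = np.zeros(len(y), dtype=bool)
    if schedule is not None:
        t = np.arange(len(y)) / target_fs
        for trial in schedule.trials:
            if trial.us_onset is not None:
                mask |= (t >= trial.us_onset - us_mask[0] - 1e-9) & (
                    t < trial.us_onset + us_mask[1] - 1e-9
                )
    return ContinuousSignal("scr", target_fs, y, mask, scr.units)


# ---------------------------------------------------------------------------
# pupil
# ---------------------------------------------------------------------------

@dataclass
class PupilConfig:
    """Validity-filter settings for pupil preprocessing.

    Defaults follow common dilation-speed / range filtering practice:
    samples outside a plausible diameter range, faster than a robust
    (median + ``speed_n_mad`` * MAD) dilation-speed threshold, near gap
    edges, far from a smooth trendline, or in very short valid islands are
    rejected before interpolation.
    """

    range_mm: tuple[float, float] = (1.5, 9.0)
    speed_n_mad: float = 16.0
    gap_min_s: float = 0.075
    gap_pad_s: float = 0.05
    island_min_s: float = 0.05
    trend_window_s: float = 0.3
    trend_n_mad: float = 16.0
    trend_passes: int = 2
    gaze_limit_deg: float = 5.0
    smooth_width_s: float = 1.0
    exclude_missing_frac: float = 0.5


@dataclass
class PupilSeries:
    """Preprocessed binocular pupil diameter with exclusion bookkeeping."""

    sampling_rate: float
    diameter: np.ndarray          # combined, NaN where missing
    missing_mask: np.ndarray
    smoothed: np.ndarray          # interpolated + 1-s moving average
    trial_missing_frac: np.ndarray
    trial_excluded: np.ndarray
    units: str = "mm"

    def to_signal(self, target_fs: float = 10.0) -> ContinuousSignal:
        """Interpolated-and-smoothed series resampled to ``target_fs``."""
        step = self.sampling_rate / target_fs
        if abs(step - round(step)) > 1e-9:
            raise ValueError("sampling rate must be an integer multiple of target")
        y = self.smoothed[:: int(round(step))]
        m = self.missing_mask[:: int(round(step))]
        return ContinuousSignal("pupil", target_fs, y, m & False, self.units)


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    """Centered moving average with edge renormalization (no zero-padding
    bias at the boundaries)."""
    if w <= 1:
        return x.copy()
    num = np.convolve(x, np.ones(w), mode="same")
    den = np.convolve(np.ones(len(x)), np.ones(w), mode="same")
    return num / den


def _mad_threshold(x: np.ndarray, n_mad: float) -> float:
    if not np.any(np.isfinite(x)):
        return np.nan
    med = np.nanmedian(x)
    mad = np.nanmedian(np.abs(x - med))
    return float(med + n_mad * mad)


def _reject_short_runs(valid: np.ndarray, min_len: int) -> np.ndarray:
    """Invalidate valid islands shorter than ``min_len`` samples."""
    v = valid.copy()
    padded = np.concatenate(([False], v, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    for s, e in zip(starts, ends):
        if e - s < min_len:
            v[s:e] = False
    return v


def _pad_gaps(valid: np.ndarray, fs: float, gap_min_s: float, pad_s: float) -> np.ndarray:
    """Invalidate samples bordering gaps longer than ``gap_min_s``."""
    v = valid.copy()
    pad = int(round(pad_s * fs))
    gap_min = int(round(gap_min_s * fs))
    padded = np.concatenate(([True], v, [True]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == -1)  # gap starts
    ends = np.flatnonzero(d == 1)     # gap ends
    for s, e in zip(starts, ends):
        if e - s >= gap_min:
            v[max(0, s - pad) : s] = False
            v[e : e + pad] = False
    return v


def _valid_mask_one_eye(d: np.ndarray, fs: float, cfg: PupilConfig) -> np.ndarray:
    valid = np.isfinite(d) & (d >= cfg.range_mm[0]) & (d <= cfg.range_mm[1])
    # dilation speed: max absolute slope to either neighbor
    dd = np.abs(np.diff(d)) * fs
    speed = np.full(len(d), 0.0)
    speed[1:] = dd
    speed[:-1] = np.maximum(speed[:-1], dd)
    with np.errstate(invalid="ignore"):
        thr = _mad_threshold(np.where(valid, speed, np.nan), cfg.speed_n_mad)
        if np.isfinite(thr) and thr > 0:
            valid &= ~(speed > thr)
    valid = _pad_gaps(valid, fs, cfg.gap_min_s, cfg.gap_pad_s)
    # trendline filter: deviation from a smooth trend of the valid samples
    for _ in range(cfg.trend_passes):
        if valid.sum() < 10:
            break
        idx = np.arange(len(d))
        interp = np.interp(idx, idx[valid], d[valid])
        trend = _moving_average(interp, max(1, int(round(cfg.trend_window_s * fs))))
        dev = np.abs(d - trend)
        thr = _mad_threshold(np.where(valid, dev, np.nan), cfg.trend_n_mad)
        if not np.isfinite(thr) or thr <= 0:
            break
        new_valid = valid & ~(dev > thr)
        if new_valid.sum() == valid.sum():
            break
        valid = new_valid
    valid = _reject_short_runs(valid, int(round(cfg.island_min_s * fs)))
    return valid


def pupil_preprocess(
    pupil_l: ContinuousSignal,
    pupil_r: ContinuousSignal,
    gaze_x: ContinuousSignal,
    gaze_y: ContinuousSignal,
    schedule: TrialSchedule | None = None,
    config: PupilConfig | None = None,
) -> PupilSeries:
    """Validity-filter, combine, and smooth binocular pupil data.

    Applies, per eye: range, speed, edge (gap padding), trendline, and
    isolated-sample filters; combines eyes by averaging valid samples
    (falling back to the valid eye); marks samples with gaze eccentricity
    beyond ±5° visual angle missing; linearly interpolates and smooths with
    a 1-s moving average for time-course analysis; and computes per-trial
    missing fractions (CS onset to nominal US), excluding trials with
    strictly more than 50% missing.
    """
    cfg = config or PupilConfig()
    fs = pupil_l.sampling_rate
    dl, dr = pupil_l.samples, pupil_r.samples
    vl = _valid_mask_one_eye(dl, fs, cfg) & ~pupil_l.missing_mask
    vr = _valid_mask_one_eye(dr, fs, cfg) & ~pupil_r.missing_mask

    combined = np.full(len(dl), np.nan)
    both = vl & vr
    combined[both] = 0.5 * (dl[both] + dr[both])
    only_l = vl & ~vr
    only_r = vr & ~vl
    combined[only_l] = dl[only_l]
    combined[only_r] = dr[only_r]

    ecc = np.hypot(gaze_x.samples, gaze_y.samples)
    off_screen = ecc > cfg.gaze_limit_deg
    combined[off_screen] = np.nan
    missing = ~np.isfinite(combined)

    if missing.all():
        smoothed = np.full(len(combined), np.nan)
    else:
        idx = np.arange(len(combined))
        interp = np.interp(idx, idx[~missing], combined[~missing])
        smoothed = _moving_average(interp, max(1, int(round(cfg.smooth_width_s * fs))))

    n_trials = len(schedule.trials) if schedule is not None else 0
    frac = np.zeros(n_trials)
    excluded = np.zeros(n_trials, dtype=bool)
    if schedule is not None:
        for k, trial in enumerate(schedule.trials):
            i0 = int(round(trial.cs_onset * fs))
            i1 = int(round(trial.nominal_us_onset * fs))
            frac[k] = float(np.mean(missing[i0:i1])) if i1 > i0 else 1.0
            excluded[k] = frac[k] > cfg.exclude_missing_frac
        if excluded.any():
            log.info("pupil: %d/%d trials excluded (>50%% missing)",
                     int(excluded.sum()), n_trials)
    return PupilSeries(
        sampling_rate=fs,
        diameter=combined,
        missing_mask=missing,
        smoothed=smoothed,
        trial_missing_frac=frac,
        trial_excluded=excluded,
    )


# ---------------------------------------------------------------------------
# ECG -> heart period
# ---------------------------------------------------------------------------

@dataclass
class HeartPeriodSeries:
    """Heart period interpolated on a 10-Hz grid.

    ``period_ms`` is the linearly interpolated inter-beat interval series;
    ``filtered`` is the same series after the 4th-order zero-phase
    0.015–0.5 Hz band-pass (fluctuation around zero). Only IBIs within
    600–1200 ms contribute.
    """

    times: np.ndarray
    period_ms: np.ndarray
    filtered: np.ndarray
    beat_times: np.ndarray = field(default_factory=lambda: np.array([]))
    n_accepted: int = 0
    n_rejected: int = 0
    sampling_rate: float = 10.0

    def to_signal(self, filtered: bool = True) -> ContinuousSignal:
        y = self.filtered if filtered else self.period_ms
        sig = ContinuousSignal("heart_period", self.sampling_rate, y, None, "ms")
        return sig


def detect_r_peaks(ecg: ContinuousSignal, *, refractory_s: float = 0.2,
                   integration_window_s: float = 0.150) -> np.ndarray:
    """Pan–Tompkins-style offline QRS detection; returns R times (s).

    Band-pass (5–15 Hz) → derivative → squaring → moving-window integration
    (150 ms) → adaptive signal/noise thresholds with 200-ms refractory
    period and search-back at half threshold for missed beats. R times are
    refined to the local maximum of the band-passed signal magnitude.
    """
    fs = ecg.sampling_rate
    x = ecg.samples
    bp = sps.sosfiltfilt(sps.butter(2, (5.0, 15.0), btype="bandpass", fs=fs,
                                    output="sos"), x)
    deriv = np.gradient(bp) * fs
    sq = deriv**2
    w = max(1, int(round(integration_window_s * fs)))
    mwi = np.convolve(sq, np.ones(w) / w, mode="same")

    refr = int(round(refractory_s * fs))
    # candidate peaks of the integrated signal
    cand, _ = sps.find_peaks(mwi, distance=refr)
    if len(cand) == 0:
        raise ValueError("no QRS candidates detected")
    spki = float(np.percentile(mwi[cand], 75))
    npki = float(np.percentile(mwi[cand], 25))
    accepted: list[int] = []
    missed_limit = None
    for i, c in enumerate(cand):
        thr = npki + 0.25 * (spki - npki)
        if mwi[c] > thr:
            accepted.append(c)
            spki = 0.125 * mwi[c] + 0.875 * spki
        else:
            npki = 0.125 * mwi[c] + 0.875 * npki
        # search-back: if the gap since the last beat exceeds 1.66x the
        # running RR average, accept the largest candidate above thr/2
        if len(accepted) >= 3:
            rr = np.diff(accepted[-9:])
            rr_avg = float(np.mean(rr))
            missed_limit = 1.66 * rr_avg
            if i + 1 < len(cand) and cand[i + 1] - accepted[-1] > missed_limit:
                seg = [j for j in cand if accepted[-1] < j < cand[i + 1]
                       and mwi[j] > thr / 2 and j - accepted[-1] > refr]
                if seg:
                    best = max(seg, key=lambda j: mwi[j])
                    accepted.append(best)
                    spki = 0.25 * mwi[best] + 0.75 * spki
    accepted_arr = np.array(sorted(set(accepted)), dtype=int)
    # refine to the dominant deflection of the raw complex (the R wave)
    half = int(round(0.050 * fs))
    centered = x - np.median(x)
    refined = []
    for c in accepted_arr:
        lo, hi = max(0, c - half), min(len(centered), c + half + 1)
        refined.append(lo + int(np.argmax(np.abs(centered[lo:hi]))))
    return np.unique(np.array(refined)) / fs


def ecg_to_heart_period(
    ecg: ContinuousSignal, *, target_fs: float = 10.0
) -> HeartPeriodSeries:
    """QRS detection, IBI screening, interpolation and band-pass filtering.

    Inter-beat intervals are assigned to the later beat of each pair,
    rejected outside 600–1200 ms, linearly interpolated onto a 10-Hz grid
    spanning the detected beats, and band-pass filtered (0.015–0.5 Hz,
    4th order, zero-phase).
    """
    beats = detect_r_peaks(ecg)
    if len(beats) < 2:
        raise ValueError("fewer than 2 detected beats")
    ibi_ms = np.diff(beats) * 1000.0
    t_assign = beats[1:]  # assigned to the later beat
    ok = (ibi_ms >= IBI_RANGE_MS[0]) & (ibi_ms <= IBI_RANGE_MS[1])
    n_rej = int((~ok).sum())
    if ok.sum() < 2:
        raise ValueError("fewer than 2 accepted inter-beat intervals")
    # grid from t=0 so downstream event-locked models share the time base;
    # values outside the detected beats are held at the edge values
    grid = np.arange(0.0, beats[-1], 1.0 / target_fs)
    period = np.interp(grid, t_assign[ok], ibi_ms[ok])
    filt = sps.sosfiltfilt(design_heart_period_bandpass(target_fs), period)
    if n_rej:
        log.info("heart period: rejected %d/%d IBIs", n_rej, len(ibi_ms))
    return HeartPeriodSeries(
        times=grid,
        period_ms=period,
        filtered=filt,
        beat_times=beats,
        n_accepted=int(ok.sum()),
        n_rejected=n_rej,
        sampling_rate=target_fs,
    )


# ---------------------------------------------------------------------------
# respiration -> cycle amplitude
# ---------------------------------------------------------------------------

@dataclass
class RespirationAmplitudeSeries:
    """Respiratory cycle amplitude interpolated on a 10-Hz grid."""

    times: np.ndarray
    amplitude: np.ndarray
    cycle_onsets: np.ndarray
    cycle_amplitudes: np.ndarray
    sampling_rate: float = 10.0

    def to_signal(self) -> ContinuousSignal:
        return ContinuousSignal(
            "respiration_amplitude", self.sampling_rate, self.amplitude, None, ""
        )


def respiration_to_amplitude(
    resp: ContinuousSignal, *, target_fs: float = 10.0
) -> RespirationAmplitudeSeries:
    """Cycle-amplitude series from the respiration belt signal.

    Inspiration onsets are positive-going zero crossings of the band-limited
    (0.04–1 Hz) detrended signal; each cycle's amplitude (max − min of the
    detrended signal within the cycle) is assigned to the *next* cycle's
    onset and linearly interpolated at 10 Hz. No further filtering.
    """
    fs = resp.sampling_rate
    y = sps.sosfiltfilt(design_respiration_detrend(fs), resp.samples)
    pos = y > 0
    onsets_idx = np.flatnonzero(~pos[:-1] & pos[1:]) + 1
    if len(onsets_idx) < 3:
        raise ValueError("fewer than 3 respiratory cycles detected")
    onsets_t = onsets_idx / fs
    amps = np.array(
        [
            float(np.max(y[s:e]) - np.min(y[s:e]))
            for s, e in zip(onsets_idx[:-1], onsets_idx[1:])
        ]
    )
    # amplitude of cycle k assigned to onset of cycle k+1; grid from t=0
    # (edge-held) so event-locked models share the time base
    t_assign = onsets_t[1:]
    grid = np.arange(0.0, len(resp.samples) / fs, 1.0 / target_fs)
    series = np.interp(grid, t_assign, amps)
    return RespirationAmplitudeSeries(
        times=grid,
        amplitude=series,
        cycle_onsets=onsets_t,
        cycle_amplitudes=amps,
        sampling_rate=target_fs,
    )
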