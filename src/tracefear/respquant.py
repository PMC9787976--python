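"""Trial-wise response quantification.

Forward response models (canonical or data-fitted kernels), their inversion
(peak scoring, GLM, constrained nonlinear least squares for the SCR trial
model), and CS−-mean normalization. Estimates are exchanged as tidy pandas
DataFrames with one row per subject × trial × component × method (see
``ESTIMATE_COLUMNS``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .design import CS_MINUS, CS_PLUS, TrialSchedule
from .signals import ContinuousSignal

ESTIMATE_COLUMNS = [
    "subject",
    "session",
    "trial_index",
    "condition",
    "modality",
    "method",
    "component",
    "amplitude",
    "latency",
    "normalized",
    "flag",
]


@dataclass
class ResponseFunction:
    """A discretized response kernel used as a GLM regressor.

    ``values`` is peak-normalized (max |values| = 1) on the uniform time
    grid ``grid`` (seconds from kernel onset).
    """

    kind: str
    grid: np.ndarray
    values: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape:
            raise ValueError("grid and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite kernel values")
        m = np.max(np.abs(self.values))
        if m == 0:
            raise ValueError("all-zero kernel")
        if not np.isclose(m, 1.0):
            self.values = self.values / m

    @property
    def sampling_rate(self) -> float:
        return 1.0 / (self.grid[1] - self.grid[0])

    def resample(self, fs: float) -> "ResponseFunction":
        grid = np.arange(0.0, self.grid[-1] + 0.5 / fs, 1.0 / fs)
        vals = np.interp(grid, self.grid, self.values)
        return ResponseFunction(self.kind, grid, vals, dict(self.params))


def _gamma_kernel(grid: np.ndarray, mode: float, shape: float) -> np.ndarray:
    scale = mode / (shape - 1.0)
    return stats.gamma.pdf(grid, shape, scale=scale)


def canonical_rf(kind: str, fs: float | None = None) -> ResponseFunction:
    """Parametric default response functions.

    kind:
      - ``sebr_canonical``: gamma density peaking ~45 ms after blink onset,
        ~25 ms wide (startle eyeblink EMG envelope).
      - ``scr_kernel``: Bateman-type difference of exponentials (rise 0.75 s,
        decay 2.5 s) delayed 1 s; skin-conductance impulse response.
      - ``pupil_canonical``: gamma kernel peaking ~2.5 s (pupil dilation).
      - ``hpr_us_locked``: biphasic heart-period kernel peaking ~4 s
        (bradycardia positive lobe, later recovery undershoot).
      - ``rar_early`` / ``rar_late``: respiration-amplitude kernels peaking
        ~2 s and ~7 s.

    All kernels are unit-peak; ``fs`` defaults to the rate they are
    normally used at (2000 Hz for the EMG envelope, 10 Hz otherwise).
    """
    if kind == "sebr_canonical":
        fs = 2000.0 if fs is None else fs
        grid = np.arange(0.0, 0.2, 1.0 / fs)
        vals = _gamma_kernel(grid, mode=0.045, shape=5.0)
        params = {"form": "gamma", "mode_s": 0.045, "shape": 5.0}
    elif kind == "scr_kernel":
        fs = 10.0 if fs is None else fs
        grid = np.arange(0.0, 30.0, 1.0 / fs)
        t = grid - 1.0
        vals = np.where(t >= 0, np.exp(-t / 2.5) - np.exp(-t / 0.75), 0.0)
        params = {"form": "bateman", "tau_rise": 0.75, "tau_decay": 2.5, "delay": 1.0}
    elif kind == "pupil_canonical":
        fs = 10.0 if fs is None else fs
        grid = np.arange(0.0, 17.0, 1.0 / fs)
        vals = _gamma_kernel(grid, mode=2.5, shape=3.0)
        params = {"form": "gamma", "mode_s": 2.5, "shape": 3.0}
    elif kind == "hpr_us_locked":
        fs = 10.0 if fs is None else fs
        grid = np.arange(0.0, 15.0, 1.0 / fs)
        vals = _gamma_kernel(grid, mode=4.0, shape=5.0) - 0.4 * _gamma_kernel(
            grid, mode=9.0, shape=7.0
        )
        params = {"form": "gamma_diff", "mode_s": 4.0}
    elif kind == "rar_early":
        # describes the cycle-amplitude series, whose assignment-to-next-
        # cycle convention lags the physiological modulation by ~1 cycle
        fs = 10.0 if fs is None else fs
        grid = np.arange(0.0, 14.0, 1.0 / fs)
        vals = _gamma_kernel(grid, mode=4.5, shape=6.0)
        params = {"form": "gamma", "mode_s": 4.5, "shape": 6.0}
    elif kind == "rar_late":
        fs = 10.0 if fs is None else fs
        grid = np.arange(0.0, 20.0, 1.0 / fs)
        vals = _gamma_kernel(grid, mode=9.5, shape=10.0)
        params = {"form": "gamma", "mode_s": 9.5, "shape": 10.0}
    else:
        raise ValueError(f"unknown response function kind {kind!r}")
    return ResponseFunction(kind, grid, vals, params)


def _new_rows() -> dict[str, list]:
    return {c: [] for c in ESTIMATE_COLUMNS}


def _append_row(
    rows: dict[str, list],
    *,
    subject: str = "s0",
    session: str = "",
    trial_index: int = 0,
    condition: str = "",
    modality: str = "",
    method: str = "",
    component: str = "",
    amplitude: float = np.nan,
    latency: float = np.nan,
    flag: str = "",
) -> None:
    rows["subject"].append(subject)
    rows["session"].append(session)
    rows["trial_index"].append(trial_index)
    rows["condition"].append(condition)
    rows["modality"].append(modality)
    rows["method"].append(method)
    rows["component"].append(component)
    rows["amplitude"].append(amplitude)
    rows["latency"].append(latency)
    rows["normalized"].append(False)
    rows["flag"].append(flag)


# ---------------------------------------------------------------------------
# startle eyeblink (SEBR)
# ---------------------------------------------------------------------------

def sebr_peak_score(
    env: ContinuousSignal,
    schedule: TrialSchedule,
    *,
    window: tuple[float, float] = (0.020, 0.100),
    subject: str = "s0",
) -> pd.DataFrame:
    """Peak-score startle eyeblinks from the rectified-smoothed EMG envelope.

    Per probe, the amplitude is the maximum of the envelope in the closed
    window 20-100 ms after probe onset (inclusive endpoints on the sample
    grid).
    """
    rows = _new_rows()
    n = len(env.samples)
    for trial in schedule.trials:
        if trial.probe_onset is None:
            raise ValueError("sebr_peak_score requires probe onsets")
        i0 = int(np.ceil((trial.probe_onset + window[0]) * env.sampling_rate - 1e-9))
        i1 = int(np.floor((trial.probe_onset + window[1]) * env.sampling_rate + 1e-9))
        if i0 < 0 or i1 >= n:
            raise ValueError(f"scoring window of trial {trial.index} exceeds record")
        _append_row(
            rows,
            subject=subject,
            session=schedule.session,
            trial_index=trial.index,
            condition=trial.condition,
            modality="sebr",
            method="peak",
            component="probe",
            amplitude=float(np.max(env.samples[i0 : i1 + 1])),
        )
    return pd.DataFrame(rows)


def sebr_glm(
    env: ContinuousSignal,
    schedule: TrialSchedule,
    rf: ResponseFunction | None = None,
    *,
    onset_grid: tuple[float, float, float] = (0.0, 0.100, 0.001),
    subject: str = "s0",
) -> pd.DataFrame:
    """Quantify startle eyeblinks by regression on a canonical blink kernel.

    For each trial the envelope segment after the probe is regressed (with
    intercept) on the canonical kernel shifted over a grid of candidate
    onsets; the amplitude is the slope at the onset minimizing the residual
    sum of squares.
    """
    if rf is None:
        rf = canonical_rf("sebr_canonical", env.sampling_rate)
    elif not np.isclose(rf.sampling_rate, env.sampling_rate):
        rf = rf.resample(env.sampling_rate)
    fs = env.sampling_rate
    x = rf.values
    nx = len(x)
    lo, hi, step = onset_grid
    onsets = np.arange(lo, hi + step / 2, step)
    rows = _new_rows()
    for trial in schedule.trials:
        if trial.probe_onset is None:
            raise ValueError("sebr_glm requires probe onsets")
        base = trial.probe_onset
        best = (np.inf, np.nan, np.nan)  # rss, amplitude, onset
        for on in onsets:
            i0 = int(round((base + on) * fs))
            y = env.samples[i0 : i0 + nx]
            if len(y) < nx:
                raise ValueError(f"segment of trial {trial.index} exceeds record")
            yc = y - y.mean()
            xc = x - x.mean()
            sxx = float(xc @ xc)
            b = float(xc @ yc) / sxx
            rss = float(yc @ yc) - b * b * sxx
            if rss < best[0]:
                best = (rss, b, on)
        _append_row(
            rows,
            subject=subject,
            session=schedule.session,
            trial_index=trial.index,
            condition=trial.condition,
            modality="sebr",
            method="glm",
            component="probe",
            amplitude=best[1],
            latency=best[2],
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# skin conductance: three-burst trial model and AUC
# ---------------------------------------------------------------------------

@dataclass
class ScrTrialModel:
    """Three sudomotor bursts per trial driving the conductance kernel.

    Bursts are unit-peak Gaussians (fixed dispersion ``sigma``) convolved
    with the skin-conductance kernel: one at fixed latency ``delta_cs``
    after CS onset, one with free latency inside the trace interval (from
    ``trace_lo`` after CS offset to ``trace_hi_margin`` before the nominal
    US), and one at fixed latency ``delta_us`` after the (nominal) US.
    """

    sigma: float = 0.3
    delta_cs: float = 1.0
    delta_us: float = 1.0
    trace_lo: float = 8.0
    trace_hi_margin: float = 1.0
    kernel: ResponseFunction | None = None
    grid_step: float = 0.5
    segment_length: float = 25.0

    def __post_init__(self) -> None:
        if self.kernel is None:
            self.kernel = canonical_rf("scr_kernel", 10.0)


def burst_response_shape(
    model: ScrTrialModel, fs_fine: float = 100.0
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-peak response to a single Gaussian burst centered at u = 0.

    Returns (lags, shape); evaluate a burst at center ``mu`` as
    ``np.interp(t - mu, lags, shape, left=0, right=0)``.
    """
    sig = model.sigma
    k = model.kernel.resample(fs_fine)
    pre = 4.0 * sig
    gu = np.arange(-pre, pre + 1.0 / fs_fine, 1.0 / fs_fine)
    g = np.exp(-0.5 * (gu / sig) ** 2)
    resp = np.convolve(g, k.values) / fs_fine
    lags = -pre + np.arange(len(resp)) / fs_fine
    resp /= np.max(np.abs(resp))
    return lags, resp


def fit_scr_trial_model(
    scr10: ContinuousSignal,
    schedule: TrialSchedule,
    model: ScrTrialModel | None = None,
    *,
    subject: str = "s0",
) -> pd.DataFrame:
    """Invert the three-burst SCR trial model by constrained least squares.

    Per trial, burst amplitudes (non-negative) and the trace-burst latency
    (bounded to the trace window) minimize the squared error between the
    preprocessed 10-Hz signal segment and the superposed burst responses
    plus an intercept. Latency is profiled: amplitudes are solved by bounded
    linear least squares on a coarse latency grid, then the best latency is
    refined by bounded 1-D minimization. Masked samples are excluded from
    the objective. Non-convergence or a latency at its bound is flagged,
    not raised.
    """
    model = model or ScrTrialModel()
    fs = scr10.sampling_rate
    lags, shape = burst_response_shape(model)

    def resp(t: np.ndarray, mu: float) -> np.ndarray:
        return np.interp(t - mu, lags, shape, left=0.0, right=0.0)

    rows = _new_rows()
    for trial in schedule.trials:
        t0 = trial.cs_onset
        i0 = int(round(t0 * fs))
        i1 = min(int(round((t0 + model.segment_length) * fs)), len(scr10.samples))
        t = np.arange(i0, i1) / fs
        y = scr10.samples[i0:i1]
        keep = ~scr10.missing_mask[i0:i1] & np.isfinite(y)
        t, y = t[keep], y[keep]
        c_cs = t0 + model.delta_cs
        c_us = trial.nominal_us_onset + model.delta_us
        lat_lo = model.trace_lo
        lat_hi = trial.trace_duration - model.trace_hi_margin

        def solve(lat: float):
            A = np.column_stack(
                [
                    resp(t, c_cs),
                    resp(t, trial.cs_offset + lat),
                    resp(t, c_us),
                    np.ones(len(t)),
                ]
            )
            res = optimize.lsq_linear(
                A,
                y,
                bounds=([0.0, 0.0, 0.0, -np.inf], np.inf),
                method="bvls",
            )
            rss = float(np.sum((A @ res.x - y) ** 2))
            return rss, res

        grid = np.arange(lat_lo, lat_hi + 1e-9, model.grid_step)
        fits = [solve(lat) for lat in grid]
        best_i = int(np.argmin([f[0] for f in fits]))
        lo = max(lat_lo, grid[best_i] - model.grid_step)
        hi = min(lat_hi, grid[best_i] + model.grid_step)
        refine = optimize.minimize_scalar(
            lambda lat: solve(lat)[0], bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-3},
        )
        if refine.success and refine.fun <= fits[best_i][0] + 1e-12:
            lat_hat = float(refine.x)
            _, res = solve(lat_hat)
            flag = ""
        else:
            lat_hat = float(grid[best_i])
            res = fits[best_i][1]
            flag = "no_converge"
        if not res.success:
            flag = (flag + "|" if flag else "") + "amp_no_converge"
        if lat_hat - lat_lo < 1e-2 or lat_hi - lat_hat < 1e-2:
            flag = (flag + "|" if flag else "") + "lat_at_bound"
        a_cs, a_trace, a_us = res.x[0], res.x[1], res.x[2]
        common = dict(
            subject=subject,
            session=schedule.session,
            trial_index=trial.index,
            condition=trial.condition,
            modality="scr",
            method="nls",
        )
        _append_row(rows, component="cs", amplitude=float(a_cs), flag=flag, **common)
        _append_row(
            rows,
            component="trace",
            amplitude=float(a_trace),
            latency=lat_hat,
            flag=flag,
            **common,
        )
        _append_row(rows, component="us", amplitude=float(a_us), flag=flag, **common)
    return pd.DataFrame(rows)


def scr_auc(
    scr10: ContinuousSignal,
    schedule: TrialSchedule,
    *,
    subject: str = "s0",
) -> pd.DataFrame:
    """Area under the baseline-subtracted SCR from CS onset to US timepoint.

    The baseline is the signal value at CS onset; missing samples are
    linearly interpolated before integration (trapezoidal rule).
    """
    fs = scr10.sampling_rate
    y_all = scr10.interpolated()
    rows = _new_rows()
    for trial in schedule.trials:
        i0 = int(round(trial.cs_onset * fs))
        i1 = int(round(trial.nominal_us_onset * fs))
        seg = y_all[i0 : i1 + 1] - y_all[i0]
        auc = float(np.trapezoid(seg, dx=1.0 / fs))
        _append_row(
            rows,
            subject=subject,
            session=schedule.session,
            trial_index=trial.index,
            condition=trial.condition,
            modality="scr",
            method="auc",
            component="whole_trial",
            amplitude=auc,
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fitted response functions and GLM inversion
# ---------------------------------------------------------------------------

def estimate_rf_from_timecourse(
    cs_plus_curves: np.ndarray,
    cs_minus_curves: np.ndarray | None = None,
    *,
    fs: float = 10.0,
    dataset_id: str,
    mode: str = "csplus_baseline",
    kind: str = "fitted",
    baseline_window: float = 0.5,
    smooth_width: float = 1.0,
    truncate: float = 17.0,
    snr_warn: float = 3.0,
) -> ResponseFunction:
    """Build an empirical response function from trial-averaged time courses.

    ``cs_plus_curves``: per-subject CS+ mean curves (n_subjects x n_time,
    starting at CS onset). The RF is the grand average minus the pre-window
    baseline (default) or minus the CS− grand average (``mode="difference"``),
    smoothed with a 1-s moving average, truncated to [0, ``truncate``] s and
    peak-normalized. The source ``dataset_id`` is recorded so that
    evaluation on the same dataset can be refused downstream.
    """
    cp = np.atleast_2d(np.asarray(cs_plus_curves, dtype=float))
    avg = cp.mean(axis=0)
    if mode == "difference":
        if cs_minus_curves is None:
            raise ValueError("difference mode needs CS− curves")
        avg = avg - np.atleast_2d(np.asarray(cs_minus_curves, float)).mean(axis=0)
    elif mode == "csplus_baseline":
        nb = max(1, int(round(baseline_window * fs)))
        avg = avg - avg[:nb].mean()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    w = max(1, int(round(smooth_width * fs)))
    smooth = np.convolve(avg, np.ones(w) / w, mode="same")
    n = min(len(smooth), int(round(truncate * fs)))
    vals = smooth[:n]
    grid = np.arange(n) / fs
    # crude noise floor: high-frequency residual of the raw average
    noise = np.std(np.diff(avg)) / np.sqrt(2.0) if len(avg) > 1 else 0.0
    peak = np.max(np.abs(vals))
    if noise > 0 and peak / noise < snr_warn:
        warnings.warn(
            f"fitted RF peak SNR {peak / noise:.2f} below {snr_warn}; "
            "kernel may be noise",
            stacklevel=2,
        )
    if peak == 0:
        raise ValueError("flat time course; cannot build response function")
    return ResponseFunction(
        kind,
        grid,
        vals,
        {"dataset_id": dataset_id, "mode": mode, "smooth_width": smooth_width},
    )


def check_train_eval_separation(
    rf_or_model, dataset_id: str | None, *, override: bool = False
) -> None:
    """Refuse evaluating a fitted object on its own training dataset."""
    src = getattr(rf_or_model, "params", None)
    src_id = (src or {}).get("dataset_id") if src is not None else getattr(
        rf_or_model, "source_dataset", None
    )
    if override or src_id is None or dataset_id is None:
        return
    if src_id == dataset_id:
        raise ValueError(
            f"fitted on dataset {src_id!r}; evaluation on the same dataset "
            "requires override=True"
        )


def glm_quantify(
    series10: ContinuousSignal,
    schedule: TrialSchedule,
    rfs: ResponseFunction | list[ResponseFunction],
    *,
    anchor: str = "cs",
    granularity: str = "trial",
    modality: str = "",
    subject: str = "s0",
    dataset_id: str | None = None,
    override_separation: bool = False,
    highpass_s: float | None = None,
) -> pd.DataFrame:
    """Amplitude estimation by ordinary least squares on shifted kernels.

    The design matrix holds one regressor per trial (``granularity="trial"``)
    or per condition (``granularity="condition"``) and per response function,
    each a copy of the kernel shifted to the anchor event (CS onset or the
    nominal US time — on recall trials the would-be US at CS offset + trace),
    plus an intercept and a linear drift. ``highpass_s`` adds a cosine
    drift basis with that cutoff period (seconds) to absorb slow baseline
    wander. Missing samples are excluded from the fit.
    """
    if isinstance(rfs, ResponseFunction):
        rfs = [rfs]
    for rf in rfs:
        check_train_eval_separation(rf, dataset_id, override=override_separation)
    fs = series10.sampling_rate
    n = len(series10.samples)
    t_anchor = {
        "cs": [tr.cs_onset for tr in schedule.trials],
        "us": [tr.nominal_us_onset for tr in schedule.trials],
    }[anchor]

    def shifted(rf: ResponseFunction, onset: float) -> np.ndarray:
        col = np.zeros(n)
        k = rf.resample(fs).values if not np.isclose(rf.sampling_rate, fs) else rf.values
        i0 = int(round(onset * fs))
        j1 = min(n, i0 + len(k))
        if i0 < n:
            col[max(i0, 0) : j1] = k[max(-i0, 0) : j1 - i0]
        return col

    cols: list[np.ndarray] = []
    meta: list[tuple] = []  # (trial_index or 0, condition, rf.kind)
    if granularity == "trial":
        for rf in rfs:
            for tr, ta in zip(schedule.trials, t_anchor):
                cols.append(shifted(rf, ta))
                meta.append((tr.index, tr.condition, rf.kind))
    elif granularity == "condition":
        for rf in rfs:
            for cond in (CS_PLUS, CS_MINUS):
                col = np.zeros(n)
                for tr, ta in zip(schedule.trials, t_anchor):
                    if tr.condition == cond:
                        col += shifted(rf, ta)
                cols.append(col)
                meta.append((0, cond, rf.kind))
    else:
        raise ValueError(f"unknown granularity {granularity!r}")

    drift_cols = [np.ones(n), np.linspace(-1.0, 1.0, n)]
    if highpass_s is not None:
        duration = n / fs
        n_cos = int(np.ceil(2.0 * duration / highpass_s))
        u = np.arange(n) / (n - 1)
        for k in range(1, n_cos + 1):
            drift_cols.append(np.cos(np.pi * k * u))
    X = np.column_stack(cols + drift_cols)
    keep = ~series10.missing_mask & np.isfinite(series10.samples)
    beta, *_ = np.linalg.lstsq(X[keep], series10.samples[keep], rcond=None)

    rows = _new_rows()
    for (idx, cond, rkind), amp in zip(meta, beta[: len(meta)]):
        _append_row(
            rows,
            subject=subject,
            session=schedule.session,
            trial_index=int(idx),
            condition=cond,
            modality=modality,
            method="glm",
            component=rkind,
            amplitude=float(amp),
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_by_cs_minus(
    estimates: pd.DataFrame, *, eps_rel: float = 1e-9
) -> pd.DataFrame:
    """Divide amplitudes by the subject's CS− mean of the same component.

    Normalization corrects for between-subject gain differences (electrode
    impedance, anatomy): after it, each subject's CS− mean is exactly 1.
    Groups whose CS− mean is at or below ``eps_rel`` times the group's
    amplitude scale are flagged ``cs_minus_degenerate`` and their normalized
    amplitudes set to NaN (excluded from normalized analyses).
    """
    df = estimates.copy()
    if df["normalized"].any():
        raise ValueError("input already normalized")
    keys = ["subject", "modality", "method", "component"]
    out = []
    excluded: list[tuple] = []
    for key, g in df.groupby(keys, sort=False):
        g = g.copy()
        cs_minus = g.loc[g["condition"] == CS_MINUS, "amplitude"]
        if len(cs_minus) == 0:
            raise ValueError(f"no CS− estimates for group {key}")
        m = float(cs_minus.mean())
        scale = float(np.abs(g["amplitude"]).mean())
        if m <= eps_rel * max(scale, np.finfo(float).tiny):
            g["amplitude"] = np.nan
            g["flag"] = g["flag"].astype(str) + "|cs_minus_degenerate"
            excluded.append(key)
        else:
            g["amplitude"] = g["amplitude"] / m
        g["normalized"] = True
        out.append(g)
    res = pd.concat(out, ignore_index=True)
    res.attrs["excluded_groups"] = excluded
    return res
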