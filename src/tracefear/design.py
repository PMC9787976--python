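"""Experimental design: trial schedules and US-intensity calibration.

A session is an ordered sequence of trials. Each trial presents a colored
conditioned stimulus (CS) for 2 s, followed by a stimulus-free 15-s trace
interval. In acquisition, every CS+ is reinforced with a ~1-s electric
unconditioned stimulus (US) at the end of the trace interval; CS− is never
reinforced. In recall (one week later) no US is delivered and a startle
probe sounds on every trial 13 s after CS offset (2 s before the expected
US). Trials are separated by a 30 ± 2 s inter-trial interval and the CS
order is randomized subject to a maximum of three same-type CS in a row.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

CS_PLUS = "CS+"
CS_MINUS = "CS-"
CONDITIONS = (CS_PLUS, CS_MINUS)

#: trials per condition for each session type
SESSION_TRIALS = {"acquisition": 20, "recall": 15}


@dataclass(frozen=True)
class Trial:
    """One trial of a conditioning session. All times in seconds from
    session start; ``us_onset`` / ``probe_onset`` are None when absent."""

    index: int  # 1-based
    condition: str
    cs_onset: float
    cs_duration: float = 2.0
    trace_duration: float = 15.0
    us_onset: float | None = None
    us_duration: float = 1.0
    probe_onset: float | None = None
    iti_duration: float = 30.0
    task_onset: float | None = None  # ITI digit-stream task, bookkeeping only

    @property
    def cs_offset(self) -> float:
        return self.cs_onset + self.cs_duration

    @property
    def nominal_us_onset(self) -> float:
        """US time (acquisition) or would-be US time (recall / CS−)."""
        return self.cs_onset + self.cs_duration + self.trace_duration


@dataclass
class TrialSchedule:
    session: str
    trials: list[Trial] = field(default_factory=list)
    rng_seed: int = 0

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def conditions(self) -> np.ndarray:
        return np.array([t.condition for t in self.trials])

    @property
    def cs_onsets(self) -> np.ndarray:
        return np.array([t.cs_onset for t in self.trials])

    @property
    def duration(self) -> float:
        """Time of the last scheduled event plus the final ITI."""
        last = self.trials[-1]
        return last.nominal_us_onset + last.us_duration + last.iti_duration

    def validate(self) -> None:
        """Raise ValueError on any violated schedule invariant."""
        n_expected = SESSION_TRIALS[self.session]
        conds = self.conditions
        for c in CONDITIONS:
            if int(np.sum(conds == c)) != n_expected:
                raise ValueError(f"expected {n_expected} {c} trials")
        if max_run_length(conds) > 3:
            raise ValueError("more than 3 same-type CS in a row")
        prev_end = -np.inf
        for t in self.trials:
            if not 28.0 <= t.iti_duration <= 32.0:
                raise ValueError(f"ITI {t.iti_duration} outside [28, 32] s")
            if t.cs_onset <= prev_end:
                raise ValueError("overlapping or non-increasing trials")
            prev_end = t.nominal_us_onset + t.us_duration
            if self.session == "acquisition":
                if t.probe_onset is not None:
                    raise ValueError("probe in acquisition")
                if t.condition == CS_PLUS:
                    if t.us_onset != t.nominal_us_onset:
                        raise ValueError("CS+ must be reinforced at trace end")
                elif t.us_onset is not None:
                    raise ValueError("reinforced CS−")
            else:
                if t.us_onset is not None:
                    raise ValueError("US in recall session")
                if t.probe_onset is None or not np.isclose(
                    t.probe_onset, t.cs_offset + 13.0
                ):
                    raise ValueError("recall probe must be 13 s after CS offset")


def max_run_length(conditions: np.ndarray) -> int:
    """Longest run of identical consecutive entries."""
    run = best = 1
    for prev, cur in zip(conditions[:-1], conditions[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best


def generate_schedule(
    session: str,
    seed: int,
    *,
    n_per_condition: int | None = None,
    cs_duration: float = 2.0,
    trace_duration: float = 15.0,
    us_duration: float = 1.0,
    probe_delay: float = 13.0,
    iti_mean: float = 30.0,
    iti_jitter: float = 2.0,
    max_run: int = 3,
    start: float = 10.0,
    max_attempts: int = 100_000,
) -> TrialSchedule:
    """Generate a randomized schedule for one session.

    The condition sequence is drawn uniformly over all sequences with the
    required per-condition counts and no run longer than ``max_run``, by
    rejection sampling of uniform shuffles. Deterministic given ``seed``.

    Parameters
    ----------
    session : {"acquisition", "recall"}
    seed : int
        Seed for the schedule's private random generator.
    probe_delay : float
        Recall-session probe latency after CS offset (s).
    iti_mean, iti_jitter : float
        ITI drawn uniformly from ``[iti_mean - iti_jitter, iti_mean + iti_jitter]``.
    """
    if session not in SESSION_TRIALS:
        raise ValueError(f"unknown session {session!r}")
    if max_run < 1:
        raise ValueError("max_run must be >= 1")
    n = n_per_condition if n_per_condition is not None else SESSION_TRIALS[session]
    rng = np.random.default_rng(seed)
    base = np.array([CS_PLUS] * n + [CS_MINUS] * n)
    for _ in range(max_attempts):
        order = rng.permutation(base)
        if max_run_length(order) <= max_run:
            break
    else:
        raise ValueError(
            f"no admissible sequence found in {max_attempts} shuffles "
            f"(max_run={max_run}, n={n})"
        )

    trials: list[Trial] = []
    t = float(start)
    for i, cond in enumerate(order, start=1):
        iti = iti_mean + rng.uniform(-iti_jitter, iti_jitter)
        nominal_us = t + cs_duration + trace_duration
        us_onset = (
            nominal_us if (session == "acquisition" and cond == CS_PLUS) else None
        )
        probe_onset = t + cs_duration + probe_delay if session == "recall" else None
        # ITI digit-stream task onset: 5-10 s after (expected) US offset.
        task_onset = nominal_us + us_duration + rng.uniform(5.0, 10.0)
        trials.append(
            Trial(
                index=i,
                condition=str(cond),
                cs_onset=t,
                cs_duration=cs_duration,
                trace_duration=trace_duration,
                us_onset=us_onset,
                us_duration=us_duration,
                probe_onset=probe_onset,
                iti_duration=iti,
                task_onset=task_onset,
            )
        )
        t = nominal_us + us_duration + iti
    sched = TrialSchedule(session=session, trials=trials, rng_seed=int(seed))
    if n_per_condition is None:
        sched.validate()
    return sched


@dataclass
class PainCalibrationCurve:
    """Subjective intensity ratings (0-100) of graded electric stimuli.

    ``painful_rating`` anchors the rating regarded as "clearly painful";
    the US current is set to the intensity whose interpolated rating equals
    a fraction (default 90%) of that anchor.
    """

    samples: list[tuple[float, float]]  # (intensity mA, rating)
    painful_rating: float = 100.0

    def __post_init__(self) -> None:
        if len(self.samples) < 2:
            raise ValueError("need at least 2 calibration samples")
        arr = np.asarray(self.samples, dtype=float)
        if np.any(arr[:, 0] <= 0):
            raise ValueError("intensities must be strictly positive")
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite calibration sample")


def calibrate_us_intensity(
    curve: PainCalibrationCurve, fraction: float = 0.9
) -> float:
    """Intensity (mA) whose rating equals ``fraction`` of the painful anchor.

    Ratings are sorted by intensity and, if non-monotone, replaced by their
    isotonic (monotone non-decreasing) regression before piecewise-linear
    inversion. No extrapolation: a target rating outside the observed range
    raises ValueError.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    arr = np.asarray(sorted(curve.samples), dtype=float)
    x, r = arr[:, 0], arr[:, 1]
    if np.any(np.diff(r) < 0):
        from sklearn.isotonic import IsotonicRegression

        r = IsotonicRegression(increasing=True).fit_transform(x, r)
    target = fraction * curve.painful_rating
    if target < r[0] or target > r[-1]:
        raise ValueError(
            f"target rating {target:.2f} outside observed range [{r[0]}, {r[-1]}]"
        )
    # first index with r[j] >= target; ties resolve to the lowest intensity
    j = int(np.searchsorted(r, target, side="left"))
    if j == 0:
        return float(x[0])
    w = (target - r[j - 1]) / (r[j] - r[j - 1])  # r[j-1] < target <= r[j]
    return float(x[j - 1] + w * (x[j] - x[j - 1]))


def with_timing(schedule: TrialSchedule, **overrides) -> TrialSchedule:
    """Return a copy of ``schedule`` with per-trial fields overridden."""
    return TrialSchedule(
        session=schedule.session,
        trials=[replace(t, **overrides) for t in schedule.trials],
        rng_seed=schedule.rng_seed,
    )
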