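"""File-format plumbing: delimited text tables with JSON sidecars.

Events, signals, estimate tables and response functions are serialized as
tab-separated UTF-8 text ("." decimal separator, header row) with a JSON
sidecar carrying the metadata needed to reconstruct the in-memory object.
Floats are written with 17 significant digits so read(write(x)) round-trips
exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import Trial, TrialSchedule
from .respquant import ResponseFunction
from .signals import ContinuousSignal

FLOAT_FMT = "%.17g"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write_sidecar(path: Path, meta: dict) -> None:
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def _read_sidecar(path: Path) -> dict:
    return json.loads(_sidecar_path(path).read_text())


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

def schedule_to_events(schedule: TrialSchedule) -> pd.DataFrame:
    """Long-format event table (onset, duration, trial_type, condition,
    trial_index) for one session."""
    rows = []
    for t in schedule.trials:
        rows.append((t.cs_onset, t.cs_duration, "cs", t.condition, t.index))
        if t.us_onset is not None:
            rows.append((t.us_onset, t.us_duration, "us", t.condition, t.index))
        if t.probe_onset is not None:
            rows.append((t.probe_onset, 0.020, "probe", t.condition, t.index))
        if t.task_onset is not None:
            rows.append((t.task_onset, 13.0, "iti_task", t.condition, t.index))
    return pd.DataFrame(
        rows, columns=["onset", "duration", "trial_type", "condition", "trial_index"]
    )


def write_events(schedule: TrialSchedule, path: str | Path) -> Path:
    path = Path(path)
    schedule_to_events(schedule).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )
    timing = {
        "cs_duration": schedule.trials[0].cs_duration,
        "trace_duration": schedule.trials[0].trace_duration,
        "us_duration": schedule.trials[0].us_duration,
        "iti_durations": [t.iti_duration for t in schedule.trials],
    }
    _write_sidecar(path, {"session": schedule.session,
                          "rng_seed": schedule.rng_seed, **timing})
    return path


def read_events(path: str | Path) -> TrialSchedule:
    path = Path(path)
    ev = pd.read_csv(path, sep="\t", float_precision="round_trip")
    meta = _read_sidecar(path)
    trials = []
    for idx, g in ev.groupby("trial_index", sort=True):
        by_type = {r.trial_type: r for r in g.itertuples()}
        cs = by_type["cs"]
        us = by_type.get("us")
        probe = by_type.get("probe")
        task = by_type.get("iti_task")
        trials.append(
            Trial(
                index=int(idx),
                condition=cs.condition,
                cs_onset=float(cs.onset),
                cs_duration=float(cs.duration),
                trace_duration=float(meta["trace_duration"]),
                us_onset=float(us.onset) if us is not None else None,
                us_duration=float(meta["us_duration"]),
                probe_onset=float(probe.onset) if probe is not None else None,
                iti_duration=float(meta["iti_durations"][int(idx) - 1]),
                task_onset=float(task.onset) if task is not None else None,
            )
        )
    return TrialSchedule(session=meta["session"], trials=trials,
                         rng_seed=int(meta["rng_seed"]))


# ---------------------------------------------------------------------------
# signals
# ---------------------------------------------------------------------------

def write_signal(sig: ContinuousSignal, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"value": sig.samples, "missing": sig.missing_mask.astype(int)})
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    _write_sidecar(path, {"channel": sig.channel,
                          "sampling_rate": sig.sampling_rate,
                          "units": sig.units})
    return path


def read_signal(path: str | Path) -> ContinuousSignal:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    meta = _read_sidecar(path)
    return ContinuousSignal(
        channel=meta["channel"],
        sampling_rate=float(meta["sampling_rate"]),
        samples=df["value"].to_numpy(),
        missing_mask=df["missing"].to_numpy().astype(bool),
        units=meta.get("units", ""),
    )


# ---------------------------------------------------------------------------
# estimates and response functions
# ---------------------------------------------------------------------------

def write_estimates(estimates: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    estimates.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    return path


def read_estimates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), sep="\t", float_precision="round_trip")
    df["flag"] = df["flag"].fillna("")
    df["condition"] = df["condition"].astype(str)
    return df


def write_rf(rf: ResponseFunction, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"time": rf.grid, "value": rf.values}).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )
    _write_sidecar(path, {"kind": rf.kind, "params": rf.params})
    return path


def read_rf(path: str | Path) -> ResponseFunction:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    meta = _read_sidecar(path)
    return ResponseFunction(meta["kind"], df["time"].to_numpy(),
                            df["value"].to_numpy(), meta.get("params", {}))
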