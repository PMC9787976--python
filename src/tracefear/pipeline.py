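"""Pipeline orchestration: synthesize → preprocess → quantify → statistics.

A :class:`RunConfig` fully determines a run (every stochastic step has an
explicit seed); outputs are tidy delimited tables plus a provenance JSON
with the config hash, seeds and package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io, preprocess, respquant, stats, synthdata

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``dataset_id`` identifies the dataset so that fitted response functions
    and frozen habituation parameters can refuse evaluation on their own
    training data.
    """

    dataset_id: str = "synth-1"
    session: str = "recall"
    n_subjects: int = 8
    seed: int = 0
    modalities: tuple[str, ...] = ("emg", "scr")
    out_dir: str = "tracefear_out"
    n_perm: int = 1000
    n_max_average: int = 15
    truth: dict = field(default_factory=dict)       # TruthParams overrides
    scr_model: dict = field(default_factory=dict)   # ScrTrialModel overrides

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        if isinstance(cfg.modalities, list):
            cfg.modalities = tuple(cfg.modalities)
        return cfg

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        d = asdict(self)
        d["modalities"] = list(self.modalities)
        path.write_text(yaml.safe_dump(d, sort_keys=True))
        return path

    def hash(self) -> str:
        d = asdict(self)
        d["modalities"] = list(self.modalities)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _quantify_subject(ds: synthdata.SessionDataset, cfg: RunConfig) -> list[pd.DataFrame]:
    out = []
    sid = ds.subject_id
    if "emg" in ds.signals:
        env = preprocess.emg_preprocess_peak(ds.signals["emg"])
        out.append(respquant.sebr_peak_score(env, ds.schedule, subject=sid))
        env_glm = preprocess.emg_preprocess_glm(ds.signals["emg"])
        out.append(respquant.sebr_glm(env_glm, ds.schedule, subject=sid))
    if "scr" in ds.signals:
        scr10 = preprocess.scr_preprocess(ds.signals["scr"], ds.schedule)
        model = respquant.ScrTrialModel(**cfg.scr_model)
        out.append(
            respquant.fit_scr_trial_model(scr10, ds.schedule, model, subject=sid)
        )
    if "pupil_l" in ds.signals:
        ps = preprocess.pupil_preprocess(
            ds.signals["pupil_l"], ds.signals["pupil_r"],
            ds.signals["gaze_x"], ds.signals["gaze_y"], ds.schedule,
        )
        out.append(
            respquant.glm_quantify(
                ps.to_signal(10.0), ds.schedule,
                respquant.canonical_rf("pupil_canonical"),
                anchor="cs", modality="pupil", subject=sid,
                dataset_id=cfg.dataset_id, highpass_s=100.0,
            )
        )
    if "ecg" in ds.signals:
        hp = preprocess.ecg_to_heart_period(ds.signals["ecg"])
        out.append(
            respquant.glm_quantify(
                hp.to_signal(), ds.schedule,
                respquant.canonical_rf("hpr_us_locked"),
                anchor="us", modality="heart_period", subject=sid,
                dataset_id=cfg.dataset_id,
            )
        )
    if "respiration" in ds.signals:
        ra = preprocess.respiration_to_amplitude(ds.signals["respiration"])
        out.append(
            respquant.glm_quantify(
                ra.to_signal(), ds.schedule,
                [respquant.canonical_rf("rar_early"),
                 respquant.canonical_rf("rar_late")],
                anchor="us", granularity="condition",
                modality="respiration", subject=sid,
                dataset_id=cfg.dataset_id,
            )
        )
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full pipeline on a synthetic cohort; write result tables.

    Returns a result bundle: estimate tables (raw and normalized), the
    trial-averaging calibration (startle peak scoring, recall session), and
    provenance. Missing/failed modalities are skipped with a warning, not a
    global failure.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = synthdata.synth_cohort(
        cfg.n_subjects, cfg.session, cfg.seed,
        modalities=cfg.modalities,
        params=synthdata.TruthParams(**cfg.truth) if cfg.truth else None,
    )
    tables: list[pd.DataFrame] = []
    for ds in cohort:
        try:
            tables.extend(_quantify_subject(ds, cfg))
        except Exception:
            log.exception("subject %s failed; skipping", ds.subject_id)
    if not tables:
        raise RuntimeError("no modality produced estimates")
    raw = pd.concat(tables, ignore_index=True)
    io.write_estimates(raw, out_dir / "estimates_raw.tsv")

    bundle: dict = {"estimates_raw": raw, "out_dir": out_dir}
    norm_parts = []
    for (modality, method), g in raw.groupby(["modality", "method"]):
        if (g["condition"] == "CS-").any() and (g["trial_index"] > 0).all():
            try:
                norm_parts.append(respquant.normalize_by_cs_minus(g))
            except ValueError as exc:
                log.warning("normalization skipped for %s/%s: %s",
                            modality, method, exc)
    if norm_parts:
        norm = pd.concat(norm_parts, ignore_index=True)
        io.write_estimates(norm, out_dir / "estimates_normalized.tsv")
        bundle["estimates_normalized"] = norm
        peak = norm[(norm["modality"] == "sebr") & (norm["method"] == "peak")]
        if cfg.session == "recall" and not peak.empty:
            calib = stats.calibrate_trial_average(peak, cfg.n_max_average)
            calib.table.to_csv(out_dir / "calibration_sebr_peak.tsv",
                               sep="\t", index=False)
            bundle["calibration"] = calib

    provenance = {
        "config": asdict(cfg) | {"modalities": list(cfg.modalities)},
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "version": __version__,
        "subjects": [ds.subject_id for ds in cohort],
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2,
                                                        sort_keys=True))
    bundle["provenance"] = provenance
    return bundle
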