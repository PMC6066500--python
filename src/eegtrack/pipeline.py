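"""End-to-end orchestration: simulate -> preprocess -> coherence -> score -> predict.

Two entry points mirror the two run modes.  :func:`run_simulate` writes a
cohort artifact directory (EEG as EDF and optionally flat CSV, tracking
traces as CSV, ground truth as JSON, lesion masks as NIfTI, plus a manifest
with content hashes).  :func:`run_analyze` consumes such a directory and
writes per-subject coherence tables, tracking scores, injury profiles, the
prediction table, and a summary JSON.  :func:`analyze_cohort` is the
in-memory fast path used heavily by the test bench.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import lesion as lesion_mod
from .behavior import TrackingTrace, score_battery
from .coherence import DEFAULT_BANDS, coherence_table
from .edf import read_edf, write_edf
from .model import SubjectRecord, TrainingGainModel, TrainingGainResults
from .montage import Montage, load_roi_config
from .preprocess import PreprocessConfig, clean_pipeline
from .simulate import Cohort, SimulationConfig, generate_cohort

__all__ = ["RunConfig", "run_simulate", "run_analyze", "analyze_cohort"]

log = logging.getLogger("eegtrack.pipeline")


@dataclasses.dataclass
class RunConfig:
    """Configuration of a pipeline run (JSON-serializable)."""

    mode: str = "simulate"  # simulate | analyze
    seed: int = 0
    simulation: SimulationConfig | None = None
    preprocess: PreprocessConfig | None = None
    bands: dict[str, tuple[float, float]] | None = None
    endpoint: str = "sr"
    write_eeg_csv: bool = False
    use_truth_templates: bool = True

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        sim = payload.pop("simulation", None)
        pre = payload.pop("preprocess", None)
        cfg = cls(**payload)
        if sim is not None:
            for key in ("coupling_range", "calib_speeds", "band"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            cfg.simulation = SimulationConfig(**sim)
        if pre is not None:
            cfg.preprocess = PreprocessConfig(**pre)
        if cfg.bands is not None:
            cfg.bands = {k: tuple(v) for k, v in cfg.bands.items()}
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(outdir: Path) -> None:
    entries = {
        str(p.relative_to(outdir)): _sha256(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    (outdir / "manifest.json").write_text(json.dumps(entries, indent=2))


def run_simulate(config: RunConfig, outdir: str | Path) -> Path:
    """Generate a cohort and write its artifact directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation or SimulationConfig(rng_seed=config.seed)
    log.info("simulating cohort: n=%d, seed=%d", sim.n_subjects, sim.rng_seed)
    cohort = generate_cohort(sim)
    cohort.montage.to_csv(outdir / "montage.csv")
    cohort.rois.to_json(outdir / "roi_config.json")
    truth_rows = []
    for sub in cohort.subjects:
        sid = sub.subject_id
        sdir = outdir / sid
        sdir.mkdir(exist_ok=True)
        write_edf(sub.recording, sdir / "eeg.edf")
        if config.write_eeg_csv:
            pd.DataFrame(sub.recording.data.T, columns=cohort.montage.lead_ids).to_csv(
                sdir / "eeg.csv", index=False
            )
        if sub.calib_rounds:
            pd.DataFrame(sub.calib_rounds, columns=["speed", "sr"]).to_csv(
                sdir / "calibration_rounds.csv", index=False
            )
            (sdir / "calibration.json").write_text(json.dumps(sub.calibration.to_dict(), indent=2))
        for phase, traces in (("pre", sub.pre_traces), ("post", sub.post_traces)):
            for k, tr in enumerate(traces, 1):
                tr.to_csv(sdir / f"{phase}_run{k}.csv")
        if sub.lesion is not None:
            sub.lesion.to_nifti(sdir / "lesion.nii.gz")
        t = sub.truth
        truth_rows.append(
            {
                "subject_id": sid, "gamma": t.gamma,
                "coherence_plain": t.coherence_plain,
                "coherence_expected": t.coherence_expected,
                "delta_true": t.delta_true, "delta_clipped": t.delta_clipped,
                "sr_pre_target": t.sr_pre_target, "sr_post_target": t.sr_post_target,
                "v_train": t.v_train, "lesion_critical": t.lesion_critical,
                "artifact_topographies": {
                    k: list(map(float, v)) for k, v in t.artifact_topographies.items()
                },
                "cardiac_period_s": t.cardiac_period_s,
                "speed": t.v_train,
            }
        )
    if cohort.roi_masks:
        rdir = outdir / "roi_masks"
        rdir.mkdir(exist_ok=True)
        for name, mask in cohort.roi_masks.items():
            mask.to_nifti(rdir / f"{name}.nii.gz")
    (outdir / "ground_truth.json").write_text(
        json.dumps({"config": _sim_to_dict(sim), "subjects": truth_rows}, indent=2)
    )
    _write_manifest(outdir)
    return outdir


def _sim_to_dict(sim: SimulationConfig) -> dict:
    d = dataclasses.asdict(sim)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def analyze_cohort(
    cohort: Cohort,
    preprocess: PreprocessConfig | None = None,
    bands: dict | None = None,
    endpoint: str = "sr",
    use_truth_templates: bool = True,
) -> tuple[list[SubjectRecord], TrainingGainResults]:
    """In-memory analysis of a generated cohort.

    Runs the cleaning chain, coherence extraction, tracking scoring, lesion
    exclusion, and the prediction model; returns the per-subject records and
    the fitted results.
    """
    pre_cfg = preprocess or PreprocessConfig()
    bands = bands or DEFAULT_BANDS
    records = []
    for sub in cohort.subjects:
        templates = sub.truth.templates() if use_truth_templates else None
        ep = clean_pipeline(sub.recording, pre_cfg, templates=templates)
        ct = coherence_table(ep, cohort.rois, bands)
        pre_score = score_battery(sub.pre_traces)
        post_score = score_battery(sub.post_traces)
        excluded = False
        if sub.lesion is not None and cohort.roi_masks:
            prof = lesion_mod.injury_profile(sub.subject_id, sub.lesion, cohort.roi_masks)
            excluded = prof.excluded
        records.append(
            SubjectRecord.from_scores(sub.subject_id, ct, pre_score, post_score, excluded)
        )
    model = TrainingGainModel(records, cohort.rois, bands=bands, endpoint=endpoint)
    return records, model.fit()


def run_analyze(config: RunConfig, indir: str | Path, outdir: str | Path) -> Path:
    """Analyze a cohort artifact directory; write report files."""
    indir, outdir = Path(indir), Path(outdir)
    missing = [f for f in ("montage.csv", "roi_config.json") if not (indir / f).exists()]
    if missing:
        raise FileNotFoundError(f"cohort directory {indir} is missing: {missing}")
    montage = Montage.from_csv(indir / "montage.csv")
    rois = load_roi_config(indir / "roi_config.json", montage)
    bands = config.bands or DEFAULT_BANDS
    pre_cfg = config.preprocess or PreprocessConfig()
    truth = {}
    gt_path = indir / "ground_truth.json"
    if gt_path.exists():
        payload = json.loads(gt_path.read_text())
        truth = {row["subject_id"]: row for row in payload["subjects"]}
    subject_dirs = sorted(d for d in indir.iterdir() if d.is_dir() and d.name.startswith("S"))
    if not subject_dirs:
        raise FileNotFoundError(f"no subject directories under {indir}")
    outdir.mkdir(parents=True, exist_ok=True)
    coh_frames, score_rows, profiles = [], [], []
    roi_mask_dir = indir / "roi_masks"
    roi_masks = None
    if roi_mask_dir.exists():
        roi_masks = {
            p.name.split(".")[0]: lesion_mod.VolumeMask.from_nifti(p, space_tag="synthetic-head")
            for p in sorted(roi_mask_dir.glob("*.nii*"))
        }
    for sdir in subject_dirs:
        sid = sdir.name
        log.info("analyzing %s", sid)
        eeg_path = sdir / "eeg.edf"
        if not eeg_path.exists():
            raise FileNotFoundError(f"missing EEG file for {sid}: {eeg_path}")
        rec = read_edf(eeg_path, montage)
        templates = None
        if config.use_truth_templates and sid in truth:
            from .preprocess import ArtifactTemplate

            tpl_info = truth[sid].get("artifact_topographies", {})
            period = truth[sid].get("cardiac_period_s")
            templates = [
                ArtifactTemplate(
                    kind=k, topography=np.asarray(v, float),
                    period_s=period if k == "cardiac" else None,
                )
                for k, v in tpl_info.items()
                if k in ("blink", "eye_movement", "cardiac")
            ]
        ep = clean_pipeline(rec, pre_cfg, templates=templates)
        (outdir / f"{sid}_provenance.json").write_text(json.dumps(ep.provenance, indent=2))
        ct = coherence_table(ep, rois, bands)
        df = ct.table.copy()
        df.insert(0, "subject_id", sid)
        coh_frames.append(df)
        speed = float(truth.get(sid, {}).get("speed", 0.0))
        scores = {}
        for phase in ("pre", "post"):
            runs = sorted(sdir.glob(f"{phase}_run*.csv"))
            if not runs:
                raise FileNotFoundError(f"missing {phase} tracking runs for {sid}")
            traces = [TrackingTrace.from_csv(p, speed=speed) for p in runs]
            scores[phase] = score_battery(traces)
        score_rows.append(
            {
                "subject_id": sid,
                "sr_pre": scores["pre"].sr, "sr_post": scores["post"].sr,
                "er_pre": scores["pre"].er, "er_post": scores["post"].er,
                "n_runs": scores["pre"].n_runs,
            }
        )
        lesion_path = sdir / "lesion.nii.gz"
        if roi_masks and lesion_path.exists():
            mask = lesion_mod.VolumeMask.from_nifti(lesion_path, space_tag="synthetic-head")
            profiles.append(lesion_mod.injury_profile(sid, mask, roi_masks))
    coh_df = pd.concat(coh_frames, ignore_index=True)
    coh_df.to_csv(outdir / "coherence.csv", index=False)
    scores_df = pd.DataFrame(score_rows)
    scores_df.to_csv(outdir / "scores.csv", index=False)
    lesion_df = None
    if profiles:
        lesion_mod.profiles_frame(profiles).to_csv(outdir / "injury_profiles.csv", index=False)
        flags = lesion_mod.exclusion_flags(profiles)
        lesion_df = pd.DataFrame(
            {"subject_id": list(flags), "excluded": list(flags.values())}
        )
    model = TrainingGainModel.from_frames(
        coh_df, scores_df, rois, lesion_df=lesion_df, endpoint=config.endpoint
    )
    results = model.fit()
    results.prediction.to_csv(outdir / "prediction.csv", index=False)
    results.change.to_csv(outdir / "change_tests.csv", index=False)
    results.baseline.to_csv(outdir / "baseline_relations.csv", index=False)
    prim = results.primary_result("all")
    summary = {
        "n_subjects": results.nobs,
        "endpoint": config.endpoint,
        "primary_circuit": prim.circuit,
        "primary_band": results.model.primary_band,
        "cohorts": {},
        "lesion_masks_present": bool(profiles),
    }
    for cohort_name in results.prediction.cohort.unique():
        row = results.primary_result(cohort_name)
        summary["cohorts"][cohort_name] = {"r": float(row.r), "p": float(row.p), "n": int(row.n)}
    if not profiles:
        summary["cohorts"].setdefault("lesion_excluded", summary["cohorts"]["all"] | {"note": "no lesion masks; identical to all"})
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    (outdir / "summary.txt").write_text(results.summary() + "\n")
    _write_manifest(outdir)
    return outdir
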