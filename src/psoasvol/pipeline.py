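"""Stage orchestration: each stage reads/writes a standard layout under
``config.out_dir`` and refuses to run with an actionable message when an
upstream artifact is missing.

Layout::

    volumes/{sid}.nii           water phantom volumes
    masks/{sid}_{side}.nii      ground-truth masks
    landmarks.csv               subject_id, lx..rz
    demographics.csv            cohort table with target volumes
    model/weights.npz(.json)    trained segmentation network
    cv_report.csv / cv_summary.json
    segmentations/{sid}_{side}.nii
    cohort.csv                  quantified + QC-screened records
    report/stats.json
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from . import io
from .augment import build_training_set
from .config import PipelineConfig, PipelineError, stage_seed, write_sidecar
from .core import MuscleMask
from .metrics import bland_altman
from .network import load_weights, save_weights
from .popstats import analyze_cohort
from .preprocess import embed_crop, prepare_subject
from .quantify import qc_screen, quantify_subject, records_to_table
from .synthetic import CohortParams, generate_cohort, generate_phantom
from .training import TrainConfig, cross_validate, train_model

STAGES = ("generate-phantoms", "train", "cross-validate", "segment",
          "quantify", "stats")


def _logger(stage: str, config: PipelineConfig) -> logging.LoggerAdapter:
    logger = logging.getLogger(f"psoasvol.{stage}")
    logger.setLevel(config.log_level)
    if not logging.getLogger("psoasvol").handlers:
        h = logging.StreamHandler()
        h.setFormatter(logging.Formatter("%(name)s %(message)s"))
        logging.getLogger("psoasvol").addHandler(h)
    return logging.LoggerAdapter(logger, {})


def _require(path: Path, producer: str):
    if not path.exists():
        raise PipelineError(
            f"missing artifact {path}; run the '{producer}' stage first"
        )
    return path


def _out(config) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def stage_generate_phantoms(config: PipelineConfig) -> None:
    log = _logger("generate-phantoms", config)
    out = _out(config)
    seed = stage_seed(config.seed, "generate-phantoms")
    log.info("seed=%d generating %d phantom subjects",
             seed, config.n_female + config.n_male)
    params = CohortParams.from_study(seed=seed)
    cohort = generate_cohort(params, config.n_female, config.n_male)
    # desk-scale grids cannot hold life-size muscles; shrink targets
    scale = 0.18 if config.desk_scale else 1.0
    (out / "volumes").mkdir(exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    landmarks = {}
    for _, row in cohort.iterrows():
        sid = row["subject_id"]
        subj = generate_phantom(
            config.phantom,
            target_left_ml=row["target_left_ml"] * scale,
            target_right_ml=row["target_right_ml"] * scale,
            subject_id=sid,
        )
        io.write_volume(subj.volume, out / "volumes" / f"{sid}.nii")
        io.write_mask(subj.left_mask, out / "masks" / f"{sid}_left.nii")
        io.write_mask(subj.right_mask, out / "masks" / f"{sid}_right.nii")
        landmarks[sid] = subj.landmarks
    io.write_landmarks(landmarks, out / "landmarks.csv")
    cohort.to_csv(out / "demographics.csv", index=False)
    write_sidecar(out / "demographics.csv", "generate-phantoms", config)
    log.info("seed=%d wrote %d subjects to %s", seed, len(cohort), out)


def _load_prepared_subjects(config: PipelineConfig, annotated: bool):
    out = Path(config.out_dir)
    _require(out / "landmarks.csv", "generate-phantoms")
    landmarks = io.read_landmarks(out / "landmarks.csv")
    subjects = []
    for sid, lms in landmarks.items():
        volume = io.read_volume(_require(out / "volumes" / f"{sid}.nii",
                                         "generate-phantoms"))
        masks = {}
        if annotated:
            for side in ("left", "right"):
                masks[side] = io.read_mask(
                    _require(out / "masks" / f"{sid}_{side}.nii",
                             "generate-phantoms"))
        subjects.append(prepare_subject(
            volume, lms,
            left_mask=masks.get("left"), right_mask=masks.get("right"),
            crop_shape=config.crop_shape, subject_id=sid,
        ))
    return subjects


def stage_train(config: PipelineConfig) -> None:
    log = _logger("train", config)
    out = _out(config)
    seed = stage_seed(config.seed, "train")
    subjects = _load_prepared_subjects(config, annotated=True)
    cfg = _train_config(config, seed)
    if cfg.augmentation is not None:
        samples = build_training_set(subjects, cfg.augmentation)
    else:
        samples = [c for s in subjects for c in (s.left, s.right)]
    log.info("seed=%d training on %d samples from %d subjects",
             seed, len(samples), len(subjects))
    result = train_model(samples, cfg, config.network)
    (out / "model").mkdir(exist_ok=True)
    save_weights(result.net, out / "model" / "weights.npz")
    (out / "model" / "history.json").write_text(json.dumps({
        "loss_history": result.loss_history,
        "best_epoch": result.best_epoch,
        "best_loss": result.best_loss,
    }, indent=2))
    write_sidecar(out / "model" / "weights.npz", "train", config)
    log.info("seed=%d best loss %.4f at epoch %d",
             seed, result.best_loss, result.best_epoch)


def _train_config(config: PipelineConfig, seed: int) -> TrainConfig:
    from dataclasses import replace

    return replace(config.train, seed=seed)


def stage_cross_validate(config: PipelineConfig) -> None:
    log = _logger("cross-validate", config)
    out = _out(config)
    seed = stage_seed(config.seed, "cross-validate")
    subjects = _load_prepared_subjects(config, annotated=True)
    report = cross_validate(subjects, config.cv_folds,
                            _train_config(config, seed), config.network)
    report.per_subject.to_csv(out / "cv_report.csv", index=False)
    ba = bland_altman(report.volume_pairs())
    (out / "cv_summary.json").write_text(json.dumps({
        "pooled_dsc_mean": report.pooled_dsc_mean,
        "pooled_dsc_sd": report.pooled_dsc_sd,
        "per_fold": [{"fold": f.fold_id, "dsc_mean": f.dsc_mean,
                      "dsc_sd": f.dsc_sd, "n_test": len(f.test_ids)}
                     for f in report.folds],
        "bland_altman": {"bias_pct": ba.bias, "loa_lower": ba.loa_lower,
                         "loa_upper": ba.loa_upper, "n": ba.n},
    }, indent=2))
    write_sidecar(out / "cv_summary.json", "cross-validate", config)
    log.info("seed=%d pooled out-of-sample DSC %.4f +/- %.4f",
             seed, report.pooled_dsc_mean, report.pooled_dsc_sd)


def stage_segment(config: PipelineConfig) -> None:
    log = _logger("segment", config)
    out = _out(config)
    seed = stage_seed(config.seed, "segment")
    weights = _require(out / "model" / "weights.npz", "train")
    net = load_weights(weights)
    subjects = _load_prepared_subjects(config, annotated=False)
    (out / "segmentations").mkdir(exist_ok=True)
    landmarks = io.read_landmarks(out / "landmarks.csv")
    for subj in subjects:
        parent_shape = io.read_volume(
            out / "volumes" / f"{subj.subject_id}.nii").shape
        for side, crop in (("left", subj.left), ("right", subj.right)):
            probs = net.forward(crop.intensities[None, None])[0, 0]
            pred = (probs >= config.network.threshold).astype(np.uint8)
            full = embed_crop(pred, crop.source_offset, parent_shape,
                              reflected=crop.reflected)
            io.write_mask(MuscleMask(full, crop.voxel_mm),
                          out / "segmentations" / f"{subj.subject_id}_{side}.nii")
    write_sidecar(out / "segmentations", "segment", config)
    log.info("seed=%d segmented %d subjects", seed, len(subjects))


def stage_quantify(config: PipelineConfig) -> None:
    log = _logger("quantify", config)
    out = _out(config)
    seed = stage_seed(config.seed, "quantify")
    seg_dir = _require(out / "segmentations", "segment")
    demo = pd.read_csv(_require(out / "demographics.csv", "generate-phantoms"))
    records = []
    for _, row in demo.iterrows():
        sid = row["subject_id"]
        left = io.read_mask(_require(seg_dir / f"{sid}_left.nii", "segment"))
        right = io.read_mask(_require(seg_dir / f"{sid}_right.nii", "segment"))
        records.append(quantify_subject(left, right, row.to_dict()))
    table = qc_screen(records_to_table(records), config.qc)
    table.to_csv(out / "cohort.csv", index=False)
    write_sidecar(out / "cohort.csv", "quantify", config)
    log.info("seed=%d quantified %d subjects (%d QC-flagged)",
             seed, len(table), int((~table["qc_pass"]).sum()))


def stage_stats(config: PipelineConfig) -> None:
    log = _logger("stats", config)
    out = _out(config)
    seed = stage_seed(config.seed, "stats")
    cohort_path = _require(out / "cohort.csv", "quantify")
    records = pd.read_csv(cohort_path)
    report = analyze_cohort(records)
    (out / "report").mkdir(exist_ok=True)
    (out / "report" / "stats.json").write_text(json.dumps(report, indent=2))
    write_sidecar(out / "report" / "stats.json", "stats", config)
    log.info("seed=%d wrote statistics report (%d tests)",
             seed, len(report["tests"]))


_STAGE_FUNCS = {
    "generate-phantoms": stage_generate_phantoms,
    "train": stage_train,
    "cross-validate": stage_cross_validate,
    "segment": stage_segment,
    "quantify": stage_quantify,
    "stats": stage_stats,
}


def run_pipeline(config: PipelineConfig,
                 stages: Optional[Sequence[str]] = None) -> None:
    """Execute the requested stages in canonical order."""
    wanted = list(stages) if stages else [s for s in STAGES
                                          if s != "cross-validate"]
    unknown = set(wanted) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    for stage in STAGES:
        if stage in wanted:
            _STAGE_FUNCS[stage](config)
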