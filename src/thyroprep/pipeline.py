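"""End-to-end orchestration: calibrate -> clean -> augment -> classify.

One master seed determines every derived seed (cohort generation, fold
assignment, forest training), so two runs with the same configuration and
inputs agree bit-for-bit, including the JSON manifest the run writes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__ as _pkg_version
from .artifact_removal import PocsParams, clean_image
from .augmentation import MALIGNANT, ROIAnnotation, Sample, crop_nine
from .calibration import calibrate_cohort, rescale_image
from .classify import (CascadeModel, build_cost_matrix, CostMatrix,
                       feature_matrix, predict, train_cascade)
from .errors import ValidationError
from .evaluation import EvaluationReport, evaluate_predictions, make_cv_plan
from .io import read_annotated_image, write_dataset, write_image
from .phantom import generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline knobs plus the master seed that derives every other."""

    # stage toggles
    calibrate: bool = True
    clean: bool = True
    augment: bool = True
    classify: bool = True
    # calibration
    search_fraction: float = 0.30
    remove_tick_column: bool = True
    # artifact removal
    pocs: PocsParams = field(default_factory=PocsParams)
    level_band: int = 0
    # augmentation
    patch_size: int = 256
    stride: int | None = None
    # classification / evaluation
    extractor_id: str = "default"
    cost_override: tuple[float, float] | None = None  # (C[b][m], C[m][b])
    k_folds: int = 10
    aggregate: str = "sample"  # or "case": majority vote over the 9 crops
    # inputs (used when no in-memory images are passed)
    input_dir: str | None = None
    simulate_n: int = 0
    simulate_malignant_fraction: float = 0.5
    # outputs
    output_dir: str | None = None
    master_seed: int = 0

    def derived_seeds(self) -> dict:
        rng = np.random.default_rng(self.master_seed)
        vals = rng.integers(0, 2**31 - 1, size=3)
        return {"cohort": int(vals[0]), "cv": int(vals[1]), "train": int(vals[2])}


def _load_inputs(config: PipelineConfig) -> tuple[dict, dict]:
    """Return ({id: image}, {id: ROIAnnotation}) from dir, or phantoms."""
    images, rois = {}, {}
    if config.simulate_n > 0:
        cohort = generate_cohort(config.simulate_n,
                                 config.simulate_malignant_fraction,
                                 seed=config.derived_seeds()["cohort"])
        for ph in cohort:
            images[ph.image_id] = ph.pixels
            rois[ph.image_id] = ph.roi
        return images, rois
    if config.input_dir is None:
        raise ValidationError("no inputs: set input_dir or simulate_n")
    in_dir = Path(config.input_dir)
    paths = sorted(list(in_dir.glob("*.png")) + list(in_dir.glob("*.tif")) +
                   list(in_dir.glob("*.tiff")))
    if not paths:
        raise ValidationError(f"no PNG/TIFF images found in {in_dir}")
    for p in paths:
        img, roi = read_annotated_image(p)
        images[p.stem] = img
        rois[p.stem] = roi
    return images, rois


def _scale_roi(roi: ROIAnnotation, ratio: float) -> ROIAnnotation:
    def s(pt):
        return (int(round(pt[0] * ratio)), int(round(pt[1] * ratio)))
    return ROIAnnotation(top=s(roi.top), left=s(roi.left),
                         bottom=s(roi.bottom), right=s(roi.right),
                         tirads=roi.tirads)


def _cross_validate(samples: list[Sample], config: PipelineConfig,
                    seeds: dict, manifest: dict) -> EvaluationReport:
    X, y, parents = feature_matrix(samples, config.extractor_id,
                                   config.patch_size)
    case_ids = sorted(set(parents))
    case_label = {pid: int(y[parents.index(pid)]) for pid in case_ids}
    k = min(config.k_folds, len(case_ids))
    plan = make_cv_plan(case_ids, [case_label[c] for c in case_ids],
                        k=k, seed=seeds["cv"])
    parent_arr = np.array(parents)
    fold_arr = np.array([plan.fold_of[p] for p in parents])

    scores = np.zeros(len(samples))
    labels = np.zeros(len(samples), dtype=int)
    fold_sizes = []
    for f in range(k):
        test = fold_arr == f
        train = ~test
        counts = (int(np.sum(y[train] == 0)), int(np.sum(y[train] == 1)))
        if config.cost_override is not None:
            cost = CostMatrix(*config.cost_override)
        else:
            cost = build_cost_matrix(counts)
        model = train_cascade(X[train], y[train], cost,
                              seed=seeds["train"] + f,
                              extractor_id=config.extractor_id)
        sc, lb = predict(model, X[test])
        scores[test] = sc
        labels[test] = lb
        fold_sizes.append(int(np.sum(test)))
    manifest["cv"] = {"k": k, "fold_sample_sizes": fold_sizes}

    if config.aggregate == "case":
        agg_truth, agg_pred, agg_score = [], [], []
        for cid in case_ids:
            sel = parent_arr == cid
            agg_truth.append(case_label[cid])
            agg_score.append(float(np.mean(scores[sel])))
            agg_pred.append(int(np.sum(labels[sel]) * 2 > np.sum(sel)))
        return evaluate_predictions(agg_score, agg_pred, agg_truth)
    return evaluate_predictions(scores, labels, y)


def run_pipeline(config: PipelineConfig,
                 images: dict | None = None,
                 rois: dict | None = None) -> tuple[EvaluationReport | None, dict]:
    """Execute the enabled stages in order and return (report, manifest).

    ``images``/``rois`` may be supplied in memory (id -> array / ROI);
    otherwise inputs come from ``config.input_dir`` or the phantom
    generator. The manifest records versions, seeds, parameters and
    per-stage counts, and is written as sorted-key JSON when
    ``config.output_dir`` is set, so reruns are byte-comparable.
    """
    if not (config.calibrate or config.clean or config.augment or config.classify):
        raise ValidationError("no stages enabled")
    seeds = config.derived_seeds()
    manifest: dict = {
        "package_version": _pkg_version,
        "master_seed": config.master_seed,
        "derived_seeds": seeds,
        "parameters": {
            "search_fraction": config.search_fraction,
            "remove_tick_column": config.remove_tick_column,
            "pocs": asdict(config.pocs),
            "level_band": config.level_band,
            "patch_size": config.patch_size,
            "stride": config.stride,
            "extractor_id": config.extractor_id,
            "cost_override": config.cost_override,
            "k_folds": config.k_folds,
            "aggregate": config.aggregate,
            "stages": {"calibrate": config.calibrate, "clean": config.clean,
                       "augment": config.augment, "classify": config.classify},
        },
        "images": {},
    }

    if images is None or rois is None:
        images, rois = _load_inputs(config)
    else:
        images = dict(images)
        rois = dict(rois)
    manifest["n_images"] = len(images)
    records = {img_id: {} for img_id in images}

    tick_columns: dict = {}
    if config.calibrate:
        detections, plan, failed = calibrate_cohort(images, config.search_fraction)
        manifest["calibration"] = {
            "reference_spacing": plan.reference_spacing,
            "n_failed": len(failed),
            "failed": sorted(failed),
        }
        new_images, new_rois = {}, {}
        for img_id, img in images.items():
            ratio = plan.per_image_ratio[img_id]
            new_images[img_id] = rescale_image(img, ratio)
            new_rois[img_id] = _scale_roi(rois[img_id], ratio)
            rec = records[img_id]
            rec["ratio"] = ratio
            if img_id in detections:
                d = detections[img_id]
                rec["tick_column"] = d.column
                rec["tick_spacing"] = d.spacing_m
                tick_columns[img_id] = int(round(d.column * ratio))
        images, rois = new_images, new_rois

    if config.clean:
        cleaned = {}
        for img_id, img in images.items():
            tick = tick_columns.get(img_id) if config.remove_tick_column else None
            try:
                restored, amask, history = clean_image(
                    img, config.pocs, band=config.level_band, tick_column=tick)
            except Exception as exc:
                raise type(exc)(f"clean stage failed on {img_id}: {exc}") from exc
            cleaned[img_id] = restored
            records[img_id].update({
                "levels": [int(l) for l in amask.levels],
                "mask_area": int(amask.mask.sum()),
                "pocs_iterations": len(history),
            })
        images = cleaned

    report: EvaluationReport | None = None
    samples: list[Sample] = []
    if config.augment:
        for img_id in sorted(images):
            try:
                samples.extend(crop_nine(images[img_id], rois[img_id],
                                         patch_size=config.patch_size,
                                         stride=config.stride,
                                         parent_id=img_id))
            except Exception as exc:
                raise type(exc)(f"augment stage failed on {img_id}: {exc}") from exc
        n_mal = sum(1 for s in samples if s.label == MALIGNANT)
        manifest["augmentation"] = {
            "n_samples": len(samples),
            "n_malignant_samples": n_mal,
            "n_benign_samples": len(samples) - n_mal,
        }
        if config.classify:
            report = _cross_validate(samples, config, seeds, manifest)
            manifest["evaluation"] = report.to_dict()
    elif config.classify:
        raise ValidationError("classify stage requires the augment stage")

    manifest["images"] = records

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for img_id in sorted(images):
            write_image(images[img_id], out / "processed" / f"{img_id}.png")
        if samples:
            write_dataset(samples, out / "dataset")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    return report, manifest
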