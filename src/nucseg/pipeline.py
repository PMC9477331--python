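"""End-to-end orchestration: synth -> pseudo-labels -> train -> segment -> evaluate.

``run_end_to_end`` executes the whole unsupervised pipeline on synthetic
slides and writes a self-contained run directory: the exact config used, the
dataset manifest, the model checkpoint, the per-epoch training history, the
predicted masks for every held-out slide, and a metrics report (pixel F1,
IoU, Dice, AJI — per image and aggregated).  Every artifact is reproducible
from the stored config and global seed alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as nio
from .config import PipelineConfig
from .metrics import MetricsReport, evaluate_masks
from .mixup import channel_bounds, normalize_patch
from .network import FGDCNet
from .pseudolabels import (
    SamplePatch,
    cluster_pixels,
    extract_padded_sample,
    extract_subgraphs,
    select_label_patches,
)
from .synthetic import SyntheticSpec, generate_synthetic_slide
from .training import dynamic_train, sliding_window_segment

__all__ = [
    "generate_slides",
    "build_patches",
    "save_patch_dataset",
    "load_patch_dataset",
    "run_end_to_end",
]

logger = logging.getLogger("nucseg")


def _spec_for(config: PipelineConfig, index: int, seed: int) -> SyntheticSpec:
    d = config.data
    return SyntheticSpec(
        n_nuclei=d.n_nuclei,
        nucleus_radius_range=(d.radius_min, d.radius_max),
        stain_quality=d.quality_for(index),
        hue_jitter=d.hue_jitter,
        noise_sd=d.noise_sd,
        overlap=d.overlap,
        seed=seed + index,
    )


def generate_slides(
    config: PipelineConfig, split: str
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Render the train or test slide collection (image, instance mask) pairs."""
    d = config.data
    count = d.n_train_slides if split == "train" else d.n_test_slides
    base = config.stage_seed(f"synth-{split}")
    slides = []
    for i in range(count):
        spec = _spec_for(config, i, base)
        slides.append(generate_synthetic_slide(spec, d.slide_height, d.slide_width))
    return slides


def build_patches(
    images: Sequence[np.ndarray], config: PipelineConfig
) -> Tuple[List[SamplePatch], List[SamplePatch]]:
    """Unsupervised sample construction over a slide collection.

    Per slide: random sub-graphs, per-sub-graph k-means tissue clustering,
    eligible-patch selection, asymmetric padded extraction.  Patch images are
    percentile-normalized against their source sub-graph.  The pooled patches
    are capped, shuffled and split 2:1 into train and validation.
    """
    p = config.pseudo
    seed = config.stage_seed("pseudo-labels")
    samples: List[SamplePatch] = []
    for si, image in enumerate(images):
        subgraphs = extract_subgraphs(
            image, p.subgraphs_per_slide, p.subgraph_size, seed + 1000 * si
        )
        for gi, sub in enumerate(subgraphs):
            try:
                tissue = cluster_pixels(sub, k=3, seed=seed + 1000 * si + gi)
            except ValueError as exc:
                logger.warning("skipping degenerate sub-graph %d/%d: %s", si, gi, exc)
                continue
            bounds = channel_bounds(sub)
            for patch in select_label_patches(
                tissue, p.label_size, p.min_frac, p.max_frac
            ):
                sample = extract_padded_sample(
                    sub, patch, provenance=f"slide{si}/sub{gi}@{patch.origin}"
                )
                sample.image = normalize_patch(sample.image, bounds=bounds)
                samples.append(sample)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))[: p.max_patches]
    samples = [samples[i] for i in order]
    n_val = len(samples) // 3  # train : validation = 2 : 1
    return samples[n_val:], samples[:n_val]


def save_patch_dataset(
    out_dir: str | Path,
    images: Sequence[np.ndarray],
    config: PipelineConfig,
) -> Path:
    """Build patches from raw slides and persist them as PNGs + JSON manifest.

    Raw 8-bit crops are stored (PNG is lossless only for integers); the
    normalization bounds of each patch's source sub-graph are recorded in the
    manifest so loading reproduces the exact float patches used in memory.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    p = config.pseudo
    seed = config.stage_seed("pseudo-labels")
    entries = []
    idx = 0
    for si, image in enumerate(images):
        subgraphs = extract_subgraphs(
            image, p.subgraphs_per_slide, p.subgraph_size, seed + 1000 * si
        )
        for gi, sub in enumerate(subgraphs):
            try:
                tissue = cluster_pixels(sub, k=3, seed=seed + 1000 * si + gi)
            except ValueError as exc:
                logger.warning("skipping degenerate sub-graph %d/%d: %s", si, gi, exc)
                continue
            lo, hi = channel_bounds(sub)
            for patch in select_label_patches(
                tissue, p.label_size, p.min_frac, p.max_frac
            ):
                sample = extract_padded_sample(sub, patch)
                img_name = f"sample_{idx:05d}.png"
                lab_name = f"label_{idx:05d}.png"
                nio.write_image(out_dir / img_name, sample.image)
                nio.write_mask(out_dir / lab_name, sample.label.astype(np.int32))
                entries.append(
                    {
                        "sample": img_name,
                        "label": lab_name,
                        "n": p.label_size,
                        "provenance": f"slide{si}/sub{gi}@{list(patch.origin)}",
                        "ref_lo": [float(v) for v in lo],
                        "ref_hi": [float(v) for v in hi],
                    }
                )
                idx += 1
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(entries))[: p.max_patches]
    entries = [entries[i] for i in order]
    n_val = len(entries) // 3
    for k, entry in enumerate(entries):
        entry["split"] = "validation" if k < n_val else "train"
    nio.write_manifest(out_dir / "manifest.json", entries)
    return out_dir


def load_patch_dataset(
    dataset_dir: str | Path,
) -> Tuple[List[SamplePatch], List[SamplePatch]]:
    """Load a persisted patch dataset back into normalized sample patches."""
    dataset_dir = Path(dataset_dir)
    entries = nio.read_manifest(dataset_dir / "manifest.json")
    train, val = [], []
    for entry in entries:
        image = nio.read_image(dataset_dir / entry["sample"])
        label = nio.read_mask(dataset_dir / entry["label"]).astype(bool)
        bounds = (np.asarray(entry["ref_lo"]), np.asarray(entry["ref_hi"]))
        sample = SamplePatch(
            image=normalize_patch(image, bounds=bounds),
            label=label,
            provenance=entry.get("provenance", ""),
        )
        (val if entry.get("split") == "validation" else train).append(sample)
    return train, val


def _log_stage(name: str, start: float) -> None:
    logger.info("stage %-14s done in %.1f s", name, time.perf_counter() - start)


def run_end_to_end(
    config: PipelineConfig, out_dir: str | Path
) -> Tuple[Path, dict]:
    """Execute the full pipeline; returns the run directory and the report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "config.yaml")

    t0 = time.perf_counter()
    train_slides = generate_slides(config, "train")
    test_slides = generate_slides(config, "test")
    slides_dir = out_dir / "slides"
    slides_dir.mkdir(exist_ok=True)
    manifest = []
    for split, slides in (("train", train_slides), ("test", test_slides)):
        for i, (image, mask) in enumerate(slides):
            img_path = slides_dir / f"{split}_{i:03d}.png"
            msk_path = slides_dir / f"{split}_{i:03d}_mask.png"
            nio.write_image(img_path, image)
            nio.write_mask(msk_path, mask)
            manifest.append(
                {"image": img_path.name, "mask": msk_path.name, "split": split}
            )
    nio.write_manifest(slides_dir / "manifest.json", manifest)
    _log_stage("synth", t0)

    t0 = time.perf_counter()
    train_patches, val_patches = build_patches(
        [img for img, _ in train_slides], config
    )
    if not train_patches or not val_patches:
        raise RuntimeError(
            "pseudo-label stage produced an empty split; relax the eligibility "
            "bounds or provide more slides"
        )
    _log_stage("build-dataset", t0)
    logger.info(
        "patch dataset: %d train / %d validation", len(train_patches), len(val_patches)
    )

    t0 = time.perf_counter()
    train_cfg = dataclasses.replace(
        config.training, seed=config.stage_seed("train")
    )
    mixup_cfg = dataclasses.replace(
        config.mixup, seed=config.stage_seed("mixup")
    )
    model, history = dynamic_train(
        train_patches, val_patches, config.network, train_cfg, mixup_cfg
    )
    model.save(out_dir / "checkpoint.npz")
    pd.DataFrame(history.to_rows()).to_csv(out_dir / "history.csv", index=False)
    (out_dir / "history_meta.json").write_text(
        json.dumps({"stop_reason": history.stop_reason, "final_p": history.final_p})
    )
    _log_stage("train", t0)

    t0 = time.perf_counter()
    pred_dir = out_dir / "predictions"
    pred_dir.mkdir(exist_ok=True)
    reports: List[MetricsReport] = []
    for i, (image, gt_mask) in enumerate(test_slides):
        prob, mask, instances = sliding_window_segment(model, image)
        np.save(pred_dir / f"test_{i:03d}_prob.npy", prob.astype(np.float32))
        nio.write_mask(pred_dir / f"test_{i:03d}_binary.png", mask.astype(np.int32))
        nio.write_mask(pred_dir / f"test_{i:03d}_instances.png", instances)
        reports.append(evaluate_masks(instances, gt_mask))
    _log_stage("segment", t0)

    per_image = [r.as_dict() for r in reports]
    aggregate = {
        key: float(np.mean([r[key] for r in per_image]))
        for key in ("f1", "iou", "dice", "aji")
    }
    report = {
        "per_image": per_image,
        "aggregate": aggregate,
        "n_train_patches": len(train_patches),
        "n_val_patches": len(val_patches),
        "epochs_run": len(history.records),
        "stop_reason": history.stop_reason,
    }
    with open(out_dir / "metrics_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    pd.DataFrame(per_image).to_csv(out_dir / "metrics_report.csv", index=False)
    return out_dir, report
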