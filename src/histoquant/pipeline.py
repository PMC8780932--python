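"""Batch orchestration behind the CLI: train, run, evaluate, simulate.

Each function here is a plain library call; the CLI module only parses flags
and maps exceptions to exit codes. No function mutates its inputs, and a
run's effective configuration is always snapshotted next to its outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as hio
from .color_model import (
    ColorTrainingTable,
    Palette,
    RGBImage,
    accumulate_training,
    derive_palette,
    merge_training,
)
from .config import RunConfig
from .errors import ConfigurationError, HistoquantError
from .evaluation import consensus_standard, evaluate_method
from .quantification import (
    image_report,
    reports_to_dataframe,
    summarize_batch,
    summary_to_dataframe,
)
from .segmentation import classify_pixels, flag_edge_images, postprocess, render_overlay
from .synthetic import SyntheticSpec, generate, generate_training_pair

logger = logging.getLogger("histoquant")


# ---------------------------------------------------------------------------
# train
# ---------------------------------------------------------------------------

def train_palette(
    annotation_files: Sequence[str | Path],
    images_dir: str | Path,
    levels: int = 64,
    threshold: float = 0.5,
    unseen_policy: str = "negative",
    merge_with: str | Path | None = None,
) -> tuple[ColorTrainingTable, Palette]:
    """Accumulate a color table from annotation files and derive the palette.

    ``merge_with`` merges a previously saved table before derivation — the
    second training pass that refines a palette with new regions.
    """
    annotations = []
    for f in annotation_files:
        annotations.extend(hio.load_annotations(f))
    images_dir = Path(images_dir)
    images = []
    for image_id in sorted({a.image_id for a in annotations}):
        candidates = [
            p for p in hio.find_images(images_dir) if p.stem == image_id
        ]
        if not candidates:
            raise ConfigurationError(
                f"annotations reference image {image_id!r} but no such file exists "
                f"under {images_dir}"
            )
        images.append(hio.read_rgb_image(candidates[0]))
    table = accumulate_training(images, annotations, levels=levels)
    if merge_with is not None:
        table = merge_training(ColorTrainingTable.load(merge_with), table)
    palette = derive_palette(table, threshold=threshold, unseen_policy=unseen_policy)
    for c in palette.classes:
        logger.info(
            "class %s: %d positive colors", c, len(palette.positive_colors[c])
        )
    return table, palette


# ---------------------------------------------------------------------------
# run
# ---------------------------------------------------------------------------

@dataclass
class BatchResult:
    n_processed: int = 0
    n_failed: int = 0
    n_edge_excluded: int = 0
    failures: list[str] = field(default_factory=list)
    reports: pd.DataFrame | None = None
    summary: pd.DataFrame | None = None


def run_batch(config: RunConfig) -> BatchResult:
    """Classify, clean, quantify and export a whole image set.

    Unreadable files are logged and counted, never abort the batch. Outputs
    per image: a label PNG, one binary mask PNG per class, an optional
    overlay; plus reports.csv, summary.csv and effective_config.json.
    """
    palette = Palette.load(config.palette)
    files = hio.find_images(config.input)
    if not files:
        raise ConfigurationError(f"no input images match {config.input!r}")
    out_dir = Path(config.output)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.save(out_dir / "effective_config.json")

    result = BatchResult()
    images: list[RGBImage] = []
    for f in files:
        try:
            images.append(hio.read_rgb_image(f))
        except Exception as exc:
            logger.error("image %s: unreadable (%s)", f.name, exc)
            result.n_failed += 1
            result.failures.append(str(f))

    if config.edge_filter:
        images, edge = flag_edge_images(
            images, config.segmentation, config.edge_max_background_fraction
        )
        result.n_edge_excluded = len(edge)
        for im in edge:
            logger.info("image %s: excluded as edge field", im.id)

    colors = config.resolve_overlay_colors(palette.classes)
    reports = []
    for im in images:
        t0 = time.perf_counter()
        try:
            mask = classify_pixels(im, palette)
            mask = postprocess(im, mask, config.segmentation)
            report = image_report(mask, config.segmentation, config.denominator_mode)
            hio.write_label_mask(mask, out_dir / f"{im.id}__labels.png")
            for name in palette.classes:
                hio.write_mask(
                    mask.class_mask(name), out_dir / f"{im.id}__{name}_mask.png"
                )
            if config.overlay:
                overlay = render_overlay(im, mask, colors, config.overlay_opacity)
                hio.write_image(overlay, out_dir / f"{im.id}__overlay.png")
            reports.append(report)
            result.n_processed += 1
            logger.info(
                "image %s: quantified in %.2fs", im.id, time.perf_counter() - t0
            )
        except HistoquantError as exc:
            logger.error("image %s: failed (%s)", im.id, exc)
            result.n_failed += 1
            result.failures.append(im.id)

    if reports:
        result.reports = reports_to_dataframe(reports)
        result.reports.to_csv(out_dir / "reports.csv", index=False)
        result.summary = summary_to_dataframe(summarize_batch(reports))
        result.summary.to_csv(out_dir / "summary.csv", index=False)
    logger.info(
        "batch done: %d processed, %d failed, %d edge-excluded",
        result.n_processed,
        result.n_failed,
        result.n_edge_excluded,
    )
    return result


# ---------------------------------------------------------------------------
# evaluate
# ---------------------------------------------------------------------------

def evaluate_dirs(
    predicted_dir: str | Path,
    reference_dirs: Sequence[str | Path],
    out_csv: str | Path | None = None,
    consensus_rule: str = "intersection",
) -> pd.DataFrame:
    """Pair mask files by filename, build a consensus reference if several
    reference sets are given, and score per image plus pooled."""
    pred_files = {p.name: p for p in hio.find_images(predicted_dir)}
    ref_sets = [{p.name: p for p in hio.find_images(d)} for d in reference_dirs]
    if not pred_files:
        raise ConfigurationError(f"no predicted masks under {predicted_dir}")
    common = set(pred_files)
    for rs in ref_sets:
        common &= set(rs)
    unpaired = sorted(set(pred_files) - common)
    if not common:
        raise ConfigurationError("no filenames shared by predicted and reference sets")
    if unpaired:
        logger.warning("unpaired predicted masks skipped: %s", unpaired)

    predicted = {name: hio.read_mask(pred_files[name]) for name in sorted(common)}
    reference = {}
    for name in sorted(common):
        masks = [hio.read_mask(rs[name]) for rs in ref_sets]
        reference[name] = (
            masks[0] if len(masks) == 1 else consensus_standard(masks, consensus_rule)
        )
    table, _pooled = evaluate_method(predicted, reference)
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return table


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def simulate_fixtures(
    spec: SyntheticSpec,
    out_dir: str | Path,
    n_images: int = 1,
    with_training_pair: bool = True,
) -> dict:
    """Write images, truth masks, annotations, metadata and a hash manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    metadata: dict[str, dict] = {}

    for i in range(n_images):
        sub = dataclasses.replace(spec, seed=int(spec.seed + i))
        image, truths, meta = generate(sub, image_id=f"image_{i:03d}")
        hio.write_image(image, out_dir / f"{image.id}.png")
        metadata[image.id] = meta
        for name, t in truths.items():
            hio.write_mask(t, out_dir / f"truth_{name}__{image.id}.png")

    if with_training_pair:
        images, annotations, metas = generate_training_pair(spec)
        for im, meta in zip(images, metas):
            hio.write_image(im, out_dir / f"{im.id}.png")
            metadata[im.id] = meta
        hio.save_annotations(annotations, out_dir / "annotations.json")

    (out_dir / "metadata.json").write_text(json.dumps(metadata, indent=1))
    for f in sorted(out_dir.iterdir()):
        if f.name == "manifest.json" or not f.is_file():
            continue
        manifest[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
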