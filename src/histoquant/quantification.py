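"""Quantitative readouts from masks: percent positive area, component
statistics, class-area ratios, and per-batch summaries.

Percent positive area is the per-image deliverable — one value per image
field per class — with the denominator either the whole image (default) or
tissue only (non-background pixels). Batch summaries report order statistics
over image fields; the median uses midpoint interpolation for even counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skimage import measure

from .errors import ConfigurationError, UndefinedDenominatorError, UndefinedRatioError
from .segmentation import LabelMask, SegmentationParams

DENOMINATOR_MODES = ("whole_image", "tissue_only")


def percent_positive_area(
    mask: np.ndarray,
    denominator_mode: str = "whole_image",
    background: np.ndarray | None = None,
) -> float:
    """100 * positive pixels / denominator pixels."""
    if denominator_mode not in DENOMINATOR_MODES:
        raise ConfigurationError(f"unknown denominator_mode {denominator_mode!r}")
    mask = np.asarray(mask, dtype=bool)
    if denominator_mode == "tissue_only":
        if background is None:
            raise ConfigurationError("tissue_only mode requires a background mask")
        denom = int((~np.asarray(background, dtype=bool)).sum())
        if denom == 0:
            raise UndefinedDenominatorError("image has zero tissue pixels")
    else:
        denom = mask.size
    return 100.0 * int(mask.sum()) / denom


def class_area_ratio(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Area of class a over area of class b (e.g. brown over blue nuclei)."""
    a = int(np.asarray(mask_a, dtype=bool).sum())
    b = int(np.asarray(mask_b, dtype=bool).sum())
    if b == 0:
        raise UndefinedRatioError("denominator class mask is empty")
    return a / b


@dataclass
class ClassStats:
    percent_positive_area: float
    positive_pixel_count: int
    component_count: int
    component_area_min: float  # NaN when no components
    component_area_median: float
    component_area_max: float


@dataclass
class ImageReport:
    """Per-image quantification record, one entry per positive class."""

    image_id: str
    classes: dict[str, ClassStats]
    denominator_mode: str
    tissue_fraction: float
    denominator_pixels: int


def image_report(
    mask: LabelMask,
    params: SegmentationParams | None = None,
    denominator_mode: str = "whole_image",
) -> ImageReport:
    """Quantify a label mask: per-class percent area and component stats.

    Background pixels (label -1) define the tissue fraction; in
    ``tissue_only`` mode they are removed from the denominator.
    """
    if denominator_mode not in DENOMINATOR_MODES:
        raise ConfigurationError(f"unknown denominator_mode {denominator_mode!r}")
    params = params or SegmentationParams()
    bg = mask.background_mask
    n_total = mask.values.size
    tissue_fraction = 1.0 - int(bg.sum()) / n_total
    stats: dict[str, ClassStats] = {}
    for name in mask.classes:
        cls = mask.class_mask(name)
        pct = percent_positive_area(cls, denominator_mode, background=bg)
        labels, n_comp = measure.label(
            cls, connectivity=params.skimage_connectivity, return_num=True
        )
        if n_comp:
            areas = np.bincount(labels.ravel())[1:]
            amin, amed, amax = float(areas.min()), float(np.median(areas)), float(areas.max())
        else:
            amin = amed = amax = math.nan
        stats[name] = ClassStats(
            percent_positive_area=pct,
            positive_pixel_count=int(cls.sum()),
            component_count=int(n_comp),
            component_area_min=amin,
            component_area_median=amed,
            component_area_max=amax,
        )
    denom = n_total if denominator_mode == "whole_image" else n_total - int(bg.sum())
    return ImageReport(
        image_id=mask.image_id,
        classes=stats,
        denominator_mode=denominator_mode,
        tissue_fraction=tissue_fraction,
        denominator_pixels=denom,
    )


@dataclass
class BatchSummary:
    """Per-class distribution of percent positive area over image fields."""

    n_images: int
    classes: dict[str, dict] = field(default_factory=dict)
    # each class entry: values, median, q1, q3, min, max


def summarize_batch(reports: Sequence[ImageReport]) -> BatchSummary:
    """Order statistics of per-image percent areas, preserving the raw lists.

    Permutation-invariant over reports; quartiles use linear interpolation.
    """
    if not reports:
        raise ConfigurationError("summarize_batch needs at least one report")
    class_names = list(reports[0].classes)
    for r in reports[1:]:
        if list(r.classes) != class_names:
            raise ConfigurationError("reports disagree on class declarations")
    summary = BatchSummary(n_images=len(reports))
    for name in class_names:
        values = [r.classes[name].percent_positive_area for r in reports]
        arr = np.asarray(values, dtype=float)
        q1, q3 = np.percentile(arr, [25, 75])
        summary.classes[name] = {
            "values": values,
            "median": float(np.median(arr)),
            "q1": float(q1),
            "q3": float(q3),
            "min": float(arr.min()),
            "max": float(arr.max()),
        }
    return summary


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------

REPORT_COLUMNS = [
    "image_id",
    "class",
    "percent_positive_area",
    "positive_pixel_count",
    "component_count",
    "component_area_min",
    "component_area_median",
    "component_area_max",
    "denominator_mode",
    "denominator_pixels",
    "tissue_fraction",
]


def reports_to_dataframe(reports: Iterable[ImageReport]) -> pd.DataFrame:
    """One row per (image, class); missing values stay NaN, never silently 0."""
    rows = []
    for r in reports:
        for name, s in r.classes.items():
            rows.append(
                {
                    "image_id": r.image_id,
                    "class": name,
                    "percent_positive_area": s.percent_positive_area,
                    "positive_pixel_count": s.positive_pixel_count,
                    "component_count": s.component_count,
                    "component_area_min": s.component_area_min,
                    "component_area_median": s.component_area_median,
                    "component_area_max": s.component_area_max,
                    "denominator_mode": r.denominator_mode,
                    "denominator_pixels": r.denominator_pixels,
                    "tissue_fraction": r.tissue_fraction,
                }
            )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def summary_to_dataframe(summary: BatchSummary) -> pd.DataFrame:
    rows = []
    for name, s in summary.classes.items():
        rows.append(
            {
                "class": name,
                "n_images": summary.n_images,
                "median": s["median"],
                "q1": s["q1"],
                "q3": s["q3"],
                "min": s["min"],
                "max": s["max"],
            }
        )
    return pd.DataFrame(rows, columns=["class", "n_images", "median", "q1", "q3", "min", "max"])
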