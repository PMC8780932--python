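"""Trainable color model: quantized color map and positive-color list.

The classifier at the heart of this package is deliberately transparent: every
24-bit RGB color is quantized into a coarse per-channel bin, annotated training
regions accumulate per-class pixel counts for each quantized color (the *color
table*), and a color becomes "positive" for a class when that class holds more
than a configurable fraction of the color's observations (the *palette*).
Classification of a full image is then a constant-time lookup per pixel.

Conventions that every downstream count depends on
--------------------------------------------------
* Quantization: bin index = ``floor(channel * levels / 256)`` per channel,
  uniform bins over [0, 255]. ``levels`` between 2 and 256.
* Pixel geometry: 0-based pixel (row i, col j) has its center at
  ``(x, y) = (j + 0.5, i + 0.5)``, origin at the top-left corner.
* Polygon membership: even-odd (ray crossing) rule evaluated at pixel
  centers, with strict inequalities so boundaries are half-open — two
  polygons sharing an edge never both claim the same pixel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    AnnotationError,
    ConfigurationError,
    EmptyPaletteError,
    EmptyRegionError,
    IncompatibleTablesError,
    TrainingError,
)

NEGATIVE_LABEL = "negative"


# ---------------------------------------------------------------------------
# basic types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RGBImage:
    """An 8-bit RGB raster plus the identifier annotations refer to."""

    pixels: np.ndarray  # (H, W, 3) uint8
    id: str

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ConfigurationError(
                f"image {self.id!r}: expected (H, W, 3) array, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ConfigurationError(f"image {self.id!r}: empty raster")
        object.__setattr__(self, "pixels", px.astype(np.uint8, copy=False))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class RegionAnnotation:
    """A labeled polygon drawn on a training image.

    ``label`` is either a declared positive class name or the reserved name
    ``"negative"``. Vertices are (x, y) in pixel coordinates, 0-based,
    origin top-left.
    """

    image_id: str
    label: str
    polygon: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        poly = tuple((float(x), float(y)) for x, y in self.polygon)
        if len(poly) < 3:
            raise AnnotationError(
                f"annotation on {self.image_id!r}: polygon needs >= 3 vertices, got {len(poly)}"
            )
        object.__setattr__(self, "polygon", poly)


# ---------------------------------------------------------------------------
# quantization
# ---------------------------------------------------------------------------

def _check_levels(levels: int) -> int:
    levels = int(levels)
    if not 2 <= levels <= 256:
        raise ConfigurationError(f"levels must be in [2, 256], got {levels}")
    return levels


def quantize_color(color: Sequence[int], levels: int) -> tuple[int, int, int]:
    """Map one (r, g, b) triple to its per-channel bin indices."""
    levels = _check_levels(levels)
    r, g, b = (int(c) for c in color)
    for c in (r, g, b):
        if not 0 <= c <= 255:
            raise ConfigurationError(f"channel value {c} outside [0, 255]")
    return (r * levels // 256, g * levels // 256, b * levels // 256)


def quantize_image(pixels: np.ndarray, levels: int) -> np.ndarray:
    """Quantize an (H, W, 3) uint8 image to an (H, W) array of color codes.

    The code of bins (rq, gq, bq) is ``(rq * levels + gq) * levels + bq``.
    """
    levels = _check_levels(levels)
    q = (pixels.astype(np.int64) * levels) >> 8
    return (q[..., 0] * levels + q[..., 1]) * levels + q[..., 2]


def code_to_bins(code: int, levels: int) -> tuple[int, int, int]:
    code = int(code)
    return (code // (levels * levels), (code // levels) % levels, code % levels)


def bins_to_code(bins: Sequence[int], levels: int) -> int:
    rq, gq, bq = (int(b) for b in bins)
    return (rq * levels + gq) * levels + bq


# ---------------------------------------------------------------------------
# polygon rasterization
# ---------------------------------------------------------------------------

def rasterize_polygon(
    polygon: Sequence[tuple[float, float]], shape: tuple[int, int]
) -> np.ndarray:
    """Rasterize a polygon to a boolean mask by the even-odd rule.

    A pixel is inside iff its center (j + 0.5, i + 0.5) is inside the polygon
    under the even-odd rule. The ray-crossing test uses strict inequalities,
    which yields a half-open boundary convention: pixels whose centers lie
    exactly on a shared edge are claimed by at most one of two abutting
    polygons.
    """
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 2:
        raise AnnotationError(f"polygon must be an (N>=3, 2) vertex list, got {poly.shape}")
    H, W = int(shape[0]), int(shape[1])
    if (poly[:, 0] < 0).any() or (poly[:, 0] > W).any() or (poly[:, 1] < 0).any() or (
        poly[:, 1] > H
    ).any():
        raise AnnotationError(
            f"polygon vertices outside image bounds {W}x{H}: "
            f"x in [{poly[:, 0].min():g}, {poly[:, 0].max():g}], "
            f"y in [{poly[:, 1].min():g}, {poly[:, 1].max():g}]"
        )

    # restrict work to the polygon's bounding box
    j0 = max(int(np.floor(poly[:, 0].min() - 0.5)), 0)
    j1 = min(int(np.ceil(poly[:, 0].max() + 0.5)), W)
    i0 = max(int(np.floor(poly[:, 1].min() - 0.5)), 0)
    i1 = min(int(np.ceil(poly[:, 1].max() + 0.5)), H)

    mask = np.zeros((H, W), dtype=bool)
    if j1 <= j0 or i1 <= i0:
        raise EmptyRegionError("polygon covers no pixel centers")

    xs = np.arange(j0, j1, dtype=float) + 0.5
    ys = np.arange(i0, i1, dtype=float) + 0.5
    X, Y = np.meshgrid(xs, ys)
    inside = np.zeros(X.shape, dtype=bool)

    n = poly.shape[0]
    for k in range(n):
        xa, ya = poly[k - 1]
        xb, yb = poly[k]
        if ya == yb:
            continue
        crosses = (ya > Y) != (yb > Y)
        with np.errstate(invalid="ignore"):
            xint = xa + (Y - ya) * (xb - xa) / (yb - ya)
        inside ^= crosses & (X < xint)

    if not inside.any():
        raise EmptyRegionError("polygon covers no pixel centers")
    mask[i0:i1, j0:j1] = inside
    return mask


def rasterize_region(annotation: RegionAnnotation, image: RGBImage) -> np.ndarray:
    """Rasterize one annotation against the image it references."""
    if annotation.image_id != image.id:
        raise AnnotationError(
            f"annotation references image {annotation.image_id!r}, got {image.id!r}"
        )
    return rasterize_polygon(annotation.polygon, image.shape)


# ---------------------------------------------------------------------------
# training table
# ---------------------------------------------------------------------------

@dataclass
class ColorTrainingTable:
    """Per-class pixel counts for each observed quantized color.

    ``counts`` maps a color code to an int64 vector of length
    ``len(classes) + 1``; the last slot is the negative class. Tables with
    equal ``levels`` and ``classes`` merge by entrywise addition, which makes
    a second training pass a plain merge.
    """

    levels: int
    classes: tuple[str, ...]
    counts: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def n_slots(self) -> int:
        return len(self.classes) + 1

    @property
    def total_pixels(self) -> int:
        return int(sum(int(v.sum()) for v in self.counts.values()))

    def class_index(self, label: str) -> int:
        if label == NEGATIVE_LABEL:
            return len(self.classes)
        return self.classes.index(label)

    def add_pixels(self, codes: np.ndarray, label: str) -> None:
        idx = self.class_index(label)
        uniq, n = np.unique(np.asarray(codes).ravel(), return_counts=True)
        for code, cnt in zip(uniq.tolist(), n.tolist()):
            vec = self.counts.get(code)
            if vec is None:
                vec = np.zeros(self.n_slots, dtype=np.int64)
                self.counts[code] = vec
            vec[idx] += cnt

    def scaled(self, factor: int) -> "ColorTrainingTable":
        if factor < 1:
            raise ConfigurationError("scale factor must be a positive integer")
        return ColorTrainingTable(
            self.levels,
            self.classes,
            {c: v * int(factor) for c, v in self.counts.items()},
        )

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        entries = []
        for code in sorted(self.counts):
            vec = self.counts[code]
            entries.append(
                {
                    "color": list(code_to_bins(code, self.levels)),
                    "counts": {
                        **{c: int(vec[i]) for i, c in enumerate(self.classes)},
                        NEGATIVE_LABEL: int(vec[-1]),
                    },
                }
            )
        return {"levels": self.levels, "classes": list(self.classes), "entries": entries}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ColorTrainingTable":
        levels = _check_levels(d["levels"])
        classes = tuple(d["classes"])
        table = cls(levels, classes)
        for entry in d["entries"]:
            code = bins_to_code(entry["color"], levels)
            vec = np.zeros(len(classes) + 1, dtype=np.int64)
            for i, c in enumerate(classes):
                vec[i] = int(entry["counts"].get(c, 0))
            vec[-1] = int(entry["counts"].get(NEGATIVE_LABEL, 0))
            table.counts[code] = vec
        return table

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ColorTrainingTable":
        return cls.from_dict(json.loads(Path(path).read_text()))


def accumulate_training(
    images: Iterable[RGBImage],
    annotations: Iterable[RegionAnnotation],
    levels: int = 64,
    classes: Sequence[str] | None = None,
) -> ColorTrainingTable:
    """Accumulate the color table from annotated regions.

    Every pixel contributes one count per (pixel, region) membership under the
    region's label; overlapping regions of different labels soften the model
    rather than raising. Requires at least one positive and one negative
    region overall.
    """
    levels = _check_levels(levels)
    images = list(images)
    annotations = list(annotations)
    by_id = {im.id: im for im in images}

    labels = {a.label for a in annotations}
    positives = sorted(labels - {NEGATIVE_LABEL})
    if classes is None:
        classes = positives
    else:
        classes = list(classes)
        unknown = set(positives) - set(classes)
        if unknown:
            raise AnnotationError(f"annotations use undeclared classes: {sorted(unknown)}")
    if not positives:
        raise TrainingError("no positive regions in training annotations")
    if NEGATIVE_LABEL not in labels:
        raise TrainingError("no negative regions in training annotations")

    table = ColorTrainingTable(levels, tuple(classes))
    code_cache: dict[str, np.ndarray] = {}
    for ann in annotations:
        image = by_id.get(ann.image_id)
        if image is None:
            raise AnnotationError(f"annotation references missing image {ann.image_id!r}")
        mask = rasterize_region(ann, image)
        codes = code_cache.get(image.id)
        if codes is None:
            codes = quantize_image(image.pixels, levels)
            code_cache[image.id] = codes
        table.add_pixels(codes[mask], ann.label)
    return table


def merge_training(
    base: ColorTrainingTable, update: ColorTrainingTable
) -> ColorTrainingTable:
    """Entrywise sum of two compatible tables (the re-training pass)."""
    if base.levels != update.levels:
        raise IncompatibleTablesError(
            f"cannot merge tables with levels {base.levels} and {update.levels}"
        )
    if base.classes != update.classes:
        raise IncompatibleTablesError(
            f"cannot merge tables with classes {base.classes} and {update.classes}"
        )
    merged = ColorTrainingTable(base.levels, base.classes)
    for table in (base, update):
        for code, vec in table.counts.items():
            cur = merged.counts.get(code)
            if cur is None:
                merged.counts[code] = vec.copy()
            else:
                cur += vec
    return merged


# ---------------------------------------------------------------------------
# palette
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Palette:
    """The derived decision rule: per class, the set of positive color codes.

    ``negative_colors`` holds the observed colors assigned to no class; the
    ``nearest`` unseen policy needs them to know the label of every observed
    color. ``threshold`` is the positive-fraction cutoff used at derivation.
    """

    levels: int
    threshold: float
    classes: tuple[str, ...]
    positive_colors: dict[str, frozenset[int]]
    negative_colors: frozenset[int]
    unseen_policy: str = "negative"

    def __post_init__(self) -> None:
        if self.unseen_policy not in ("negative", "nearest"):
            raise ConfigurationError(f"unknown unseen_policy {self.unseen_policy!r}")
        if not 0.0 < self.threshold <= 1.0:
            raise ConfigurationError(f"threshold must be in (0, 1], got {self.threshold}")

    @property
    def observed_codes(self) -> frozenset[int]:
        out = set(self.negative_colors)
        for s in self.positive_colors.values():
            out |= s
        return frozenset(out)

    def label_of(self, code: int) -> str:
        for c in self.classes:
            if code in self.positive_colors[c]:
                return c
        return NEGATIVE_LABEL

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "levels": self.levels,
            "threshold": self.threshold,
            "unseen_policy": self.unseen_policy,
            "classes": list(self.classes),
            "positive_colors": {
                c: sorted(list(code_to_bins(k, self.levels)) for k in self.positive_colors[c])
                for c in self.classes
            },
            "negative_colors": sorted(
                list(code_to_bins(k, self.levels)) for k in self.negative_colors
            ),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Palette":
        levels = _check_levels(d["levels"])
        classes = tuple(d["classes"])
        return cls(
            levels=levels,
            threshold=float(d["threshold"]),
            classes=classes,
            positive_colors={
                c: frozenset(bins_to_code(b, levels) for b in d["positive_colors"][c])
                for c in classes
            },
            negative_colors=frozenset(
                bins_to_code(b, levels) for b in d.get("negative_colors", [])
            ),
            unseen_policy=d.get("unseen_policy", "negative"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "Palette":
        return cls.from_dict(json.loads(Path(path).read_text()))


def derive_palette(
    table: ColorTrainingTable,
    threshold: float = 0.5,
    unseen_policy: str = "negative",
) -> Palette:
    """Derive the positive-color list from a training table.

    A color joins class ``c`` iff ``c`` holds the strictly largest count among
    the positive classes (ties go negative) *and* ``count_c / total > threshold``
    where ``total`` sums all class counts for that color. The rule is
    scale-invariant in the counts, so merging a table with itself never
    changes the palette.
    """
    if not 0.0 < threshold <= 1.0:
        raise ConfigurationError(f"threshold must be in (0, 1], got {threshold}")
    if not table.counts:
        raise TrainingError("empty training table")

    positive: dict[str, set[int]] = {c: set() for c in table.classes}
    negative: set[int] = set()
    for code, vec in table.counts.items():
        total = int(vec.sum())
        if total == 0:
            continue
        class_counts = vec[:-1]
        best = int(np.argmax(class_counts))
        best_count = int(class_counts[best])
        tie = int((class_counts == best_count).sum()) > 1
        if not tie and best_count / total > threshold:
            positive[table.classes[best]].add(code)
        else:
            negative.add(code)

    if not any(positive.values()):
        raise EmptyPaletteError(
            "no color passed the positive-fraction threshold for any class; "
            "lower the threshold or revisit the training annotations"
        )
    return Palette(
        levels=table.levels,
        threshold=float(threshold),
        classes=table.classes,
        positive_colors={c: frozenset(s) for c, s in positive.items()},
        negative_colors=frozenset(negative),
        unseen_policy=unseen_policy,
    )
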