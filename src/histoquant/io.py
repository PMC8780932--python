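"""File I/O: images, masks, annotations, and config documents.

Input rasters are coerced to 8-bit RGB; multi-page TIFFs are rejected with a
clear error because the unit of analysis is a single field-of-view tile.
Masks are written as single-channel PNGs with 0/255 values; any nonzero pixel
reads back as positive.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from PIL import Image

from .color_model import RegionAnnotation, RGBImage
from .errors import AnnotationError, ImageFormatError
from .segmentation import BACKGROUND, LabelMask

logger = logging.getLogger("histoquant")

IMAGE_EXTENSIONS = (".png", ".tif", ".tiff", ".jpg", ".jpeg")


def read_rgb_image(path: str | Path) -> RGBImage:
    """Read a PNG/TIFF/JPEG as 8-bit RGB; the file stem is the image id."""
    path = Path(path)
    try:
        im = Image.open(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # PIL raises various subclasses for corrupt files
        raise ImageFormatError(f"{path}: cannot read image ({exc})") from exc
    with im:
        n_frames = getattr(im, "n_frames", 1)
        if n_frames > 1:
            raise ImageFormatError(
                f"{path}: multi-page image ({n_frames} pages); "
                "export single field-of-view tiles instead"
            )
        if im.mode != "RGB":
            warnings.warn(
                f"{path.name}: mode {im.mode} converted/rescaled to 8-bit RGB",
                stacklevel=2,
            )
            if im.mode in ("I;16", "I", "F"):
                arr = np.asarray(im, dtype=np.float64)
                top = arr.max() if arr.max() > 0 else 1.0
                arr8 = np.rint(arr / top * 255).astype(np.uint8)
                im = Image.fromarray(arr8).convert("RGB")
            else:
                im = im.convert("RGB")
        pixels = np.asarray(im, dtype=np.uint8)
    return RGBImage(pixels, path.stem)


def write_image(image: RGBImage, path: str | Path) -> None:
    Image.fromarray(image.pixels, mode="RGB").save(path)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    arr = (np.asarray(mask, dtype=bool) * np.uint8(255))
    Image.fromarray(arr, mode="L").save(path)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a single-channel mask image; any nonzero pixel is positive."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return arr > 0


def write_label_mask(mask: LabelMask, path: str | Path) -> None:
    """Label PNG: 0 negative, 1..K class indices, 255 background."""
    values = mask.values
    out = np.where(values == BACKGROUND, 255, values).astype(np.uint8)
    Image.fromarray(out, mode="L").save(path)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def load_annotations(path: str | Path) -> list[RegionAnnotation]:
    """Annotation JSON: list of {image, label, polygon: [[x, y], ...]}.

    ``image`` may be a filename; the extension is stripped so it matches the
    image id derived from the file stem.
    """
    doc = json.loads(Path(path).read_text())
    if not isinstance(doc, list):
        raise AnnotationError(f"{path}: expected a JSON list of annotations")
    out = []
    for i, entry in enumerate(doc):
        try:
            image_id = Path(str(entry["image"])).stem
            label = str(entry["label"])
            polygon = tuple((float(x), float(y)) for x, y in entry["polygon"])
        except (KeyError, TypeError, ValueError) as exc:
            raise AnnotationError(f"{path}: malformed annotation entry {i}: {exc}") from exc
        out.append(RegionAnnotation(image_id, label, polygon))
    return out


def save_annotations(annotations: Sequence[RegionAnnotation], path: str | Path) -> None:
    doc = [
        {
            "image": a.image_id,
            "label": a.label,
            "polygon": [[x, y] for x, y in a.polygon],
        }
        for a in annotations
    ]
    Path(path).write_text(json.dumps(doc, indent=1))


# ---------------------------------------------------------------------------
# config documents
# ---------------------------------------------------------------------------

def load_config_file(path: str | Path) -> dict:
    """YAML or JSON config document -> dict (YAML parses both)."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise AnnotationError(f"{path}: config must be a mapping")
    return doc


def find_images(input_spec: str | Path) -> list[Path]:
    """Resolve a directory or glob pattern to a sorted list of image files."""
    p = Path(input_spec)
    if p.is_dir():
        files = [f for f in sorted(p.iterdir()) if f.suffix.lower() in IMAGE_EXTENSIONS]
    else:
        files = sorted(p.parent.glob(p.name))
        files = [f for f in files if f.suffix.lower() in IMAGE_EXTENSIONS]
    return files
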