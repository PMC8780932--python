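"""Apply a palette (or an RGB box threshold) to images and clean the masks.

Post-processing order is fixed by default: slide-background exclusion, then
morphology, then component size filtering — size thresholds apply to the
final, cleaned components. Each step is configurable through
:class:`SegmentationParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure, morphology

from .color_model import NEGATIVE_LABEL, Palette, RGBImage, quantize_image
from .errors import ConfigurationError

BACKGROUND = -1  # label value for excluded slide background
NEGATIVE = 0  # label value for trained-negative pixels; classes are 1..K

_MORPH_STEPS = ("open", "close", "fill_holes")


@dataclass(frozen=True)
class SegmentationParams:
    """Mask post-processing settings.

    ``background_min_channel``: a pixel is slide background iff all three
    channels are >= this value (near-white test, default 220).
    ``morphology``: ordered (step, radius) pairs; steps are ``open``,
    ``close`` (disk structuring element) and ``fill_holes`` (radius ignored).
    ``max_component_area=None`` means unlimited.
    """

    background_exclusion: bool = False
    background_min_channel: int = 220
    min_component_area: int = 0
    max_component_area: int | None = None
    morphology: tuple[tuple[str, int], ...] = ()
    connectivity: int = 8

    def __post_init__(self) -> None:
        if not 0 <= self.background_min_channel <= 255:
            raise ConfigurationError(
                f"background_min_channel must be in [0, 255], got {self.background_min_channel}"
            )
        if self.min_component_area < 0:
            raise ConfigurationError("min_component_area must be >= 0")
        if self.max_component_area is not None and self.max_component_area < self.min_component_area:
            raise ConfigurationError("max_component_area < min_component_area")
        if self.connectivity not in (4, 8):
            raise ConfigurationError(f"connectivity must be 4 or 8, got {self.connectivity}")
        steps = tuple((str(s), int(r)) for s, r in self.morphology)
        for s, r in steps:
            if s not in _MORPH_STEPS:
                raise ConfigurationError(f"unknown morphology step {s!r}")
            if r < 0:
                raise ConfigurationError("morphology radius must be >= 0")
        object.__setattr__(self, "morphology", steps)

    @property
    def skimage_connectivity(self) -> int:
        return 1 if self.connectivity == 4 else 2


@dataclass
class LabelMask:
    """Per-pixel class labels: -1 background, 0 negative, 1..K positive classes."""

    values: np.ndarray  # (H, W) int16
    classes: tuple[str, ...]
    image_id: str = ""

    def class_mask(self, name: str) -> np.ndarray:
        return self.values == (self.classes.index(name) + 1)

    @property
    def background_mask(self) -> np.ndarray:
        return self.values == BACKGROUND

    def copy(self) -> "LabelMask":
        return LabelMask(self.values.copy(), self.classes, self.image_id)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _palette_lookup(palette: Palette) -> np.ndarray:
    """Dense code -> label table (0 negative, 1..K classes)."""
    lut = np.zeros(palette.levels**3, dtype=np.int16)
    for i, c in enumerate(palette.classes):
        codes = np.fromiter(palette.positive_colors[c], dtype=np.int64)
        if codes.size:
            lut[codes] = i + 1
    return lut


def _resolve_unseen_nearest(
    lut: np.ndarray, palette: Palette, unseen_codes: np.ndarray
) -> np.ndarray:
    """Label unseen codes by their nearest observed color in bin space.

    Euclidean distance over (rq, gq, bq); if the nearest observed colors are
    equidistant but disagree on the label, the pixel goes negative.
    """
    observed = np.fromiter(palette.observed_codes, dtype=np.int64)
    if observed.size == 0:
        return np.zeros(unseen_codes.size, dtype=np.int16)
    L = palette.levels

    def bins(codes: np.ndarray) -> np.ndarray:
        return np.stack([codes // (L * L), (codes // L) % L, codes % L], axis=1)

    tree = cKDTree(bins(observed))
    k = min(8, observed.size)
    dist, idx = tree.query(bins(unseen_codes), k=k)
    dist = np.atleast_2d(dist.T).T if dist.ndim == 1 else dist
    idx = np.atleast_2d(idx.T).T if idx.ndim == 1 else idx
    labels_obs = lut[observed]
    out = np.empty(unseen_codes.size, dtype=np.int16)
    for row in range(unseen_codes.size):
        at_min = dist[row] <= dist[row, 0] + 1e-9
        cand = np.unique(labels_obs[idx[row, at_min]])
        out[row] = cand[0] if cand.size == 1 else NEGATIVE
    return out


def classify_pixels(image: RGBImage, palette: Palette) -> LabelMask:
    """Label every pixel by palette lookup of its quantized color.

    Purely per-pixel and deterministic: permuting pixel positions permutes
    labels identically.
    """
    if not any(palette.positive_colors[c] for c in palette.classes):
        raise ConfigurationError("palette has no positive colors")
    codes = quantize_image(image.pixels, palette.levels)
    lut = _palette_lookup(palette)
    if palette.unseen_policy == "nearest":
        lut = lut.copy()
        present = np.unique(codes)
        observed = palette.observed_codes
        unseen = np.array([c for c in present.tolist() if c not in observed], dtype=np.int64)
        if unseen.size:
            lut[unseen] = _resolve_unseen_nearest(lut, palette, unseen)
    return LabelMask(lut[codes], palette.classes, image.id)


def threshold_baseline(
    image: RGBImage,
    r_range: tuple[int, int],
    g_range: tuple[int, int],
    b_range: tuple[int, int],
) -> np.ndarray:
    """Axis-aligned RGB box classifier: the standard color-threshold baseline.

    A pixel is positive iff each channel lies inside its inclusive interval.
    """
    for name, (lo, hi) in zip("rgb", (r_range, g_range, b_range)):
        if not (0 <= lo <= hi <= 255):
            raise ConfigurationError(f"empty or out-of-range {name} interval [{lo}, {hi}]")
    px = image.pixels.astype(np.int16)
    return (
        (px[..., 0] >= r_range[0]) & (px[..., 0] <= r_range[1])
        & (px[..., 1] >= g_range[0]) & (px[..., 1] <= g_range[1])
        & (px[..., 2] >= b_range[0]) & (px[..., 2] <= b_range[1])
    )


def best_box_threshold(
    pixels: np.ndarray, truth: np.ndarray, step: int = 8
) -> tuple[tuple[tuple[int, int], tuple[int, int], tuple[int, int]], float]:
    """Exhaustively grid-search the RGB box maximizing Youden's J.

    Channel bounds are restricted to multiples of ``step``. Since
    J = TP/P - FP/N for a box, the search maximizes the box sum of the
    density difference histogram via 3-D prefix sums plus a vectorized
    maximum-subarray scan over the blue axis — exhaustive over the grid,
    O(bins^4) instead of O(bins^6) naive.
    Returns ((r_lo, r_hi), (g_lo, g_hi), (b_lo, b_hi)) in channel units and J.
    """
    if 256 % step != 0:
        raise ConfigurationError("step must divide 256")
    bins = 256 // step
    px = np.asarray(pixels).reshape(-1, 3)
    t = np.asarray(truth).reshape(-1).astype(bool)
    P = int(t.sum())
    N = int((~t).sum())
    if P == 0 or N == 0:
        raise ConfigurationError("truth must contain both positive and negative pixels")
    q = px.astype(np.int64) // step
    codes = (q[:, 0] * bins + q[:, 1]) * bins + q[:, 2]
    hp = np.bincount(codes[t], minlength=bins**3).reshape(bins, bins, bins)
    hn = np.bincount(codes[~t], minlength=bins**3).reshape(bins, bins, bins)
    D = hp / P - hn / N

    rcum = np.zeros((bins + 1, bins, bins))
    np.cumsum(D, axis=0, out=rcum[1:])
    g0s, g1s = np.tril_indices(bins)  # g1s <= g0s? tril gives row>=col: rows are g1? fix below
    g_lo, g_hi = g1s, g0s  # tril_indices: first array is row index >= second; row=hi, col=lo

    best_j = -np.inf
    best = (0, 0, 0, 0)
    for r0 in range(bins):
        for r1 in range(r0, bins):
            slab = rcum[r1 + 1] - rcum[r0]  # (g, b)
            gcum = np.zeros((bins + 1, bins))
            np.cumsum(slab, axis=0, out=gcum[1:])
            M = gcum[g_hi + 1] - gcum[g_lo]  # (n_gpairs, bins) — all g intervals
            # vectorized Kadane over the b axis (non-empty subarrays)
            cur = M[:, 0].copy()
            bestv = cur.copy()
            for b in range(1, bins):
                cur = np.maximum(cur + M[:, b], M[:, b])
                np.maximum(bestv, cur, out=bestv)
            row = int(np.argmax(bestv))
            if bestv[row] > best_j:
                best_j = float(bestv[row])
                best = (r0, r1, int(g_lo[row]), int(g_hi[row]))

    # recover the b interval for the winning (r, g) choice
    r0, r1, g0, g1 = best
    vec = (rcum[r1 + 1] - rcum[r0])[g0 : g1 + 1].sum(axis=0)
    cur = best_sum = vec[0]
    start = b_lo = b_hi = 0
    for b in range(1, bins):
        if cur + vec[b] < vec[b]:
            cur = vec[b]
            start = b
        else:
            cur += vec[b]
        if cur > best_sum:
            best_sum = cur
            b_lo, b_hi = start, b
    box = (
        (r0 * step, (r1 + 1) * step - 1),
        (g0 * step, (g1 + 1) * step - 1),
        (b_lo * step, (b_hi + 1) * step - 1),
    )
    return box, best_j


# ---------------------------------------------------------------------------
# post-processing
# ---------------------------------------------------------------------------

def background_mask(image: RGBImage, params: SegmentationParams) -> np.ndarray:
    """Near-white slide background: all channels >= background_min_channel."""
    return (image.pixels >= params.background_min_channel).all(axis=2)


def exclude_background(
    image: RGBImage, mask: LabelMask, params: SegmentationParams
) -> LabelMask:
    """Relabel slide-background pixels; identity when exclusion is off."""
    if not params.background_exclusion:
        return mask.copy()
    out = mask.copy()
    out.values[background_mask(image, params)] = BACKGROUND
    return out


def filter_components(mask: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Drop connected components outside [min_component_area, max_component_area]."""
    if params.min_component_area <= 1 and params.max_component_area is None:
        return mask.copy()
    labels, n = measure.label(
        mask, connectivity=params.skimage_connectivity, return_num=True
    )
    if n == 0:
        return mask.copy()
    areas = np.bincount(labels.ravel())
    keep = areas >= params.min_component_area
    if params.max_component_area is not None:
        keep &= areas <= params.max_component_area
    keep[0] = False
    return keep[labels]


def apply_morphology(mask: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Apply the configured morphology steps in order.

    ``open``/``close`` use a disk of the given radius (radius 0 is the
    identity); ``fill_holes`` fills false regions not connected to the border.
    """
    out = np.asarray(mask, dtype=bool).copy()
    for step, radius in params.morphology:
        if step == "fill_holes":
            out = ndimage.binary_fill_holes(out)
        else:
            footprint = morphology.disk(radius)
            if step == "open":
                out = morphology.opening(out, footprint)
            else:
                out = morphology.closing(out, footprint)
    return out


def postprocess(
    image: RGBImage, mask: LabelMask, params: SegmentationParams
) -> LabelMask:
    """Full cleanup: background exclusion, then per-class morphology
    and size filtering, recombined into one label mask.

    Pixels a class loses become negative (never another class); class masks
    stay disjoint because each is processed independently and ``close`` /
    ``fill_holes`` gains are only kept where no other class claims the pixel
    first (classes are recombined in declaration order).
    """
    out = exclude_background(image, mask, params)
    values = out.values
    cleaned = np.where(values > 0, NEGATIVE, values).astype(np.int16)
    claimed = np.zeros(values.shape, dtype=bool)
    for i, _name in enumerate(out.classes):
        cls_mask = values == i + 1
        cls_mask = apply_morphology(cls_mask, params)
        cls_mask = filter_components(cls_mask, params)
        cls_mask &= values != BACKGROUND
        cls_mask &= ~claimed
        cleaned[cls_mask] = i + 1
        claimed |= cls_mask
    return LabelMask(cleaned, out.classes, out.image_id)


# ---------------------------------------------------------------------------
# overlays and edge filtering
# ---------------------------------------------------------------------------

def render_overlay(
    image: RGBImage,
    mask: LabelMask,
    colors: Mapping[str, Sequence[int]],
    opacity: float = 0.5,
) -> RGBImage:
    """Alpha-blend class colors over positive pixels; source pixels untouched."""
    if not 0.0 <= opacity <= 1.0:
        raise ConfigurationError(f"opacity must be in [0, 1], got {opacity}")
    missing = [c for c in mask.classes if c not in colors]
    if missing:
        raise ConfigurationError(f"no overlay color for classes: {missing}")
    out = image.pixels.astype(np.float64)
    for i, name in enumerate(mask.classes):
        sel = mask.values == i + 1
        color = np.asarray(colors[name], dtype=np.float64)
        out[sel] = (1.0 - opacity) * out[sel] + opacity * color
    blended = np.rint(out).clip(0, 255).astype(np.uint8)
    return RGBImage(blended, image.id + "__overlay")


def flag_edge_images(
    images: Iterable[RGBImage],
    params: SegmentationParams,
    max_background_fraction: float = 0.5,
) -> tuple[list[RGBImage], list[RGBImage]]:
    """Partition images into (continuous, edge) by slide-background fraction.

    An image is *edge* iff its near-white fraction exceeds the cutoff —
    an automated stand-in for manually sorting tiles that fall on the
    section boundary.
    """
    if not 0.0 <= max_background_fraction <= 1.0:
        raise ConfigurationError("max_background_fraction must be in [0, 1]")
    continuous: list[RGBImage] = []
    edge: list[RGBImage] = []
    for im in images:
        frac = float(background_mask(im, params).mean())
        (edge if frac > max_background_fraction else continuous).append(im)
    return continuous, edge
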