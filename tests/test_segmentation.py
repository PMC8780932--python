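"""Pixel classification, post-processing, baseline box threshold, overlays."""

import numpy as np
import pytest

from histoquant import (
    ConfigurationError,
    ImageFormatError,
    RGBImage,
    SegmentationParams,
    apply_morphology,
    best_box_threshold,
    classify_pixels,
    exclude_background,
    filter_components,
    flag_edge_images,
    postprocess,
    render_overlay,
    threshold_baseline,
)
from histoquant.color_model import Palette, bins_to_code, quantize_color
from histoquant.segmentation import BACKGROUND, LabelMask

from conftest import uniform_image


def palette_of(positive_rgbs, negative_rgbs=(), levels=16, classes=("pos",), policy="negative"):
    """Build a palette whose positive colors are the given raw RGB triples."""
    if isinstance(positive_rgbs, dict):
        pos = {
            c: frozenset(bins_to_code(quantize_color(v, levels), levels) for v in vs)
            for c, vs in positive_rgbs.items()
        }
        classes = tuple(positive_rgbs)
    else:
        pos = {
            classes[0]: frozenset(
                bins_to_code(quantize_color(v, levels), levels) for v in positive_rgbs
            )
        }
    neg = frozenset(bins_to_code(quantize_color(v, levels), levels) for v in negative_rgbs)
    return Palette(
        levels=levels,
        threshold=0.5,
        classes=classes,
        positive_colors=pos,
        negative_colors=neg,
        unseen_policy=policy,
    )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def test_uniform_images_classify_uniformly():
    pal = palette_of([(200, 40, 40)], negative_rgbs=[(20, 200, 20)])
    pos = classify_pixels(uniform_image((200, 40, 40)), pal)
    assert (pos.values == 1).all()
    neg = classify_pixels(uniform_image((20, 200, 20)), pal)
    assert (neg.values == 0).all()


def test_classification_counts_by_construction():
    px = np.empty((10, 10, 3), dtype=np.uint8)
    px[...] = (20, 200, 20)
    px[:3, :, :] = (200, 40, 40)  # 30 positive pixels
    pal = palette_of([(200, 40, 40)], negative_rgbs=[(20, 200, 20)])
    mask = classify_pixels(RGBImage(px, "img"), pal)
    assert int((mask.values == 1).sum()) == 30


def test_classification_is_per_pixel(rng):
    """Permuting pixel positions permutes labels identically."""
    px = rng.integers(0, 256, size=(8, 8, 3), dtype=np.uint8)
    pal = palette_of([(200, 40, 40), (100, 100, 100)], negative_rgbs=[(0, 0, 0)])
    base = classify_pixels(RGBImage(px, "a"), pal).values
    perm = rng.permutation(64)
    shuffled = px.reshape(64, 3)[perm].reshape(8, 8, 3)
    out = classify_pixels(RGBImage(shuffled, "b"), pal).values
    assert (out.reshape(64) == base.reshape(64)[perm]).all()


def test_classification_is_deterministic(rng):
    px = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
    pal = palette_of([(200, 40, 40)], negative_rgbs=[(20, 20, 20)], policy="nearest")
    a = classify_pixels(RGBImage(px, "x"), pal).values
    b = classify_pixels(RGBImage(px, "x"), pal).values
    assert (a == b).all()


def test_unseen_policy_negative_vs_nearest():
    # trained colors: red positive, dark negative; probe color near red
    probe = (190, 50, 50)
    pal_neg = palette_of([(200, 40, 40)], negative_rgbs=[(10, 10, 10)], levels=64)
    assert (classify_pixels(uniform_image(probe), pal_neg).values == 0).all()
    pal_near = palette_of(
        [(200, 40, 40)], negative_rgbs=[(10, 10, 10)], levels=64, policy="nearest"
    )
    assert (classify_pixels(uniform_image(probe), pal_near).values == 1).all()
    # probe near the dark negative color resolves negative
    assert (classify_pixels(uniform_image((30, 20, 20)), pal_near).values == 0).all()


def test_nearest_policy_tie_goes_negative():
    # observed: (0,0,0) positive and (4,0,0) negative at levels=64 (bin width 4);
    # probe (8,0,0) -> bins (2,0,0), equidistant from bins (0,0,0) and (1,0,0)...
    # use symmetric construction: positive at bin 0, negative at bin 2, probe at bin 1
    levels = 64
    pal = Palette(
        levels=levels,
        threshold=0.5,
        classes=("pos",),
        positive_colors={"pos": frozenset([bins_to_code((0, 0, 0), levels)])},
        negative_colors=frozenset([bins_to_code((2, 0, 0), levels)]),
        unseen_policy="nearest",
    )
    probe = uniform_image((4, 0, 0))  # bin (1,0,0), distance 1 to both
    assert (classify_pixels(probe, pal).values == 0).all()


# ---------------------------------------------------------------------------
# background exclusion
# ---------------------------------------------------------------------------

def test_background_threshold_is_inclusive_on_all_channels():
    params = SegmentationParams(background_exclusion=True, background_min_channel=220)
    pal = palette_of([(255, 255, 255), (219, 219, 219)], levels=256)
    white = classify_pixels(uniform_image((255, 255, 255)), pal)
    out = exclude_background(uniform_image((255, 255, 255)), white, params)
    assert (out.values == BACKGROUND).all()
    near = classify_pixels(uniform_image((219, 219, 219)), pal)
    out = exclude_background(uniform_image((219, 219, 219)), near, params)
    assert (out.values == 1).all()  # 219 < 220 on every channel: unchanged


def test_background_exclusion_off_is_identity():
    params = SegmentationParams(background_exclusion=False)
    pal = palette_of([(255, 255, 255)])
    mask = classify_pixels(uniform_image((255, 255, 255)), pal)
    out = exclude_background(uniform_image((255, 255, 255)), mask, params)
    assert (out.values == mask.values).all()


# ---------------------------------------------------------------------------
# component size filtering
# ---------------------------------------------------------------------------

def two_component_mask():
    mask = np.zeros((20, 20), dtype=bool)
    mask[1, 1:6] = True  # 5-px line
    mask[10:15, 10:20] = True  # 50-px rectangle
    return mask


def test_size_filter_examples():
    mask = two_component_mask()
    identity = filter_components(mask, SegmentationParams())
    assert (identity == mask).all()
    kept = filter_components(mask, SegmentationParams(min_component_area=10))
    assert int(kept.sum()) == 50
    empty = filter_components(mask, SegmentationParams(min_component_area=100))
    assert not empty.any()
    small_only = filter_components(
        mask, SegmentationParams(min_component_area=0, max_component_area=10)
    )
    assert int(small_only.sum()) == 5


def test_size_filter_monotone_in_min_area(rng):
    mask = rng.random((40, 40)) < 0.35
    prev = mask.sum() + 1
    for lo in (0, 2, 4, 8, 16, 32):
        kept = filter_components(mask, SegmentationParams(min_component_area=lo))
        assert kept.sum() <= prev
        prev = kept.sum()


def test_connectivity_matters_for_diagonal_touch():
    mask = np.zeros((4, 4), dtype=bool)
    mask[0, 0] = mask[1, 1] = True  # diagonal pair
    eight = filter_components(mask, SegmentationParams(min_component_area=2, connectivity=8))
    four = filter_components(mask, SegmentationParams(min_component_area=2, connectivity=4))
    assert eight.sum() == 2 and four.sum() == 0


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------

def naive_erode(mask, radius):
    """Disk erosion with zero padding, by exhaustive neighborhood check."""
    H, W = mask.shape
    out = np.zeros_like(mask)
    offsets = [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
        if dy * dy + dx * dx <= radius * radius
    ]
    for i in range(H):
        for j in range(W):
            out[i, j] = all(
                0 <= i + dy < H and 0 <= j + dx < W and mask[i + dy, j + dx]
                for dy, dx in offsets
            )
    return out


def naive_dilate(mask, radius):
    H, W = mask.shape
    out = np.zeros_like(mask)
    for i in range(H):
        for j in range(W):
            if mask[i, j]:
                for dy in range(-radius, radius + 1):
                    for dx in range(-radius, radius + 1):
                        if dy * dy + dx * dx <= radius * radius:
                            y, x = i + dy, j + dx
                            if 0 <= y < H and 0 <= x < W:
                                out[y, x] = True
    return out


def test_morphology_identity_and_fill_holes():
    mask = np.zeros((12, 12), dtype=bool)
    mask[1:11, 1:11] = True
    mask[5, 5] = False
    assert (apply_morphology(mask, SegmentationParams()) == mask).all()
    filled = apply_morphology(mask, SegmentationParams(morphology=(("fill_holes", 0),)))
    assert filled[5, 5] and int(filled.sum()) == 100


def test_open_radius_zero_is_identity(rng):
    mask = rng.random((15, 15)) < 0.4
    out = apply_morphology(mask, SegmentationParams(morphology=(("open", 0),)))
    assert (out == mask).all()


def test_opening_removes_isolated_pixel_and_matches_naive_oracle(rng):
    mask = np.zeros((9, 9), dtype=bool)
    mask[4, 4] = True
    opened = apply_morphology(mask, SegmentationParams(morphology=(("open", 1),)))
    assert not opened.any()
    # random mask with empty border so padding conventions cannot differ
    mask = np.zeros((14, 14), dtype=bool)
    mask[3:11, 3:11] = rng.random((8, 8)) < 0.6
    opened = apply_morphology(mask, SegmentationParams(morphology=(("open", 1),)))
    assert (opened == naive_dilate(naive_erode(mask, 1), 1)).all()


# ---------------------------------------------------------------------------
# box-threshold baseline
# ---------------------------------------------------------------------------

def test_box_threshold_examples():
    im = uniform_image((100, 100, 100))
    assert threshold_baseline(im, (0, 255), (0, 255), (0, 255)).all()
    assert not threshold_baseline(im, (0, 50), (0, 255), (0, 255)).any()
    px = np.empty((10, 10, 3), dtype=np.uint8)
    px[...] = (10, 10, 10)
    px[:5] = (200, 10, 10)
    mask = threshold_baseline(RGBImage(px, "x"), (150, 255), (0, 255), (0, 255))
    assert int(mask.sum()) == 50
    with pytest.raises(ConfigurationError):
        threshold_baseline(im, (200, 100), (0, 255), (0, 255))


def test_grid_searched_box_agrees_with_naive_search(rng):
    """On a tiny color space the fast search equals brute force over all boxes."""
    from histoquant.evaluation import ConfusionCounts, youden_j

    px = rng.integers(0, 256, size=(300, 3), dtype=np.uint8)
    truth = rng.random(300) < 0.4
    step = 64  # 4 bins/channel -> 10^3 boxes, brute-forceable
    _box, fast_j = best_box_threshold(px, truth, step=step)
    best = -np.inf
    bounds = range(0, 256, step)
    for rlo in bounds:
        for rhi in bounds:
            if rhi < rlo:
                continue
            for glo in bounds:
                for ghi in bounds:
                    if ghi < glo:
                        continue
                    for blo in bounds:
                        for bhi in bounds:
                            if bhi < blo:
                                continue
                            pred = (
                                (px[:, 0] >= rlo) & (px[:, 0] <= rhi + step - 1)
                                & (px[:, 1] >= glo) & (px[:, 1] <= ghi + step - 1)
                                & (px[:, 2] >= blo) & (px[:, 2] <= bhi + step - 1)
                            )
                            tp = int((pred & truth).sum())
                            fp = int((pred & ~truth).sum())
                            j = tp / truth.sum() - fp / (~truth).sum()
                            best = max(best, j)
    assert fast_j == pytest.approx(best, abs=1e-12)


# ---------------------------------------------------------------------------
# overlays, edge flagging, pipeline postprocess
# ---------------------------------------------------------------------------

def test_overlay_blending_arithmetic():
    im = uniform_image((100, 60, 20), shape=(4, 4))
    empty = LabelMask(np.zeros((4, 4), dtype=np.int16), ("pos",), "img")
    out = render_overlay(im, empty, {"pos": (0, 255, 0)}, opacity=0.7)
    assert (out.pixels == im.pixels).all()
    full = LabelMask(np.ones((4, 4), dtype=np.int16), ("pos",), "img")
    solid = render_overlay(im, full, {"pos": (0, 255, 0)}, opacity=1.0)
    assert (solid.pixels == (0, 255, 0)).all()
    half = render_overlay(im, full, {"pos": (0, 255, 0)}, opacity=0.5)
    assert (half.pixels == (50, 158, 10)).all()  # rounded channelwise midpoint
    assert (im.pixels == 100).any()  # source untouched


def test_overlay_requires_colors_for_all_classes():
    im = uniform_image((0, 0, 0), shape=(2, 2))
    mask = LabelMask(np.zeros((2, 2), dtype=np.int16), ("a", "b"), "img")
    with pytest.raises(ConfigurationError, match="b"):
        render_overlay(im, mask, {"a": (255, 0, 0)})


def test_edge_flagging_partition():
    params = SegmentationParams(background_min_channel=220)
    tissue = uniform_image((150, 100, 120), shape=(10, 10), image_id="tissue")
    white = uniform_image((255, 255, 255), shape=(10, 10), image_id="white")
    px = np.empty((10, 10, 3), dtype=np.uint8)
    px[...] = (150, 100, 120)
    px[:3] = (255, 255, 255)  # 30% white
    partial = RGBImage(px, "partial")
    cont, edge = flag_edge_images([tissue, white, partial], params, 0.25)
    assert [i.id for i in cont] == ["tissue"] and {i.id for i in edge} == {"white", "partial"}
    cont, edge = flag_edge_images([partial], params, 0.35)
    assert [i.id for i in cont] == ["partial"]


def test_postprocess_order_and_class_disjointness():
    """Background exclusion applies before size filtering; classes stay disjoint."""
    px = np.empty((12, 12, 3), dtype=np.uint8)
    px[...] = (50, 50, 50)
    px[0:2, 0:2] = (200, 40, 40)  # 4-px positive blob
    px[6:10, 6:10] = (200, 40, 40)  # 16-px positive blob
    px[11, 11] = (255, 255, 255)  # background pixel
    pal = palette_of([(200, 40, 40), (255, 255, 255)], negative_rgbs=[(50, 50, 50)])
    im = RGBImage(px, "img")
    mask = classify_pixels(im, pal)
    params = SegmentationParams(
        background_exclusion=True, background_min_channel=220, min_component_area=10
    )
    out = postprocess(im, mask, params)
    assert out.values[11, 11] == BACKGROUND  # excluded even though palette-positive
    assert int((out.values == 1).sum()) == 16  # small blob removed
    assert out.values[0, 0] == 0


def test_multipage_tiff_rejected(tmp_path):
    import tifffile

    from histoquant.io import read_rgb_image

    arr = np.zeros((2, 5, 5, 3), dtype=np.uint8)
    path = tmp_path / "stack.tif"
    tifffile.imwrite(path, arr, photometric="rgb")
    with pytest.raises(ImageFormatError, match="multi-page"):
        read_rgb_image(path)
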