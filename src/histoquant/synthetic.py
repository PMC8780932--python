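"""Deterministic synthetic histology-like images with pixel-exact ground truth.

The generator emulates the color structure of brightfield histology tiles —
a noisy tissue-colored background, blended-color stained features (ellipses
or star-convex blobs), and optionally a near-white blank-slide margin —
without attempting photorealistic texture. Its purpose is to make every
other module testable against exact truth masks:

* truth is recorded at paint time, never re-estimated from the image;
* identical (spec, seed) yields bit-identical images and masks;
* per-class target area fractions are hit by adaptive feature sizing, and
  the realized fractions are recorded in the metadata.

Noise model: independent per-pixel, per-channel integer offsets drawn
uniformly from [-noise, +noise] and clamped to [0, 255]. A bounded symmetric
distribution keeps separability reasoning exact: with spread 0 every feature
pixel equals its class mean, and two means further apart than twice the
spread (plus a quantization bin) can never produce overlapping observed
colors.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .color_model import RGBImage, RegionAnnotation
from .errors import ConfigurationError, InfeasibleSpecError

MARGIN_COLOR = (247, 246, 244)  # near-white blank slide
_MAX_PACKING = 0.6  # conservative random-packing bound for feasibility


@dataclass(frozen=True)
class FeatureClassSpec:
    """One positive feature class.

    ``mean_colors`` may hold several means: each feature picks one uniformly,
    which models blended stains whose joint RGB distribution is multimodal
    (and therefore not axis-aligned). ``size_range`` bounds the equivalent
    radius (sqrt(area/pi)) in pixels. If ``target_area_fraction`` is set it
    overrides ``count``: features are added, sized to the remaining deficit,
    until the realized fraction is within ``target_tolerance`` of the target.
    """

    name: str
    mean_colors: tuple[tuple[int, int, int], ...]
    noise: int = 8
    shape: str = "ellipse"  # "ellipse" | "blob"
    count: int = 10
    size_range: tuple[float, float] = (4.0, 12.0)
    overlap_allowed: bool = False
    target_area_fraction: float | None = None
    target_tolerance: float = 0.01

    def __post_init__(self) -> None:
        if self.shape not in ("ellipse", "blob"):
            raise ConfigurationError(f"unknown feature shape {self.shape!r}")
        if not self.mean_colors:
            raise ConfigurationError(f"class {self.name!r}: needs at least one mean color")
        for color in self.mean_colors:
            if any(not 0 <= c <= 255 for c in color):
                raise ConfigurationError(f"class {self.name!r}: color {color} out of range")
        if self.noise < 0 or self.count < 0:
            raise ConfigurationError(f"class {self.name!r}: negative noise or count")
        rmin, rmax = self.size_range
        if not 0.5 <= rmin <= rmax:
            raise ConfigurationError(f"class {self.name!r}: bad size_range {self.size_range}")
        if self.target_area_fraction is not None and not 0.0 < self.target_area_fraction < 1.0:
            raise ConfigurationError(
                f"class {self.name!r}: target_area_fraction must be in (0, 1)"
            )


@dataclass(frozen=True)
class SyntheticSpec:
    width: int = 256
    height: int = 256
    seed: int = 0
    background_colors: tuple[tuple[int, int, int], ...] = ((225, 180, 195),)
    background_noise: int = 10
    slide_margin: int = 0
    features: tuple[FeatureClassSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ConfigurationError("image dimensions must be positive")
        if self.slide_margin < 0 or 2 * self.slide_margin >= min(self.width, self.height):
            raise ConfigurationError("slide_margin leaves no interior")
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate feature class names: {names}")


@dataclass
class FeatureRecord:
    class_name: str
    shape: str
    center: tuple[float, float]
    equivalent_radius: float
    area_px: int
    mean_color: tuple[int, int, int]
    params: dict = field(default_factory=dict)


def _check_feasible(spec: SyntheticSpec) -> None:
    m = spec.slide_margin
    interior = (spec.width - 2 * m) * (spec.height - 2 * m)
    total = spec.width * spec.height
    requested = 0.0
    for fc in spec.features:
        rmax = fc.size_range[1]
        # placement needs a safe half-extent of 2r+1 on both sides of the center
        if 2 * (2 * rmax + 1) >= min(spec.width, spec.height) - 2 * m:
            raise InfeasibleSpecError(
                f"class {fc.name!r}: max radius {rmax} does not fit the interior"
            )
        if fc.target_area_fraction is not None:
            requested += fc.target_area_fraction
        else:
            requested += fc.count * math.pi * ((fc.size_range[0] + fc.size_range[1]) / 2) ** 2 / total
    if requested * total > _MAX_PACKING * interior:
        raise InfeasibleSpecError(
            f"requested feature area fraction {requested:.3f} exceeds the packing "
            f"bound {_MAX_PACKING * interior / total:.3f} for this geometry"
        )


# ---------------------------------------------------------------------------
# shape rasterization
# ---------------------------------------------------------------------------

def _ellipse_pixels(
    rng: np.random.Generator, cx: float, cy: float, r: float
) -> tuple[np.ndarray, np.ndarray, dict]:
    aspect = float(rng.uniform(0.7, 1.4))
    a, b = r * aspect, r / aspect  # equivalent radius preserved: sqrt(a*b) = r
    theta = float(rng.uniform(0.0, math.pi))
    e = max(a, b)
    j0, j1 = int(math.floor(cx - e - 1)), int(math.ceil(cx + e + 1))
    i0, i1 = int(math.floor(cy - e - 1)), int(math.ceil(cy + e + 1))
    jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
    dx = jj + 0.5 - cx
    dy = ii + 0.5 - cy
    ct, st = math.cos(theta), math.sin(theta)
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    inside = u * u + v * v <= 1.0
    return ii[inside], jj[inside], {"a": a, "b": b, "theta": theta}


def _blob_pixels(
    rng: np.random.Generator, cx: float, cy: float, r: float
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Star-convex blob: radius modulated by low-order angular harmonics."""
    amps = rng.uniform(0.0, 0.22, size=4)
    phases = rng.uniform(0.0, 2 * math.pi, size=4)
    e = r * (1.0 + float(amps.sum()))
    j0, j1 = int(math.floor(cx - e - 1)), int(math.ceil(cx + e + 1))
    i0, i1 = int(math.floor(cy - e - 1)), int(math.ceil(cy + e + 1))
    jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
    dx = jj + 0.5 - cx
    dy = ii + 0.5 - cy
    dist = np.hypot(dx, dy)
    phi = np.arctan2(dy, dx)
    radius = r * (
        1.0
        + sum(amps[k] * np.cos((k + 2) * phi + phases[k]) for k in range(4))
    )
    inside = dist <= radius
    return ii[inside], jj[inside], {"amps": amps.tolist(), "phases": phases.tolist()}


def _boundary_polygon(rec: FeatureRecord, inset: float = 1.0, n_vertices: int = 16):
    """Polygon tracing a feature's interior, shrunk ``inset`` px inward."""
    cx, cy = rec.center
    ts = np.linspace(0.0, 2 * math.pi, n_vertices, endpoint=False)
    if rec.shape == "ellipse":
        a = max(rec.params["a"] - inset, 0.8)
        b = max(rec.params["b"] - inset, 0.8)
        theta = rec.params["theta"]
        ct, st = math.cos(theta), math.sin(theta)
        xs = cx + a * np.cos(ts) * ct - b * np.sin(ts) * st
        ys = cy + a * np.cos(ts) * st + b * np.sin(ts) * ct
    else:
        amps = np.asarray(rec.params["amps"])
        phases = np.asarray(rec.params["phases"])
        radius = rec.equivalent_radius * (
            1.0 + sum(amps[k] * np.cos((k + 2) * ts + phases[k]) for k in range(4))
        )
        radius = np.maximum(radius - inset, 0.8)
        xs = cx + radius * np.cos(ts)
        ys = cy + radius * np.sin(ts)
    return list(zip(xs.tolist(), ys.tolist()))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate(
    spec: SyntheticSpec, image_id: str = "synthetic"
) -> tuple[RGBImage, dict[str, np.ndarray], dict]:
    """Generate one image plus per-class truth masks and a metadata record."""
    _check_feasible(spec)
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width
    m = spec.slide_margin

    # background: per-pixel choice among background colors, plus noise
    bg_colors = np.asarray(spec.background_colors, dtype=np.int16)
    idx = rng.integers(0, len(bg_colors), size=(H, W))
    canvas = bg_colors[idx]
    if spec.background_noise > 0:
        canvas = canvas + rng.integers(
            -spec.background_noise, spec.background_noise + 1, size=(H, W, 3)
        )

    truths: dict[str, np.ndarray] = {fc.name: np.zeros((H, W), dtype=bool) for fc in spec.features}
    occupied = np.zeros((H, W), dtype=bool)
    records: list[FeatureRecord] = []
    total = H * W

    for fc in spec.features:
        rmin, rmax = fc.size_range
        if fc.target_area_fraction is not None:
            target_px = fc.target_area_fraction * total
            tol_px = fc.target_tolerance * total
        n_placed = 0
        attempts = 0
        max_attempts = 500 + 200 * max(
            fc.count, int(4 * (fc.target_area_fraction or 0) * total / (math.pi * rmin**2)) + 1
        )
        while True:
            if fc.target_area_fraction is not None:
                realized = int(truths[fc.name].sum())
                remaining = target_px - realized
                if remaining <= tol_px:
                    break
                r = min(max(math.sqrt(max(remaining, 1.0) / math.pi), rmin), rmax)
            else:
                if n_placed >= fc.count:
                    break
                r = float(rng.uniform(rmin, rmax))
            attempts += 1
            if attempts > max_attempts:
                raise InfeasibleSpecError(
                    f"class {fc.name!r}: could not place features "
                    f"(placed {n_placed}, attempts {attempts}); spec too dense"
                )
            e = 2.0 * r + 1.0  # safe half-extent for any shape variant
            lo_x, hi_x = m + e, W - m - e
            lo_y, hi_y = m + e, H - m - e
            if hi_x <= lo_x or hi_y <= lo_y:
                raise InfeasibleSpecError(f"class {fc.name!r}: radius {r:.1f} does not fit")
            cx = float(rng.uniform(lo_x, hi_x))
            cy = float(rng.uniform(lo_y, hi_y))
            if fc.shape == "ellipse":
                ii, jj, params = _ellipse_pixels(rng, cx, cy, r)
            else:
                ii, jj, params = _blob_pixels(rng, cx, cy, r)
            if ii.size == 0:
                continue
            if not fc.overlap_allowed and occupied[ii, jj].any():
                continue
            color_i = int(rng.integers(0, len(fc.mean_colors)))
            mean = np.asarray(fc.mean_colors[color_i], dtype=np.int16)
            px = np.broadcast_to(mean, (ii.size, 3)).copy()
            if fc.noise > 0:
                px = px + rng.integers(-fc.noise, fc.noise + 1, size=(ii.size, 3))
            canvas[ii, jj] = px
            # later paint wins: visible truth only
            for other in truths.values():
                other[ii, jj] = False
            truths[fc.name][ii, jj] = True
            occupied[ii, jj] = True
            n_placed += 1
            records.append(
                FeatureRecord(
                    class_name=fc.name,
                    shape=fc.shape,
                    center=(cx, cy),
                    equivalent_radius=r,
                    area_px=int(ii.size),
                    mean_color=tuple(int(c) for c in fc.mean_colors[color_i]),
                    params=params,
                )
            )

    if m > 0:
        ring = np.zeros((H, W), dtype=bool)
        ring[:m, :] = ring[-m:, :] = True
        ring[:, :m] = ring[:, -m:] = True
        white = np.asarray(MARGIN_COLOR, dtype=np.int16)
        n_ring = int(ring.sum())
        canvas[ring] = white + rng.integers(-3, 4, size=(n_ring, 3))
        for t in truths.values():
            t[ring] = False

    image = RGBImage(np.clip(canvas, 0, 255).astype(np.uint8), image_id)
    metadata = {
        "image_id": image_id,
        "width": W,
        "height": H,
        "seed": spec.seed,
        "slide_margin": m,
        "background_colors": [list(c) for c in spec.background_colors],
        "realized_area_fractions": {
            name: int(t.sum()) / total for name, t in truths.items()
        },
        "features": [dataclasses.asdict(r) for r in records],
    }
    return image, truths, metadata


def generate_training_pair(
    spec: SyntheticSpec,
    n_images: int = 2,
    max_positive_per_class: int = 12,
    n_negative_patches: int = 6,
) -> tuple[list[RGBImage], list[RegionAnnotation], list[dict]]:
    """Generate training images plus polygon annotations for them.

    Positive polygons trace feature interiors eroded ~1 px inward, so the
    annotated pixels avoid boundary color mixing; negative annotations are
    rectangles over untouched background (plus one blank-margin patch when a
    margin exists). The result feeds ``accumulate_training`` directly.
    """
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(n_images + 1)
    ann_rng = np.random.default_rng(children[-1])
    images: list[RGBImage] = []
    annotations: list[RegionAnnotation] = []
    metas: list[dict] = []
    for i in range(n_images):
        child_seed = int(children[i].generate_state(1)[0] % (2**31))
        sub = dataclasses.replace(spec, seed=child_seed)
        image_id = f"train_{i}"
        image, truths, meta = generate(sub, image_id=image_id)
        images.append(image)
        metas.append(meta)
        H, W = image.shape

        per_class: dict[str, list[dict]] = {fc.name: [] for fc in spec.features}
        for rec in meta["features"]:
            per_class[rec["class_name"]].append(rec)
        for fc in spec.features:
            recs = per_class[fc.name]
            order = ann_rng.permutation(len(recs))
            taken = 0
            for k in order:
                if taken >= max_positive_per_class:
                    break
                rec = FeatureRecord(**recs[k])
                if rec.equivalent_radius < 2.5:
                    continue
                poly = _boundary_polygon(rec)
                xs = [p[0] for p in poly]
                ys = [p[1] for p in poly]
                if min(xs) < 0 or max(xs) > W or min(ys) < 0 or max(ys) > H:
                    continue
                annotations.append(RegionAnnotation(image_id, fc.name, tuple(poly)))
                taken += 1

        # negative background rectangles over pixels no feature touched
        occupied = np.zeros((H, W), dtype=bool)
        for t in truths.values():
            occupied |= t
        mrg = spec.slide_margin
        side = max(min(H, W) // 10, 4)
        placed = 0
        for _ in range(400):
            if placed >= n_negative_patches:
                break
            x0 = int(ann_rng.integers(mrg, max(W - mrg - side, mrg + 1)))
            y0 = int(ann_rng.integers(mrg, max(H - mrg - side, mrg + 1)))
            if occupied[y0 : y0 + side, x0 : x0 + side].any():
                continue
            annotations.append(
                RegionAnnotation(
                    image_id,
                    "negative",
                    ((x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side)),
                )
            )
            occupied[y0 : y0 + side, x0 : x0 + side] = True  # avoid duplicate patches
            placed += 1
        if mrg >= 6:
            annotations.append(
                RegionAnnotation(
                    image_id,
                    "negative",
                    ((1, 1), (mrg - 1, 1), (mrg - 1, H - 1), (1, H - 1)),
                )
            )
    return images, annotations, metas


# ---------------------------------------------------------------------------
# named presets for the shipped scenarios (illustrative, not stain-calibrated)
# ---------------------------------------------------------------------------

def preset_spec(name: str, seed: int = 0, width: int = 256, height: int = 256) -> SyntheticSpec:
    """Named scenario presets.

    ``steatosis``: near-white fat droplets on pink tissue.
    ``obstruction``: pink occlusive blobs on a purple H&E-like background.
    ``sirius``: red collagen strands on a pale yellow counterstain.
    ``tunel``: brown (positive) and blue (counterstained) nuclei; truth
    brown:blue area ratio 0.16 by construction.
    ``blended``: positive features drawn from two blended means whose
    channel marginals each overlap the multimodal background — separable in
    joint RGB only. This is the scenario where an axis-aligned box threshold
    is provably capped near J = 0.5 while the palette separates cleanly.
    ``edge``: a wide blank-slide margin for edge-image filtering.
    """
    common = dict(width=width, height=height, seed=seed)
    # feature counts are stated for a 256x256 tile and scale with area
    density = (width * height) / (256 * 256)

    def n(base: int) -> int:
        return max(1, round(base * density))

    if name == "steatosis":
        return SyntheticSpec(
            background_colors=((235, 172, 192),),
            background_noise=9,
            features=(
                FeatureClassSpec(
                    name="droplet",
                    mean_colors=((246, 244, 248),),
                    noise=4,
                    shape="ellipse",
                    count=n(25),
                    size_range=(4.0, 13.0),
                ),
            ),
            **common,
        )
    if name == "obstruction":
        return SyntheticSpec(
            background_colors=((198, 168, 214),),
            background_noise=10,
            features=(
                FeatureClassSpec(
                    name="obstruction",
                    mean_colors=((232, 148, 170),),
                    noise=8,
                    shape="blob",
                    count=n(10),
                    size_range=(6.0, 18.0),
                ),
            ),
            **common,
        )
    if name == "sirius":
        return SyntheticSpec(
            background_colors=((232, 214, 142),),
            background_noise=9,
            features=(
                FeatureClassSpec(
                    name="collagen",
                    mean_colors=((190, 58, 52),),
                    noise=7,
                    shape="blob",
                    count=n(14),
                    size_range=(4.0, 12.0),
                ),
            ),
            **common,
        )
    if name == "tunel":
        return SyntheticSpec(
            background_colors=((228, 220, 228),),
            background_noise=7,
            features=(
                FeatureClassSpec(
                    name="blue",
                    mean_colors=((72, 86, 152),),
                    noise=6,
                    shape="ellipse",
                    size_range=(2.5, 6.0),
                    target_area_fraction=0.125,
                    target_tolerance=0.0008,
                ),
                FeatureClassSpec(
                    name="brown",
                    mean_colors=((128, 84, 40),),
                    noise=6,
                    shape="ellipse",
                    size_range=(2.5, 6.0),
                    target_area_fraction=0.02,
                    target_tolerance=0.0004,
                ),
            ),
            **common,
        )
    if name == "blended":
        return SyntheticSpec(
            background_colors=(
                (130, 130, 120),
                (180, 130, 120),
                (80, 130, 120),
                (130, 180, 120),
                (130, 80, 120),
            ),
            background_noise=6,
            features=(
                FeatureClassSpec(
                    name="stain",
                    mean_colors=((180, 80, 120), (80, 180, 120)),
                    noise=6,
                    shape="blob",
                    count=0,
                    size_range=(4.0, 11.0),
                    target_area_fraction=0.15,
                ),
            ),
            **common,
        )
    if name == "edge":
        base = preset_spec("obstruction", seed=seed, width=width, height=height)
        margin = max(min(width, height) // 6, 8)
        fit = max((min(width, height) - 2 * margin - 6) / 4.5, 2.0)
        feats = tuple(
            dataclasses.replace(
                f, size_range=(min(f.size_range[0], fit), min(f.size_range[1], fit))
            )
            for f in base.features
        )
        return dataclasses.replace(base, slide_margin=margin, features=feats)
    raise ConfigurationError(
        f"unknown preset {name!r}; available: steatosis, obstruction, sirius, tunel, blended, edge"
    )


PRESET_NAMES = ("steatosis", "obstruction", "sirius", "tunel", "blended", "edge")


def spec_from_dict(d: Mapping) -> SyntheticSpec:
    """Build a SyntheticSpec from a parsed YAML/JSON document."""
    features = tuple(
        FeatureClassSpec(
            name=f["name"],
            mean_colors=tuple(tuple(c) for c in f["mean_colors"]),
            noise=int(f.get("noise", 8)),
            shape=f.get("shape", "ellipse"),
            count=int(f.get("count", 10)),
            size_range=tuple(f.get("size_range", (4.0, 12.0))),
            overlap_allowed=bool(f.get("overlap_allowed", False)),
            target_area_fraction=f.get("target_area_fraction"),
            target_tolerance=float(f.get("target_tolerance", 0.01)),
        )
        for f in d.get("features", [])
    )
    return SyntheticSpec(
        width=int(d.get("width", 256)),
        height=int(d.get("height", 256)),
        seed=int(d.get("seed", 0)),
        background_colors=tuple(tuple(c) for c in d.get("background_colors", [(225, 180, 195)])),
        background_noise=int(d.get("background_noise", 10)),
        slide_margin=int(d.get("slide_margin", 0)),
        features=features,
    )
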