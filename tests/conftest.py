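import numpy as np
import pytest

from histoquant.color_model import RGBImage


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def uniform_image(color, shape=(10, 10), image_id="img"):
    """An image of one solid color."""
    px = np.empty(shape + (3,), dtype=np.uint8)
    px[...] = color
    return RGBImage(px, image_id)


def point_in_polygon_evenodd(px, py, poly):
    """Scalar even-odd (ray crossing) membership test — the oracle."""
    inside = False
    n = len(poly)
    for k in range(n):
        xa, ya = poly[k - 1]
        xb, yb = poly[k]
        if (ya > py) != (yb > py):
            xint = xa + (py - ya) * (xb - xa) / (yb - ya)
            if px < xint:
                inside = not inside
    return inside


def brute_rasterize(poly, shape):
    """Exhaustive pixel-center rasterization oracle."""
    H, W = shape
    mask = np.zeros((H, W), dtype=bool)
    for i in range(H):
        for j in range(W):
            mask[i, j] = point_in_polygon_evenodd(j + 0.5, i + 0.5, poly)
    return mask


def brute_confusion(pred, ref):
    """Naive per-pixel confusion counting — the metric oracle."""
    tp = fp = tn = fn = 0
    for p, r in zip(np.asarray(pred).ravel().tolist(), np.asarray(ref).ravel().tolist()):
        if p and r:
            tp += 1
        elif p and not r:
            fp += 1
        elif not p and r:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn
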