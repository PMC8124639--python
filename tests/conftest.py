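"""Shared fixtures and the naive reference implementations.

The naive operators here are literal transcriptions of the defining
formulas (explicit offset loops, geodesic steps iterated until two
successive iterates are pixelwise equal).  They are deliberately
independent of the package's fast paths and serve as oracles.
"""

from __future__ import annotations

import numpy as np
import pytest

from msthgr.morphology import StructuringElement, cross_se, disk_se, iterated_dilation_se

FAMILIES = {"disk": disk_se, "iterated-dilation": iterated_dilation_se}


def naive_dilate(img: np.ndarray, se: StructuringElement) -> np.ndarray:
    """max over SE offsets, out-of-bounds ignored (identity -inf)."""
    h, w = img.shape
    out = np.full((h, w), -np.inf)
    for dy, dx in se.offsets():
        ys = slice(max(0, -dy), min(h, h - dy))
        xs = slice(max(0, -dx), min(w, w - dx))
        ys_src = slice(max(0, dy), min(h, h + dy))
        xs_src = slice(max(0, dx), min(w, w + dx))
        out[ys, xs] = np.maximum(out[ys, xs], img[ys_src, xs_src])
    return out


def naive_erode(img: np.ndarray, se: StructuringElement) -> np.ndarray:
    """min over SE offsets, out-of-bounds ignored (identity +inf)."""
    h, w = img.shape
    out = np.full((h, w), np.inf)
    for dy, dx in se.offsets():
        ys = slice(max(0, -dy), min(h, h - dy))
        xs = slice(max(0, -dx), min(w, w - dx))
        ys_src = slice(max(0, dy), min(h, h + dy))
        xs_src = slice(max(0, dx), min(w, w + dx))
        out[ys, xs] = np.minimum(out[ys, xs], img[ys_src, xs_src])
    return out


def naive_reconstruct_dilation(marker, mask, se=None) -> np.ndarray:
    """Loop-until-stable geodesic dilation."""
    se = se or cross_se()
    g = np.asarray(marker, dtype=np.float64)
    f = np.asarray(mask, dtype=np.float64)
    while True:
        nxt = np.minimum(naive_dilate(g, se), f)
        if np.array_equal(nxt, g):
            return g
        g = nxt


def naive_reconstruct_erosion(marker, mask, se=None) -> np.ndarray:
    """Loop-until-stable geodesic erosion."""
    se = se or cross_se()
    g = np.asarray(marker, dtype=np.float64)
    f = np.asarray(mask, dtype=np.float64)
    while True:
        nxt = np.maximum(naive_erode(g, se), f)
        if np.array_equal(nxt, g):
            return g
        g = nxt


def naive_enhance(img, n: int, family: str = "disk", clip: bool = True):
    """Literal transcription of the whole multi-scale pipeline."""
    fam = FAMILIES[family]
    arr = np.asarray(img, dtype=np.float64)
    h1 = cross_se()
    rth, rbh = [], []
    for i in range(1, n + 1):
        hi = fam(i)
        opening = naive_dilate(naive_erode(arr, hi), hi)
        closing = naive_erode(naive_dilate(arr, hi), hi)
        wt = arr - opening
        bt = closing - arr
        rw = arr - naive_reconstruct_dilation(naive_erode(arr, hi), arr, h1)
        rb = naive_reconstruct_erosion(naive_dilate(arr, hi), arr, h1) - arr
        rth.append(naive_reconstruct_dilation(rw, wt, h1))
        rbh.append(naive_reconstruct_dilation(rb, bt, h1))
    srth = np.maximum.reduce(rth)
    srbh = np.maximum.reduce(rbh)
    if n >= 2:
        ssw = np.maximum.reduce([rth[i] - rth[i - 1] for i in range(1, n)])
        ssb = np.maximum.reduce([rbh[i] - rbh[i - 1] for i in range(1, n)])
    else:
        ssw = np.zeros_like(arr)
        ssb = np.zeros_like(arr)
    ie = arr + (srth + ssw) - (srbh + ssb)
    if clip:
        return np.floor(np.clip(ie, 0.0, 255.0) + 0.5).astype(np.uint8)
    return ie


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210331)


@pytest.fixture
def ramp3():
    """The 3x3 ramp used throughout the worked morphology examples."""
    return np.array([[1.0, 2, 3], [4, 5, 6], [7, 8, 9]])


def random_images(rng, count, shapes=((8, 8), (16, 16)), high=256):
    """A reproducible stream of random integer-valued test images."""
    for k in range(count):
        shape = shapes[k % len(shapes)]
        yield rng.integers(0, high, size=shape).astype(np.float64)
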