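"""Edge-detection demo: Sobel gradients thresholded by maximum entropy.

Enhancement is commonly a preprocessing step for edge detection or
segmentation; this module provides the demo pipeline: Sobel gradient
magnitude followed by Kapur maximum-entropy threshold selection, applied
to both the original and the enhanced image for side-by-side comparison.
"""

from __future__ import annotations

import numpy as np
from skimage import filters

from .enhance import render_uint8

__all__ = ["sobel_magnitude", "kapur_threshold", "edge_demo"]


def sobel_magnitude(img) -> np.ndarray:
    """Sobel gradient magnitude (float)."""
    return filters.sobel(np.asarray(img, dtype=np.float64))


def kapur_threshold(img) -> int:
    """Kapur maximum-entropy threshold of an 8-bit image.

    Scans all 256 candidate thresholds t and picks the one maximizing the
    sum of the Shannon entropies of the background ([0, t]) and foreground
    ((t, 255]) histogram partitions.
    """
    arr = np.asarray(img)
    if arr.dtype != np.uint8:
        arr = render_uint8(arr)
    hist = np.bincount(arr.ravel(), minlength=256).astype(np.float64)
    p = hist / hist.sum()
    if np.count_nonzero(p) < 2:
        raise ValueError("maximum-entropy threshold undefined: flat histogram")

    cum = np.cumsum(p)
    best_t, best_h = None, -np.inf
    for t in range(256):
        w0 = cum[t]
        w1 = 1.0 - w0
        if w0 <= 0.0 or w1 <= 0.0:
            continue
        p0 = p[: t + 1] / w0
        p1 = p[t + 1 :] / w1
        h0 = -np.sum(p0[p0 > 0] * np.log(p0[p0 > 0]))
        h1 = -np.sum(p1[p1 > 0] * np.log(p1[p1 > 0]))
        if h0 + h1 > best_h:
            best_h, best_t = h0 + h1, t
    return int(best_t)


def edge_demo(original, enhanced) -> dict[str, np.ndarray]:
    """Four comparison panels: Sobel magnitude and its entropy threshold.

    Returns uint8 renderings: the gradient magnitudes linearly rescaled to
    [0, 255] and the binary masks (0/255) from the Kapur threshold of the
    rescaled gradients.  Flat inputs raise (threshold undefined).
    """
    panels = {}
    for tag, img in (("original", original), ("enhanced", enhanced)):
        grad = sobel_magnitude(img)
        peak = grad.max()
        if peak == 0.0:
            raise ValueError(f"edge demo undefined for a flat {tag} image")
        grad8 = render_uint8(grad / peak * 255.0)
        t = kapur_threshold(grad8)
        panels[f"sobel_{tag}"] = grad8
        panels[f"mask_{tag}"] = np.where(grad8 > t, 255, 0).astype(np.uint8)
    return panels
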