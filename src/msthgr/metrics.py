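"""Image-quality metrics for contrast-enhancement evaluation.

Six metrics, each a pure function of one or two grayscale images:

* ``contrast`` / ``rec`` — decibel-scaled RMS contrast and its ratio
  (relative enhancement in contrast, REC),
* ``cir`` — contrast improvement ratio from a 3x3 local-contrast map,
* ``entropy`` — Shannon entropy of the 256-level histogram, in bits,
* ``spatial_frequency`` — quadrature combination of row and column
  first-difference energies,
* ``psnr`` / ``mse`` — peak signal-to-noise ratio with L = 256,
* ``ambe`` — absolute mean brightness error.

Convention note: the RMS-contrast decibel reading is C = 20*log10(sigma)
with sigma the population standard deviation and a base-10 logarithm; this
is the only reading consistent with the 20x decibel prefactor, and it is
recorded in every report header so comparisons stay interpretable.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "contrast",
    "rec",
    "local_contrast_map",
    "cir",
    "entropy",
    "spatial_frequency",
    "mse",
    "psnr",
    "ambe",
    "METRIC_COLUMNS",
    "evaluate_pair",
]

METRIC_COLUMNS = ["REC", "CIR", "E", "SF", "PSNR", "AMBE"]

CONTRAST_CONVENTION = (
    "C = 20*log10(population std of pixel values); REC = C(enhanced)/C(original)"
)


def _as_float(img) -> np.ndarray:
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"expected a non-empty 2-D image, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    return arr


def _check_pair(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"incompatible image dimensions: {a.shape} vs {b.shape}")


def contrast(img) -> float:
    """Decibel-scaled RMS contrast: 20*log10(population sigma)."""
    arr = _as_float(img)
    sigma = float(arr.std())
    if sigma == 0.0:
        raise ValueError("undefined contrast: image is constant (sigma = 0)")
    return 20.0 * np.log10(sigma)


def rec(original, enhanced) -> float:
    """Relative enhancement in contrast: C(enhanced) / C(original)."""
    a = _as_float(original)
    b = _as_float(enhanced)
    _check_pair(a, b)
    return contrast(b) / contrast(a)


def local_contrast_map(img) -> np.ndarray:
    """3x3 local contrast |rho - iota| / |rho + iota| on interior pixels.

    rho is the center pixel, iota the mean of its 8 neighbours (center
    excluded).  The one-pixel border is excluded; where rho + iota = 0 the
    ratio is defined as 0.
    """
    arr = _as_float(img)
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValueError("local contrast needs an image of at least 3x3 pixels")
    ring = np.ones((3, 3))
    ring[1, 1] = 0.0
    iota = ndi.correlate(arr, ring / 8.0, mode="constant")[1:-1, 1:-1]
    rho = arr[1:-1, 1:-1]
    num = np.abs(rho - iota)
    den = np.abs(rho + iota)
    return np.divide(num, den, out=np.zeros_like(num), where=den != 0)


def cir(original, enhanced) -> float:
    """Contrast improvement ratio over the interior domain.

    CIR = sum((w - w~)^2) / sum(w^2) with w, w~ the local-contrast maps of
    the original and the enhanced image.
    """
    a = _as_float(original)
    b = _as_float(enhanced)
    _check_pair(a, b)
    w = local_contrast_map(a)
    wt = local_contrast_map(b)
    denom = float(np.sum(w * w))
    if denom == 0.0:
        raise ValueError("CIR undefined: original image has zero local contrast")
    return float(np.sum((w - wt) ** 2)) / denom


def entropy(img) -> float:
    """Shannon entropy in bits of the 256-level gray histogram.

    Requires an 8-bit rendering: integer-valued pixels in [0, 255].
    """
    arr = _as_float(img)
    if np.any(arr < 0) or np.any(arr > 255) or not np.array_equal(arr, np.round(arr)):
        raise ValueError("entropy requires an 8-bit image: integer values in [0, 255]")
    counts = np.bincount(arr.astype(np.int64).ravel(), minlength=256)
    p = counts[counts > 0] / arr.size
    return float(-np.sum(p * np.log2(p)))


def spatial_frequency(img) -> float:
    """Spatial frequency: sqrt(RF^2 + CF^2) of first-difference energies.

    RF and CF are the root-mean energies of vertical and horizontal
    neighbour differences, summed over valid index pairs and normalised by
    the full M*N pixel count.
    """
    arr = _as_float(img)
    mn = arr.size
    rf2 = float(np.sum(np.diff(arr, axis=0) ** 2)) / mn
    cf2 = float(np.sum(np.diff(arr, axis=1) ** 2)) / mn
    return float(np.sqrt(rf2 + cf2))


def mse(original, enhanced) -> float:
    """Mean squared error between two compatible images."""
    a = _as_float(original)
    b = _as_float(enhanced)
    _check_pair(a, b)
    return float(np.mean((a - b) ** 2))


def psnr(original, enhanced) -> float:
    """Peak signal-to-noise ratio, 10*log10(255^2 / MSE), in dB.

    Identical images give +inf.
    """
    err = mse(original, enhanced)
    if err == 0.0:
        return float("inf")
    return float(10.0 * np.log10(255.0**2 / err))


def ambe(original, enhanced) -> float:
    """Absolute mean brightness error |mean(original) - mean(enhanced)|."""
    a = _as_float(original)
    b = _as_float(enhanced)
    _check_pair(a, b)
    return float(abs(a.mean() - b.mean()))


def evaluate_pair(original, enhanced) -> dict[str, float]:
    """All six metrics for an original/enhanced pair.

    E and SF are computed on the enhanced image (the original's own E and
    SF belong in a separate original-only row).
    """
    return {
        "REC": rec(original, enhanced),
        "CIR": cir(original, enhanced),
        "E": entropy(enhanced),
        "SF": spatial_frequency(enhanced),
        "PSNR": psnr(original, enhanced),
        "AMBE": ambe(original, enhanced),
    }
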