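"""Reference enhancement baselines used only to populate comparison rows."""

from __future__ import annotations

import numpy as np
from skimage import exposure

from .enhance import render_uint8

__all__ = ["hist_equalize", "clahe", "gamma_correction", "baseline_enhancer"]


def hist_equalize(img) -> np.ndarray:
    """Global histogram equalization of an 8-bit image."""
    arr = np.asarray(img)
    if arr.dtype != np.uint8:
        arr = render_uint8(arr)
    out = exposure.equalize_hist(arr, nbins=256)
    return render_uint8(out * 255.0)


def clahe(img) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization, default parameters."""
    arr = np.asarray(img)
    if arr.dtype != np.uint8:
        arr = render_uint8(arr)
    out = exposure.equalize_adapthist(arr)
    return render_uint8(out * 255.0)


def gamma_correction(img, gamma: float = 1.0) -> np.ndarray:
    """Power-law mapping 255*(I/255)**gamma; gamma = 1 is the identity."""
    arr = np.asarray(img)
    if arr.dtype != np.uint8:
        arr = render_uint8(arr)
    return exposure.adjust_gamma(arr, gamma)


_BASELINES = {"he": hist_equalize, "clahe": clahe, "gc": gamma_correction}


def baseline_enhancer(name: str):
    """Look up a baseline by name ('he', 'clahe' or 'gc')."""
    try:
        return _BASELINES[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown baseline {name!r}; choose from {sorted(_BASELINES)}"
        ) from None
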