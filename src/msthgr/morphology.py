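"""Flat grayscale morphology and geodesic reconstruction.

This module is the algebra every later stage of the enhancement pipeline
composes: dilation/erosion with flat structuring elements, opening/closing,
the classic white/black top-hats, geodesic dilation/erosion, reconstruction
by dilation/erosion, opening/closing by reconstruction, and the top-hats by
reconstruction built from them.

Conventions
-----------
* Images are 2-D arrays of finite, nonnegative reals (8-bit inputs are
  lifted to float64; all intermediate values stay unclipped).
* Structuring elements are flat (binary) and symmetric about their origin,
  so reflection is a no-op.
* At image borders the out-of-bounds neighbours are ignored: they
  contribute the identity of the max (-inf) for dilation and of the min
  (+inf) for erosion.  This preserves anti-extensivity/extensivity and
  min/max duality without inventing padded values.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import reconstruction as _sk_reconstruction

__all__ = [
    "StructuringElement",
    "disk_se",
    "iterated_dilation_se",
    "cross_se",
    "se_family",
    "dilate",
    "erode",
    "open_",
    "close_",
    "wth",
    "bth",
    "geodesic_dilate",
    "geodesic_erode",
    "reconstruct_by_dilation",
    "reconstruct_by_erosion",
    "open_by_reconstruction",
    "close_by_reconstruction",
    "rwth",
    "rbth",
]


def as_image(img) -> np.ndarray:
    """Validate and lift an array to the float64 image domain."""
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"image must be a non-empty 2-D array, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    if np.any(arr < 0):
        raise ValueError("image contains negative values")
    return arr


def _check_compatible(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"incompatible image dimensions: {a.shape} vs {b.shape}")


class StructuringElement:
    """A flat (binary) structuring element with its origin at the center.

    The mask must be odd-sized in both dimensions, contain its origin and
    be symmetric about it (H equals its reflection), so that opening and
    closing need no reflection bookkeeping.
    """

    __slots__ = ("mask", "scale", "shape_tag")

    def __init__(self, mask, scale: int | None = None, shape_tag: str = "custom"):
        m = np.ascontiguousarray(mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("structuring element mask must be 2-D")
        if not m.any():
            raise ValueError("empty structuring element")
        if m.shape[0] % 2 == 0 or m.shape[1] % 2 == 0:
            raise ValueError("structuring element mask must have odd dimensions")
        if not m[m.shape[0] // 2, m.shape[1] // 2]:
            raise ValueError("structuring element origin must be a member of the mask")
        if not np.array_equal(m, m[::-1, ::-1]):
            raise ValueError("structuring element must be symmetric about its origin")
        self.mask = m
        self.scale = scale
        self.shape_tag = shape_tag

    @property
    def size(self) -> int:
        return int(self.mask.sum())

    def offsets(self) -> np.ndarray:
        """Member offsets (dy, dx) relative to the origin."""
        c = np.array(self.mask.shape) // 2
        return np.argwhere(self.mask) - c

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"StructuringElement({self.shape_tag}, scale={self.scale}, "
            f"shape={self.mask.shape}, members={self.size})"
        )


def disk_se(i: int) -> StructuringElement:
    """Discrete Euclidean disk of radius ``i``: cells with x**2 + y**2 <= i**2.

    ``disk_se(1)`` is the 3x3 cross (5 members).  The family is nested:
    disk_se(i).mask is contained in disk_se(i+1).mask.
    """
    if i < 1:
        raise ValueError(f"scale index must be >= 1, got {i}")
    y, x = np.ogrid[-i : i + 1, -i : i + 1]
    return StructuringElement(x * x + y * y <= i * i, scale=i, shape_tag="disk")


def cross_se() -> StructuringElement:
    """The 3x3 cross (unit isotropic neighbourhood, 4-connectivity)."""
    return disk_se(1)


def iterated_dilation_se(i: int) -> StructuringElement:
    """H_i built by binary-dilating the 3x3 cross H_1 with itself i-1 times.

    For a cross seed this yields the diamond (L1 ball) of radius ``i``.
    Unlike the Euclidean disks, this family is a true granulometry: each
    member is open with respect to every smaller member, so openings are
    ordered across scales.
    """
    if i < 1:
        raise ValueError(f"scale index must be >= 1, got {i}")
    h1 = disk_se(1).mask
    m = np.zeros((2 * i + 1, 2 * i + 1), dtype=bool)
    m[i - 1 : i + 2, i - 1 : i + 2] = h1
    if i > 1:
        m = ndi.binary_dilation(m, structure=h1, iterations=i - 1)
    return StructuringElement(m, scale=i, shape_tag="iterated-dilation")


_FAMILIES: dict[str, Callable[[int], StructuringElement]] = {
    "disk": disk_se,
    "iterated-dilation": iterated_dilation_se,
}


def se_family(name: str) -> Callable[[int], StructuringElement]:
    """Look up a scale family by name ('disk' or 'iterated-dilation')."""
    try:
        return _FAMILIES[name]
    except KeyError:
        raise ValueError(
            f"unknown structuring-element family {name!r}; "
            f"choose from {sorted(_FAMILIES)}"
        ) from None


def dilate(img, se: StructuringElement) -> np.ndarray:
    """Flat dilation: pixelwise max over the in-bounds SE neighbourhood."""
    arr = as_image(img)
    return ndi.grey_dilation(arr, footprint=se.mask, mode="constant", cval=-np.inf)


def erode(img, se: StructuringElement) -> np.ndarray:
    """Flat erosion: pixelwise min over the in-bounds SE neighbourhood."""
    arr = as_image(img)
    return ndi.grey_erosion(arr, footprint=se.mask, mode="constant", cval=np.inf)


def open_(img, se: StructuringElement) -> np.ndarray:
    """Morphological opening: erosion followed by dilation (symmetric SE)."""
    return dilate(erode(img, se), se)


def close_(img, se: StructuringElement) -> np.ndarray:
    """Morphological closing: dilation followed by erosion (symmetric SE)."""
    return erode(dilate(img, se), se)


def wth(img, se: StructuringElement) -> np.ndarray:
    """White top-hat: image minus its opening.  Nonnegative everywhere."""
    arr = as_image(img)
    return arr - open_(arr, se)


def bth(img, se: StructuringElement) -> np.ndarray:
    """Black top-hat: closing minus the image.  Nonnegative everywhere."""
    arr = as_image(img)
    return close_(arr, se) - arr


def _check_marker_leq_mask(marker: np.ndarray, mask: np.ndarray, what: str) -> None:
    bad = marker > mask
    if bad.any():
        u, v = np.argwhere(bad)[0]
        raise ValueError(
            f"{what} requires marker <= mask pointwise; first violation at "
            f"pixel ({u}, {v}): marker={marker[u, v]} > mask={mask[u, v]}"
        )


def geodesic_dilate(marker, mask, se: StructuringElement | None = None) -> np.ndarray:
    """One geodesic dilation step: min(dilate(marker, se), mask).

    Requires marker <= mask pointwise.  The default SE is the 3x3 cross.
    """
    g = as_image(marker)
    f = as_image(mask)
    _check_compatible(g, f)
    _check_marker_leq_mask(g, f, "geodesic dilation")
    if se is None:
        se = cross_se()
    return np.minimum(dilate(g, se), f)


def geodesic_erode(marker, mask, se: StructuringElement | None = None) -> np.ndarray:
    """One geodesic erosion step: max(erode(marker, se), mask).

    Requires marker >= mask pointwise.  The default SE is the 3x3 cross.
    """
    g = as_image(marker)
    f = as_image(mask)
    _check_compatible(g, f)
    _check_marker_leq_mask(f, g, "geodesic erosion")
    if se is None:
        se = cross_se()
    return np.maximum(erode(g, se), f)


def reconstruct_by_dilation(
    marker, mask, se: StructuringElement | None = None
) -> np.ndarray:
    """Geodesic dilation iterated to its fixed point.

    Equals the literal loop-until-stable iteration of :func:`geodesic_dilate`
    bit-exactly; computed with the fast hybrid reconstruction algorithm.
    """
    g = as_image(marker)
    f = as_image(mask)
    _check_compatible(g, f)
    _check_marker_leq_mask(g, f, "reconstruction by dilation")
    if se is None:
        se = cross_se()
    return _sk_reconstruction(g, f, method="dilation", footprint=se.mask)


def reconstruct_by_erosion(
    marker, mask, se: StructuringElement | None = None
) -> np.ndarray:
    """Geodesic erosion iterated to its fixed point (dual of dilation)."""
    g = as_image(marker)
    f = as_image(mask)
    _check_compatible(g, f)
    _check_marker_leq_mask(f, g, "reconstruction by erosion")
    if se is None:
        se = cross_se()
    return _sk_reconstruction(g, f, method="erosion", footprint=se.mask)


def open_by_reconstruction(
    img,
    scale: int,
    family: str | Callable[[int], StructuringElement] = "disk",
    recon_se: StructuringElement | None = None,
) -> np.ndarray:
    """Opening by reconstruction: reconstruct the image from its erosion.

    The marker is erode(img, H_scale); geodesic propagation uses the unit
    cross (the scale lives in the marker, not in the propagation SE).
    """
    arr = as_image(img)
    fam = se_family(family) if isinstance(family, str) else family
    marker = erode(arr, fam(scale))
    return reconstruct_by_dilation(marker, arr, se=recon_se)


def close_by_reconstruction(
    img,
    scale: int,
    family: str | Callable[[int], StructuringElement] = "disk",
    recon_se: StructuringElement | None = None,
) -> np.ndarray:
    """Closing by reconstruction: dual reconstruction from the dilation."""
    arr = as_image(img)
    fam = se_family(family) if isinstance(family, str) else family
    marker = dilate(arr, fam(scale))
    return reconstruct_by_erosion(marker, arr, se=recon_se)


def rwth(
    img,
    scale: int,
    family: str | Callable[[int], StructuringElement] = "disk",
) -> np.ndarray:
    """White top-hat by reconstruction: img - open_by_reconstruction(img).

    Nonnegative, and pointwise <= the classic white top-hat at the same
    scale (reconstruction recovers at least the plain opening), which is
    exactly the marker-below-mask contract the enhancement stage needs.
    """
    arr = as_image(img)
    return arr - open_by_reconstruction(arr, scale, family)


def rbth(
    img,
    scale: int,
    family: str | Callable[[int], StructuringElement] = "disk",
) -> np.ndarray:
    """Black top-hat by reconstruction: close_by_reconstruction(img) - img."""
    arr = as_image(img)
    return close_by_reconstruction(arr, scale, family) - arr
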