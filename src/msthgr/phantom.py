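"""Synthetic radiograph-like phantoms with ground-truth masks.

A phantom emulates the content of a panoramic dental radiograph at desk
scale: a dark background, a bright arch-shaped band, elliptical "teeth"
with brighter enamel rims placed along the arch, smooth illumination
shading, Gaussian blur, mild additive noise, and a final squeeze of the
histogram into a sub-range of [0, 255] to emulate the low global contrast
of real radiographs.  Every phantom is reproducible bit-exactly from its
(parameters, seed) pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import ellipse

from .enhance import render_uint8

__all__ = ["PhantomParams", "Phantom", "make_phantom", "phantom_batch"]


@dataclass(frozen=True)
class PhantomParams:
    """Generator parameters; intensity units are 8-bit gray levels."""

    size: tuple[int, int] = (256, 256)
    n_teeth: int = 14
    background_range: tuple[float, float] = (10.0, 40.0)
    arch_range: tuple[float, float] = (80.0, 120.0)
    tooth_range: tuple[float, float] = (120.0, 180.0)
    rim_delta: float = 30.0
    shading_amplitude: float = 8.0
    blur_sigma: float = 1.5
    noise_sigma: float = 3.0
    out_range: tuple[float, float] = (20.0, 200.0)


@dataclass
class Phantom:
    """A generated image plus its ground-truth region masks."""

    image: np.ndarray  # uint8
    masks: dict[str, np.ndarray] = field(repr=False)
    params: PhantomParams = field(repr=False)
    seed: int = 0


def make_phantom(params: PhantomParams | None = None, seed: int = 0) -> Phantom:
    """Generate one phantom, deterministic per (params, seed)."""
    p = params or PhantomParams()
    rng = np.random.default_rng(seed)
    h, w = p.size
    img = np.full((h, w), rng.uniform(*p.background_range))

    # Arch band: the upper half of an annulus anchored below the frame.
    cy, cx = int(h * 0.78), w // 2
    band_mid = 0.42 * min(h, w)
    band_half = 0.10 * min(h, w)
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - cy, xx - cx)
    arch = (np.abs(r - band_mid) <= band_half) & (yy < cy)
    img[arch] = rng.uniform(*p.arch_range)

    # Teeth: radially oriented ellipses along the arch mid-line.
    teeth = np.zeros((h, w), dtype=bool)
    rims = np.zeros((h, w), dtype=bool)
    angles = np.linspace(np.deg2rad(20), np.deg2rad(160), p.n_teeth)
    a_len = 0.055 * min(h, w)  # radial semi-axis
    b_len = 0.028 * min(h, w)  # tangential semi-axis
    for th in angles:
        ty = cy - band_mid * np.sin(th)
        tx = cx + band_mid * np.cos(th)
        rot = np.pi / 2 - th  # align the long axis radially
        rr, cc = ellipse(ty, tx, a_len, b_len, shape=(h, w), rotation=rot)
        tooth = np.zeros((h, w), dtype=bool)
        tooth[rr, cc] = True
        rr, cc = ellipse(ty, tx, a_len - 3, b_len - 3, shape=(h, w), rotation=rot)
        core = np.zeros((h, w), dtype=bool)
        rr_ok = (a_len - 3 > 0) and (b_len - 3 > 0)
        if rr_ok:
            core[rr, cc] = True
        level = rng.uniform(*p.tooth_range)
        img[tooth] = level
        rim = tooth & ~core
        img[rim] = level + p.rim_delta
        teeth |= tooth
        rims |= rim

    # Smooth illumination shading: a low-frequency vertical falloff.
    if p.shading_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        shade = p.shading_amplitude * np.sin(np.pi * yy / h + phase)
        img = np.maximum(img + shade, 0.0)

    if p.blur_sigma > 0:
        img = ndi.gaussian_filter(img, p.blur_sigma)
    if p.noise_sigma > 0:
        img = img + rng.normal(0.0, p.noise_sigma, size=img.shape)

    # Squeeze the histogram into out_range to emulate low global contrast.
    lo, hi = p.out_range
    mn, mx = img.min(), img.max()
    if mx > mn:
        img = lo + (img - mn) * (hi - lo) / (mx - mn)
    else:
        img = np.full_like(img, lo)

    masks = {
        "background": ~(arch | teeth),
        "arch": arch & ~teeth,
        "teeth": teeth & ~rims,
        "rims": rims,
    }
    return Phantom(image=render_uint8(img), masks=masks, params=p, seed=seed)


def phantom_batch(
    count: int = 20, seed: int = 0, params: PhantomParams | None = None
) -> list[Phantom]:
    """A reproducible batch of phantoms with seeds seed, seed+1, ..."""
    return [make_phantom(params, seed=seed + k) for k in range(count)]
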