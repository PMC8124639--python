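"""The multi-scale top-hat / geodesic-reconstruction enhancement pipeline.

At each scale i the bright-feature image RTH_i is the reconstruction (by
dilation, unit-cross propagation) of a gentle marker — the white top-hat by
reconstruction RW_i — under the classic white top-hat WT_i as mask; the
dark-feature image RBH_i is built the same way from the black top-hats.
Adjacent scales are differenced, everything is fused by a pixelwise
maximum, and the enhanced image is

    IE = I + (SRTH + SSW) - (SRBH + SSB)

computed on unclipped reals and rendered to 8 bits by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import morphology as mm

__all__ = [
    "EnhancementConfig",
    "ScaleStack",
    "bright_scales",
    "dark_scales",
    "scale_differences",
    "max_fusion",
    "decompose",
    "enhance",
    "render_uint8",
]


@dataclass(frozen=True)
class EnhancementConfig:
    """Parameters of the multi-scale enhancement.

    n
        Number of scales (structuring-element radii 1..n).  The default of
        7 follows the standard setup for radiograph enhancement: the most
        useful detail lives at small scales.
    se_family
        'disk' (discrete Euclidean disk of radius i, the experimental
        setup) or 'iterated-dilation' (the cross dilated with itself i-1
        times, i.e. diamonds — the formal construction, and the family for
        which scale monotonicity is a theorem).
    clip
        If True (default), the output is clipped to [0, 255] and rounded
        half away from zero to 8-bit; if False the unclipped float image
        is returned for metric experiments.
    """

    n: int = 7
    se_family: str = "disk"
    clip: bool = True

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"number of scales must be >= 1, got {self.n}")
        mm.se_family(self.se_family)  # validate the name early

    def family(self):
        return mm.se_family(self.se_family)


@dataclass
class ScaleStack:
    """Per-scale feature images and their max-fused summaries.

    rth[i-1] / rbh[i-1] hold the bright / dark features at scale i; sw and
    sb hold the differences between adjacent scales (empty when n == 1).
    """

    rth: list[np.ndarray] = field(default_factory=list)
    rbh: list[np.ndarray] = field(default_factory=list)
    sw: list[np.ndarray] = field(default_factory=list)
    sb: list[np.ndarray] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.rth)

    @property
    def srth(self) -> np.ndarray:
        return np.maximum.reduce(self.rth)

    @property
    def srbh(self) -> np.ndarray:
        return np.maximum.reduce(self.rbh)

    @property
    def ssw(self) -> np.ndarray:
        if not self.sw:
            return np.zeros_like(self.rth[0])
        return np.maximum.reduce(self.sw)

    @property
    def ssb(self) -> np.ndarray:
        if not self.sb:
            return np.zeros_like(self.rbh[0])
        return np.maximum.reduce(self.sb)


def bright_scales(img, cfg: EnhancementConfig) -> list[np.ndarray]:
    """Bright features RTH_1..RTH_n.

    RTH_i reconstructs the marker RW_i (white top-hat by reconstruction)
    under the mask WT_i (classic white top-hat); RW_i <= WT_i holds by
    construction and is asserted as an internal contract.
    """
    arr = mm.as_image(img)
    fam = cfg.family()
    unit = mm.cross_se()
    out = []
    for i in range(1, cfg.n + 1):
        mask = mm.wth(arr, fam(i))
        marker = mm.rwth(arr, i, fam)
        if np.any(marker > mask):
            raise AssertionError(
                "internal contract violated: reconstruction top-hat exceeds "
                f"classic top-hat at scale {i}"
            )
        out.append(mm.reconstruct_by_dilation(marker, mask, se=unit))
    return out


def dark_scales(img, cfg: EnhancementConfig) -> list[np.ndarray]:
    """Dark features RBH_1..RBH_n, the black-top-hat dual of bright_scales."""
    arr = mm.as_image(img)
    fam = cfg.family()
    unit = mm.cross_se()
    out = []
    for i in range(1, cfg.n + 1):
        mask = mm.bth(arr, fam(i))
        marker = mm.rbth(arr, i, fam)
        if np.any(marker > mask):
            raise AssertionError(
                "internal contract violated: reconstruction top-hat exceeds "
                f"classic top-hat at scale {i}"
            )
        out.append(mm.reconstruct_by_dilation(marker, mask, se=unit))
    return out


def scale_differences(
    rth: list[np.ndarray], rbh: list[np.ndarray]
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Adjacent-scale differences SW_{i-1} = RTH_i - RTH_{i-1} (dito SB).

    Empty for a single scale.  Nonnegative whenever the scale family keeps
    the per-scale features monotone (guaranteed for 'iterated-dilation').
    """
    sw = [rth[i] - rth[i - 1] for i in range(1, len(rth))]
    sb = [rbh[i] - rbh[i - 1] for i in range(1, len(rbh))]
    return sw, sb


def max_fusion(stack: ScaleStack) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pixelwise maxima (SRTH, SRBH, SSW, SSB) over the stack collections.

    For n == 1 the difference maxima run over an empty index set and are
    defined as zero images, so the enhancement reduces to I + RTH_1 - RBH_1.
    """
    return stack.srth, stack.srbh, stack.ssw, stack.ssb


def decompose(img, cfg: EnhancementConfig | None = None) -> ScaleStack:
    """Run the per-scale extraction and differencing, returning the stack."""
    cfg = cfg or EnhancementConfig()
    rth = bright_scales(img, cfg)
    rbh = dark_scales(img, cfg)
    sw, sb = scale_differences(rth, rbh)
    return ScaleStack(rth=rth, rbh=rbh, sw=sw, sb=sb)


def render_uint8(img) -> np.ndarray:
    """Clip to [0, 255] and round half away from zero to 8-bit."""
    arr = np.clip(np.asarray(img, dtype=np.float64), 0.0, 255.0)
    return np.floor(arr + 0.5).astype(np.uint8)


def enhance(
    img,
    cfg: EnhancementConfig | None = None,
    return_stack: bool = False,
):
    """Enhance a grayscale image: IE = I + (SRTH + SSW) - (SRBH + SSB).

    Parameters
    ----------
    img : 2-D array
        Grayscale image, 8-bit or 8-bit-derived nonnegative reals.
    cfg : EnhancementConfig, optional
        Scale count, SE family and clipping policy; defaults to n=7,
        disk SEs, clipped 8-bit output.
    return_stack : bool
        Also return the diagnostic :class:`ScaleStack`.

    Returns
    -------
    enhanced : ndarray
        uint8 when ``cfg.clip`` (the default), float64 otherwise.
    stack : ScaleStack, only when ``return_stack``.
    """
    cfg = cfg or EnhancementConfig()
    arr = mm.as_image(img)
    stack = decompose(arr, cfg)
    srth, srbh, ssw, ssb = max_fusion(stack)
    ie = arr + (srth + ssw) - (srbh + ssb)
    out = render_uint8(ie) if cfg.clip else ie
    if return_stack:
        return out, stack
    return out
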