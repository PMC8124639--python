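# msthgr — multi-scale top-hat enhancement by geodesic reconstruction

Contrast, detail and edge enhancement for 8-bit grayscale images,
developed for panoramic dental radiographs.  Panoramic radiographs are
low-contrast by nature, and their diagnostic value hinges on how well
fine structure — enamel rims, root canals, trabecular bone — stands out.
`msthgr` implements a multi-scale mathematical-morphology enhancement
(MSTHGR) together with the six image-quality metrics commonly used to
evaluate enhancement algorithms, a synthetic phantom generator for
data-free testing, and a batch harness that produces comparison tables
against classic baselines (HE, CLAHE, gamma correction).

It is aimed at researchers in medical image analysis who need a
reproducible, well-tested reference implementation of
reconstruction-based multi-scale top-hats — as a preprocessing step for
segmentation/edge detection or as a baseline in enhancement studies.

## The algorithm

With flat structuring elements H₁ ⊆ H₂ ⊆ … ⊆ Hₙ (discrete disks of
radius 1..n by default, n = 7), the image I is enhanced as

    IE = I + (SRTH + SSW) − (SRBH + SSB)

where, for each scale i,

* WT_i = I − γ(I, H_i)  (classic white top-hat) and
  RW_i = I − γR(i)(I)  (white top-hat by reconstruction) give the
  bright features  RTH_i = R^δ_{WT_i}(RW_i) — the reconstruction by
  dilation of the gentle marker RW_i under the generous mask WT_i;
* BT_i, RB_i and RBH_i are the dual dark features from the black
  top-hats;
* SRTH = max_i RTH_i, SRBH = max_i RBH_i, and SSW, SSB are the maxima of
  the adjacent-scale differences RTH_i − RTH_{i−1}, RBH_i − RBH_{i−1}.

Reconstruction (geodesic dilation iterated to its fixed point, unit
cross propagation) regrows exactly the structures a marker touches, so
the extracted features keep their shapes instead of the ragged residues
plain top-hats produce.  All arithmetic runs on unclipped floats; the
result is rendered to 8 bits (clip + round) by default.  See
`docs/methods.md` for the full model, conventions and limitations.

## Worked example

```python
from msthgr import make_phantom, enhance, evaluate_pair, entropy, spatial_frequency

ph = make_phantom(seed=0)              # 256x256 radiograph-like phantom
out = enhance(ph.image)                # n=7, disk SEs, 8-bit output
print(evaluate_pair(ph.image, out))
print(entropy(ph.image), spatial_frequency(ph.image))
```

prints (values rounded)

```
REC   1.031    # decibel contrast ratio: contrast increased
CIR   2.091    # local 3x3 contrast strongly improved
E     6.360    # entropy up from 5.779 bits: more detail
SF    14.654   # spatial frequency up from 7.248: sharper edges
PSNR  30.487   # distortion stays moderate
AMBE  0.637    # mean brightness shifted by < 1 gray level
```

The same run from the shell:

```
msthgr phantom --seed 0 --out phantom.png
msthgr enhance phantom.png enhanced.png --scales 7 --se disk
msthgr metrics phantom.png enhanced.png
msthgr edge-demo phantom.png panels/          # Sobel + max-entropy threshold
msthgr batch images/ --out report.csv --method msthgr
```

`batch` writes a CSV with one row per image (columns `image, REC, CIR,
E, SF, PSNR, AMBE`), a final `MEAN` row, and header comments recording
the metric conventions; `--method he|clahe|gc` fills the baseline rows
of a comparison table, and `--method original` reports the
reference-free metrics (E, SF) of the unenhanced images.  Pointing
`batch` at a directory of panoramic radiographs (e.g. a downloaded
clinical dataset) evaluates the full-scale experiment with the same code
path.

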