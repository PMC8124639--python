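# Methods

## The enhancement model

`msthgr` enhances an 8-bit grayscale image `I` by adding its multi-scale
bright features and subtracting its multi-scale dark features:

    IE = I + (SRTH + SSW) - (SRBH + SSB)

At each scale `i = 1..n` the bright-feature image is

    RTH_i = R^δ[ WTH(I, H_i) ]( RWTH_i(I) )

the reconstruction by dilation of a *marker* — the white top-hat by
reconstruction `RWTH_i(I) = I - γR(i)(I)` — under a *mask*, the classic
white top-hat `WTH(I, H_i) = I - γ(I, H_i)`.  The dark features `RBH_i`
are built the same way from the black top-hats (`BTH`, `RBTH`); the
reconstruction is again by dilation, which is valid because the
reconstruction top-hat never exceeds the classic one (see below).
Adjacent scales are differenced (`SW_{i-1} = RTH_i - RTH_{i-1}`, likewise
`SB`), and all collections are fused by a pixelwise maximum into `SRTH`,
`SRBH`, `SSW`, `SSB`.

The idea is that the classic top-hat is a generous detail detector (it
picks up everything smaller than `H_i`, including noise), while the
reconstruction top-hat is conservative (reconstruction regrows every
structure that survives erosion anywhere, so only completely removed
structures register).  Reconstructing the conservative marker under the
generous mask recovers detail with well-preserved shapes, scale by scale.

### Why the marker/mask ordering always holds

Reconstruction by dilation recovers at least the plain opening:
any pixel of `γ(I, H_i)` attains its value over some translate of `H_i`
whose cells all carry mask values at least that high and which is
4-connected, so iterated unit geodesic dilation propagates the eroded
value across it.  Hence `γR(i) ≥ γ(·, H_i)`, and subtracting from `I`
(monotone even in floating point) gives `RWTH_i ≤ WTH_i` pixelwise.  The
pipeline still asserts this internally as a contract.

## Operators and numerical choices

* **Arithmetic domain.** All morphology runs on unclipped float64 lifted
  from 8-bit integers; every intermediate value is integral, so exact
  pixelwise equality is the right stability test for reconstruction and
  determinism is bit-exact.  Clipping is purely a rendering step: the
  final image is clipped to [0, 255] and rounded half away from zero
  (`floor(x + 0.5)` on the clipped nonnegative values), with an
  `clip=False` mode that returns the raw float image for metric
  experiments.
* **Borders.** Out-of-bounds neighbours are ignored: they contribute the
  identity of the max (−∞) for dilation and of the min (+∞) for erosion.
  This keeps anti-extensivity/extensivity and min/max duality exact
  without inventing padded values.
* **Reconstruction.** Implemented with the fast hybrid algorithm
  (scikit-image) with an explicit unit-cross footprint; the test suite
  verifies bit-exact agreement with the literal loop-until-stable
  iteration of the unit geodesic step on hundreds of random marker/mask
  pairs.  The propagation footprint is always the unit cross
  (4-connectivity): the scale of the decomposition lives in the
  marker/mask pair, not in the propagation neighbourhood.
* **Degenerate cases.** A constant image has vanishing top-hats at every
  scale and is returned unchanged.  For `n = 1` the difference
  collections are empty and their maxima `SSW`, `SSB` are defined as zero
  images — the only convention under which the enhancement degrades
  gracefully to `I + RTH_1 - RBH_1`.

## Structuring-element families

Two nested flat families are provided, both symmetric so reflection is a
no-op:

* **`disk` (default).** The discrete Euclidean disk of radius `i` (cells
  with `x² + y² ≤ i²`); radius 1 is the 3×3 cross, radius 2 has 13
  members.  This mirrors the usual experimental setup: a disk whose
  radius grows by 1 per iteration.
* **`iterated-dilation`.** `H_i` is the cross binary-dilated with itself
  `i−1` times, i.e. the diamond (L1 ball) of radius `i` — the formal
  convex construction `H_i = H_1 ⊕ … ⊕ H_1`.

The families agree up to radius 2 and diverge from radius 3.  The
distinction matters for one documented property: the diamond family is a
true granulometry (every member is open with respect to every smaller
member), so openings — and with them the per-scale features `RTH_i`,
`RBH_i` — are monotone across scales and all `SW`/`SB` differences are
nonnegative.  The Euclidean disks are *not* (first failure at radii 2→3:
the cell (2, 2) of the radius-3 disk cannot be covered by a radius-2 disk
inside it), so strict scale monotonicity can fail locally; the test suite
pins down a concrete counterexample.  The pipeline is insensitive to
this because every fused image is defined as a pixelwise maximum over
its collection, which is well-defined with or without monotonicity; the
identity `SRTH = RTH_n` is asserted only where it is a theorem (diamond
family).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `n` | 7 | number of scales (SE radii 1..n). Small scales carry the diagnostically useful detail; larger `n` adds coarser structure and more brightness drift. |
| `se_family` | `disk` | scale family, see above |
| `clip` | `True` | render to 8-bit (clip + round) or return unclipped floats |

## Quality metrics

Six standard enhancement metrics, computed on in-memory arrays (no
recompression), on the 8-bit rendering by default:

* **REC** = `C(IE)/C(I)` with `C = 20·log10(σ)`, σ the population
  standard deviation.  The decibel-contrast reading (root of the variance
  bracket, base-10 logarithm) is the only one consistent with the ×20
  prefactor and with REC values near 1 for realistic enhancements; it is
  recorded in every CSV report header so numbers stay comparable.
  Constant images have undefined contrast (an error, not a sentinel).
* **CIR** = `Σ(ω−ω̃)² / Σω²` over interior pixels, where ω is the 3×3
  local contrast `|ρ−ι|/|ρ+ι|` and ι the mean of the 8 neighbours
  (center excluded); ω := 0 where `ρ+ι = 0`, and a flat original (zero
  denominator) is an error.
* **E**: Shannon entropy in bits of the 256-level histogram; requires an
  8-bit rendering (integer values in [0, 255]).
* **SF** = `√(RF² + CF²)`; RF/CF sum squared vertical/horizontal
  neighbour differences over valid index pairs but keep the full `1/(M·N)`
  normalisation, following the standard printed form of the formula.
* **PSNR** = `10·log10(255²/MSE)`; identical images report `inf`.
* **AMBE** = absolute difference of mean gray levels.

Batch reports are CSV tables with one row per image and a final `MEAN`
row of unweighted arithmetic means, with `#` header lines recording the
method, configuration and metric conventions.

## The phantom generator

Real panoramic radiographs cannot ship with the package, so the fixture
suite uses synthetic phantoms that emulate the *structure* the algorithm
exploits: a dark background (level drawn from 10–40), a bright arch-shaped
band (80–120), 14 radially oriented elliptical teeth (120–180) with
brighter enamel rims (+30) along the arch, a smooth low-frequency
illumination shading (amplitude 8), Gaussian blur (σ = 1.5 px), additive
Gaussian noise (σ = 3 gray levels), and a final affine squeeze of the
histogram into [20, 200] to emulate the low global contrast of real
radiographs.  Default size is 256×256; every phantom is bit-exactly
reproducible from its (parameters, seed) pair, and ground-truth region
masks are returned alongside the image.

What phantoms do *not* emulate: anatomical texture (trabecular bone,
pulp chambers, root canals), overlapping projective anatomy, JPEG
artefacts, and the nearly full dynamic range of clinical radiographs
(original entropy ≈ 5.7 bits here vs ≈ 7.2 on real data).  Passing the
phantom checks therefore shows that the pipeline adds local contrast,
detail and spatial information while preserving brightness on
radiograph-like structure — not that clinical metric values are
reproduced.  One consequence worth naming: on these deliberately
compressed-histogram phantoms, global histogram equalization produces a
much larger CIR than the multi-scale enhancement (it rescales the whole
histogram), whereas on real full-range radiographs its CIR is small.
The brightness story is unaffected: histogram equalization shifts the
mean by ~70 gray levels on phantoms while the multi-scale enhancement
stays below 1, and that ordering is asserted.

## Problem sizes used by the test suite and acceptance script

Property tests run on random 8×8 and 16×16 integer images (over a
hundred marker/mask pairs for the reconstruction oracle; pipeline/oracle
agreement for `n ∈ {1, 2, 3}` under both SE families).  The batch checks
use the default 20-phantom batch at 256×256 with the default `n = 7`
configuration — the package's standard desk-scale experiment, which
completes in well under a minute.  The `batch` CLI command applies the
identical code path to any directory of radiographs for full-scale
evaluation.

## Known limitations

* Flat structuring elements only; no gray-weighted SEs, no 3-D.
* The enhancement is global in its parameterisation — no spatially
  adaptive scale selection.
* Metrics follow the printed normalisations (e.g. SF divides by `M·N`
  although only `(M−1)·N` differences exist); this is deliberate, for
  comparability with published tables, and is recorded in report headers.
* `n = 7` with disk SEs is tuned for ~2-megapixel panoramic radiographs;
  much smaller images may prefer fewer scales.
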