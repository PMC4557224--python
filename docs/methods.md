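# Methods

## Model

Each detected object is represented by an inverse multiquadric radial
basis function centred on its centroid,

```
C(x, y) = α · sqrt( 1/(β + γ(x − x_P)²) + 1/(β + γ(y − y_P)²) ),
```

with α chosen per kernel so the peak equals 100 arbitrary units
(α = 100·√(β/2)). Distances are in pixels; the package's reporting
scale assumes 0.5 µm/pixel (≈200 px per 100 µm), exposed as
`pixel_size_um`. Two parameterizations are built in:

| mode     | β | γ       | intent                              |
|----------|---|---------|-------------------------------------|
| direct   | 3 | 0.01    | direct cell–cell / cell–niche contact (high over the nucleus, steep decay) |
| indirect | 3 | 0.00002 | paracrine interaction (medium values out to ~250 µm) |

Fields of several objects are summed (convolution of the object
indicator image with the kernel) and the summation field is normalized
by the affine map C′ = 100·(C − C_min)/(C_max − C_min). The source
formulation of this map carries a sign/denominator erratum (it maps
C_max to a negative value as printed); the implemented form is the
evident intent, mapping onto [0, 100] while preserving pixel order.

### Separable vs. radial kernel shape

The expression above is a *sum of two one-dimensional terms*, not a
function of radial distance: along the entire row and column through a
source it never decays below ≈70 % of the peak (each term's floor is
√(1/β)/√(2/β) ≈ 0.707). This anisotropy is harmless — in fact it is
part of the measured geometry — for the colocalization and histogram
statistics, and the package implements it verbatim as the default
(`kernel_shape="separable"`, including the closed-form check
C(10, 0) = 100·√(1/4 + 1/3)/√(2/3) ≈ 93.54 under peak normalization).

For gradient/divergence analysis the ridges are disqualifying: they
carry transverse curvature comparable to the peaks, so per-object sinks
cannot be separated at any relative threshold. The isotropic variant
`C = α·√(2/(β + γ·r²))` (`kernel_shape="radial"`) has the same peak and
the same axial profile but no ridges, and it reproduces the documented
sink phenomenology exactly (one fused sink at ≤25 px spacing, five
sinks at ≥50 px, for the five-point cross). Sink analyses therefore use
the radial shape; both shapes are first-class.

### Kernel support and convolution

Convolution is zero-padded linear FFT convolution cropped to the image
size (`scipy.signal.fftconvolve`, mode "same"), never circular:
circular wrap-around makes every single-point field a cyclic shift of
the same kernel, which collapses all field histograms to identity
(intersection ≡ 1) and creates spurious cross-border interactions.

Kernel support is a genuine modelling choice:

* `support="image"` (default) — the kernel has exactly the image's
  size, peak at ((h−1)//2, (w−1)//2). Each source's contribution is
  truncated ±h/2 away. This truncation is *part of the method's
  histogram geometry*: it is what makes a field's value histogram
  depend on the object's position, so that histogram intersection
  decreases with separation (measured: 0.980/0.900/0.800 at
  10/50/100 px for a centre-anchored point pair). The cost is a small
  step discontinuity at the truncation boundary and possible exact
  zeros in far corners for near-border sources.
* `support="full"` — the kernel is evaluated over the whole
  displacement range (2h−1, 2w−1), giving the exact untruncated linear
  convolution: strictly positive and C¹-smooth everywhere. This is the
  right field for derivative work (normalized gradient, divergence,
  sinks); its histograms are nearly position-invariant and are *not*
  used for intersection distances.

## Statistics

* **Pairing and background threshold.** Fields are compared pixel-wise
  after background handling at threshold 25 (on the 0–100 scale). The
  default rule, `clip`, sets sub-threshold values to zero and keeps
  every pixel pair — reading "densities below the threshold are
  excluded" as *excluded from the density*, not as dropped pixels.
  This convention reproduces the documented single-point-pair PCC at
  both 10 px (0.96) and 100 px (0.30 vs 0.31) and MOC at 10 px (0.97).
  Pair-dropping rules (`both-below-excluded`, `either-below-excluded`,
  `none`) are available for sensitivity analysis; the both-rule yields
  PCC 0.88/−0.05 at the same distances and was rejected as the default
  on that evidence.
* **PCC** — Pearson product-moment correlation over retained pairs.
* **MOC** — Σab/√(Σa²·Σb²) over retained pairs.
* **M1/M2** — partner-threshold split coefficients: M1 = fraction of
  field-a mass where b > 50; M2 symmetric. The threshold 50 selects the
  partner's 50-percentile region of the normalized scale.
* **Binary baseline** — the same statistics on raw indicator images,
  no fields, no thresholds; used to demonstrate the collapse at 1 px.
* **Histogram intersection** — 100 uniform bins over [0, 100]
  (configurable); masses normalized to 1; intersection Σ min. Values a
  rounding error outside [0, 100] are clipped before binning.
* **Niche allocation** — per-object intersection of the object's field
  histogram with a niche (e.g. bone) field histogram; an object is
  allocated when the intersection reaches the threshold; the mean ± sd
  over a population summarizes its infiltration pattern.

## Gradient, divergence, sinks

Gradients and divergence use central differences (`numpy.gradient`,
one-sided at borders). The normalized gradient is the gradient
*magnitude* divided by its own field mean (output mean exactly 1); the
formulation leaves scalar-vs-vector status of the normalizing mean
open, and the magnitude reading is adopted. Divergence is normalized by
its mean absolute value. Sinks are 8-connected components of pixels
with divergence below `rel_threshold × min(divergence)`;
`rel_threshold` defaults to 0.4, calibrated — as the method prescribes —
to reproduce the fuse-at-25-px / split-at-125-px behaviour of the
five-point cluster (any value in [0.2, 0.4] does; 0.5 already splits
the 25 px cluster).

## Synthetic data

`make_point_image` / `make_cluster_image` generate the binary
proof-of-principle images (500×500 by convention; cross clusters are
the centre plus four axis neighbours at the given spacing — the
arrangement is not specified in the source and the cross is the
package's choice, giving a single spacing parameter).

`make_pseudo_ihc` emulates an Aperio-scanned, registered brightfield
IHC tile: stain densities are composed in optical-density space from
the Ruifrok–Johnston H-DAB basis (every cell gets a hematoxylin nucleus
of σ = 3.5 px at OD ≈ 1.0–1.2; stained cells add a DAB blob of
σ = 4.5 px), converted to RGB by the inverse Beer–Lambert mixing, so
colour deconvolution round-trips. Cell centres are rejection-sampled
with ≥24 px separation and cannot fall on bone bands; bands are drawn
as a pale-green wash and recorded in the ground-truth mask. All
randomness flows from one `numpy` seed; repeated calls are
bit-identical. What this generator does *not* emulate: sectioning
artefacts, registration error fields, stain variability, overlapping
nuclei, tissue texture. Tests passing on these fixtures therefore
validate the algorithmic chain, not robustness to real-slide noise.

Preprocessing detects nuclei by Otsu threshold on the summed stain
density, removes components below 5 px, and splits touching blobs by a
distance-transform watershed seeded at local maxima ≥5 px apart (ties
broken by the peak finder's row-major order). The original description
mentions cross-correlation object detection without specifying a
template; threshold+watershed is substituted. Stained classification
uses the Euclidean distance transform to the Otsu-thresholded DAB mask
with a default range of 5 px (≈2.5 µm).

## Reproduction notes and known mismatches

The acceptance experiments reproduce, from scratch, the published
desk-scale values. Reproduced within tolerance: single-point-pair PCC
at 10 and 100 px, MOC at 10 px, the binary-baseline values (exact), the
point-pair histogram-intersection triplet (±0.01), and the sink counts
(exact). Not reproduced, after a systematic search over threshold
rules, point placements, kernel shapes, kernel supports, convolution
modes and cluster spacings:

* MOC at 100 px (printed 0.83; all principled variants give 0.51–0.75);
* the cluster-vs-point M coefficients (printed 0.83/0.59 at 50 px and
  0.03/0.02 at 200 px; the stated construction gives 0.24/0.36 and
  0.15/0.30, and the printed ordering M_cluster > M_point is
  unattainable under the stated formulas for a compact cluster, whose
  larger >50 region necessarily collects the larger partner-mass
  fraction);
* the cluster-point intersection triplet's absolute values (printed
  1.00/0.95/0.83; computed 0.88/0.84/0.78 — order matches; 1.00 is
  impossible for histograms of a 5-source vs a 1-source field);
* the long-range flattening of the intersection profile (successive
  differences stay ≈0.04 per 20 px out to the largest in-image
  separation; the profile is nearly linear, HI ≈ 1 − 0.002·d, within a
  500-wide image anchored at the centre).

The corresponding assertions are kept at face value in the test suite
and fail openly rather than being loosened.

## Numerical choices and limitations

* FFT round-off can leave ~1e−13 negatives where the exact convolution
  is 0; these are clamped to 0.
* Normalization requires a non-constant field; constant fields raise.
* Strict positivity of an un-normalized field holds whenever every
  image pixel is within kernel support of some source (always true for
  `support="full"`; true for `support="image"` when sources are within
  the central region). Corner zeros for extreme placements are allowed
  and documented rather than silently repaired.
* Registration is out of scope: multi-section inputs are declared
  pre-registered by the caller.
* Sink counting on separable-kernel fields is supported but not
  recommended (ridge artefacts); the API does not forbid it because the
  divergence map itself remains well defined.
* Runtime: all shipped experiments use 500×500 grids; a field build is
  a single FFT convolution (milliseconds), and the complete test suite
  runs in seconds on one CPU.
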