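# histofield

Scalar-field analysis of cells and structures in histological sections,
built for bone-marrow pathology and any setting where populations defined
by several immunohistochemical markers must be compared across registered
serial sections.

## The problem and the idea

Bone marrow combines a dense, heterogeneous cell mix with fuzzily
delimited functional compartments (paratrabecular niches, perivascular
spaces). Populations such as regulatory T cells need a *set* of markers
for identification, so the evidence is spread over several serially
stained sections. Pixel-level colocalization across such sections is
fragile: the "same" cell sits at a slightly different position in every
section, and two one-pixel marks that miss each other by a single pixel
score zero overlap.

`histofield` replaces each detected object (cell centroid, bone
trabecula) by a scalar field with its maximum at the object and a shape
chosen to model an interaction range. The field of an object at
(x_P, y_P) is an inverse multiquadric radial basis function

```
C(x, y) = α · sqrt( 1/(β + γ(x − x_P)²) + 1/(β + γ(y − y_P)²) )
```

with α set so that C = 100 (arbitrary units) at the centroid. Two stock
shapes are provided: **direct** (β = 3, γ = 0.01), sharp, for direct
cell–cell contact; **indirect** (β = 3, γ = 0.00002), broad, keeping
medium values over the ~250 µm paracrine range. Fields are additive:
an image's objects are convolved with the kernel (FFT) into a summation
field, which is linearly rescaled to [0, 100].

On these fields the package computes:

* **Colocalization / spatial interaction** — Pearson's r (PCC), the
  Manders overlap coefficient (MOC) and the split coefficients M1/M2,
  with a background threshold (default 25) on the normalized scale;
  plus the standard no-convolution binary baseline for comparison.
* **Distance surrogates** — each field is summarized as a value
  histogram; the histogram intersection Σ_b min(h1_b, h2_b) is 1 for
  identical fields and falls with object separation. It also drives the
  allocation of cells to niches (e.g. the paratrabecular region) via
  per-cell intersection with a bone field.
* **Cluster description** — the divergence of the field's gradient is
  deeply negative at field maxima; connected "sinks" count clusters
  without any explicit distance cutoff (nearby objects fuse into one
  compound sink).

Everything upstream of the fields is included: colour deconvolution of
RGB brightfield IHC (Ruifrok–Johnston H-DAB), nucleus segmentation with
a distance-transform watershed, centroid extraction, and stained /
non-stained classification by distance to DAB-positive areas. Serial
sections are assumed registered before they reach this package. A
synthetic-data module generates all proof-of-principle binary images
and pseudo-IHC images with ground truth.

## Worked example

```python
from histofield import (baseline_binary_coloc, make_point_image,
                        manders_overlap, pair_fields, pearson, point_field)

SHAPE, CENTER = (500, 500), (250, 250)
a = point_field([CENTER], SHAPE)                 # direct kernel, peak 100
b = point_field([(250, 260)], SHAPE)             # 10 px away
pairs = pair_fields(a, b, threshold=25.0)
print(f"PCC={pearson(pairs):.2f}  MOC={manders_overlap(pairs):.2f}")

base = baseline_binary_coloc(make_point_image(*SHAPE, [CENTER]),
                             make_point_image(*SHAPE, [(250, 251)]))
print(f"binary baseline at 1 px: PCC={base.pcc:.2f}  MOC={base.moc:.2f}")
```

prints

```
PCC=0.96  MOC=0.97
binary baseline at 1 px: PCC=-0.00  MOC=0.00
```

Two points ten pixels apart still correlate at 0.96 through their
fields, while the classical binary overlap is already zero at one pixel
— the robustness that makes colocalization across serial sections
feasible. The scripts in `examples/` walk through each capability
(point-pair colocalization, sink-based cluster counting, histogram
intersection distance profiles, and the full pseudo-IHC pipeline); the
`histofield` command exposes the same steps from the shell
(`histofield simulate | detect | field | coloc | intersect | sinks | run`).

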