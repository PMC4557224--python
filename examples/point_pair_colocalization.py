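"""Colocalization of two single points, with and without fields.

Builds 500x500 binary images containing one point each, converts them to
direct-interaction scalar fields, and compares the field-based PCC/MOC
against the standard binary colocalization.  The field statistics fall
gradually with distance; the binary baseline collapses at one pixel.
"""

from histofield import (
    baseline_binary_coloc,
    make_point_image,
    manders_overlap,
    pair_fields,
    pearson,
    point_field,
)

SHAPE = (500, 500)
CENTER = (250, 250)

center_field = point_field([CENTER], SHAPE)

print("field-based statistics (direct kernel, threshold 25):")
for d in (10, 50, 100, 200):
    other = point_field([(CENTER[0], CENTER[1] + d)], SHAPE)
    pairs = pair_fields(center_field, other, threshold=25.0)
    print(f"  d={d:>3} px: PCC={pearson(pairs):5.2f}  MOC={manders_overlap(pairs):5.2f}")

print("binary baseline (no convolution):")
for d in (0, 1):
    a = make_point_image(*SHAPE, [CENTER])
    b = make_point_image(*SHAPE, [(CENTER[0], CENTER[1] + d)])
    res = baseline_binary_coloc(a, b)
    print(f"  d={d} px: PCC={res.pcc:5.2f}  MOC={res.moc:5.2f}")

print(
    "\nThe field PCC stays above 0.9 at 10 px and decays smoothly, while\n"
    "the binary PCC drops from 1 to 0 the moment the points stop coinciding\n"
    "— the robustness that makes serial-section colocalization workable."
)
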