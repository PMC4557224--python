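"""Distance measurement through histogram intersection.

Each normalized field is summarized as a histogram of its values; the
intersection of two such histograms is 1 for identical fields and falls
as the underlying objects move apart — a distance surrogate that scales
to thousands of cells because it never enumerates object pairs.
"""

from histofield import RBFParams, intersection_distance_profile

profile = intersection_distance_profile(
    RBFParams.direct(), distances=[0, 10, 50, 100, 150, 200, 240]
)
print("separation -> histogram intersection (direct kernel, 500x500):")
for d, hi in profile:
    bar = "#" * int(round(hi * 40))
    print(f"  {d:>3} px: {hi:0.3f} {bar}")

print(
    "\nIntersection 1.0 means indistinguishable value distributions;\n"
    "lower values mean the two objects occupy increasingly different\n"
    "positions relative to the tissue section."
)
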