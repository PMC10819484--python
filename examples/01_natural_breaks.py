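"""Classify a 1-D intensity sample with exact natural-breaks (Jenks).

The solver finds the partition of the sorted values into k contiguous
classes minimising the within-class sum of squared deviations — the same
rule a GIS uses to reclassify a raster into k colour classes.
"""

from rhizoquant import classify_value, jenks_breaks

# a small bimodal sample: two tight clusters separated by a gap
values = [0.11, 0.13, 0.15, 0.14, 0.52, 0.49, 0.51, 0.86, 0.84, 0.88]

res = jenks_breaks(values, k=3)
print("breaks:", [round(b, 2) for b in res.breaks])
print("within-class SSD:", round(res.within_class_ssd, 5))
for v in (0.10, 0.50, 0.90):
    print(f"value {v:.2f} -> class {classify_value(v, res)}")

# The two breaks (0.49 and 0.84) open the middle and upper classes, so the
# three intensity modes land in classes 0, 1 and 2; the SSD is the residual
# spread inside the three clusters.
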